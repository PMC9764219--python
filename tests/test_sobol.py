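import numpy as np
import pytest
from scipy import stats

from coroflow.errors import DegenerateError, DesignError
from coroflow.sobol import (CLINICAL_INPUTS, UncertainInput,
                            distal_location_cv, perturb_case,
                            saltelli_sample, sobol_indices)

Z2 = [UncertainInput("z1", "value", 0.0, 1.0),
      UncertainInput("z2", "value", 0.0, 1.0)]


def test_design_size_and_determinism():
    X = saltelli_sample(CLINICAL_INPUTS, 8, seed=3)
    assert X.shape == (8 * (2 * 4 + 2), 4)
    assert np.array_equal(X, saltelli_sample(CLINICAL_INPUTS, 8, seed=3))
    assert not np.array_equal(X, saltelli_sample(CLINICAL_INPUTS, 8, seed=4))


def test_design_needs_two_inputs():
    with pytest.raises(DesignError):
        saltelli_sample(CLINICAL_INPUTS[:1], 8)


def test_marginals_match_distributions():
    n = 4096
    X = saltelli_sample(CLINICAL_INPUTS, n, seed=1)
    base = X[:2 * n]  # A and B blocks are plain samples
    for j, inp in enumerate(CLINICAL_INPUTS):
        se_mean = inp.sigma / np.sqrt(len(base))
        assert abs(np.mean(base[:, j]) - inp.mu) < 3 * se_mean
        assert abs(np.std(base[:, j]) - inp.sigma) < 3 * se_mean * np.sqrt(2)


def test_distal_location_cv():
    assert distal_location_cv() == pytest.approx(3.5 / 30.0)


def test_additive_gaussian_indices():
    n = 4096
    X = saltelli_sample(Z2, n, seed=3)
    Y = X[:, 0] + 2.0 * X[:, 1]
    r = sobol_indices(Y, 2, n, names=["z1", "z2"], seed=5)
    assert r.Si[0] == pytest.approx(0.2, abs=0.02)
    assert r.Si[1] == pytest.approx(0.8, abs=0.02)
    assert abs(r.Sij[("z1", "z2")]) < 0.02
    assert np.allclose(r.Si, r.STi, atol=0.02)
    assert set(r.significant) == {"z1", "z2"}


def test_constant_output_is_degenerate():
    n = 64
    Y = np.ones(n * 6)
    with pytest.raises(DegenerateError):
        sobol_indices(Y, 2, n)


def test_indices_match_double_loop_monte_carlo():
    """Saltelli/Jansen estimates agree with a brute-force double-loop
    conditional-variance estimate on an additive quadratic model."""
    def f(x):
        return x[..., 0] + x[..., 1] ** 2

    n = 8192
    X = saltelli_sample(Z2, n, seed=9)
    r = sobol_indices(f(X), 2, n, seed=2, bootstrap_B=200)

    # double-loop oracle: outer Gauss-Hermite quadrature over the
    # conditioned input, inner Monte Carlo over the others
    rng = np.random.default_rng(12)
    nodes, wts = np.polynomial.hermite_e.hermegauss(64)
    wts = wts / wts.sum()
    gx, gy = np.meshgrid(nodes, nodes)
    gw = np.outer(wts, wts)
    fv = f(np.stack([gx, gy], axis=-1))
    V = float(np.sum(gw * fv ** 2) - np.sum(gw * fv) ** 2)
    brute = []
    n_inner = 4000
    for i in range(2):
        cond = np.empty(len(nodes))
        for a, za in enumerate(nodes):
            x = rng.standard_normal((n_inner, 2))
            x[:, i] = za
            cond[a] = np.mean(f(x))
        brute.append(float(np.sum(wts * cond ** 2)
                           - np.sum(wts * cond) ** 2) / V)
    assert r.Si[0] == pytest.approx(brute[0], abs=0.02)
    assert r.Si[1] == pytest.approx(brute[1], abs=0.02)
    # analytic check: V = 1 + 2 -> S1 = 1/3, S2 = 2/3
    assert r.Si[0] == pytest.approx(1.0 / 3.0, abs=0.02)
    assert r.Si[1] == pytest.approx(2.0 / 3.0, abs=0.02)


def test_bootstrap_ci_shrinks_with_n():
    widths = []
    for n in (512, 2048):
        X = saltelli_sample(Z2, n, seed=3)
        Y = X[:, 0] + 2.0 * X[:, 1]
        r = sobol_indices(Y, 2, n, seed=5, bootstrap_B=300)
        widths.append(float(np.mean(r.Si_ci[:, 1] - r.Si_ci[:, 0])))
    assert widths[1] < 0.75 * widths[0]


def test_single_uncertain_source_total_index_one():
    ins = [UncertainInput("a", "value", 0.0, 1.0),
           UncertainInput("b", "value", 0.0, 1e-12)]
    # only input a matters
    n = 2048
    X = saltelli_sample([ins[0], UncertainInput("b", "value", 0.0, 1.0)],
                        n, seed=4)
    Y = np.sin(X[:, 0])
    r = sobol_indices(Y, 2, n, seed=6, bootstrap_B=200)
    assert r.STi[0] == pytest.approx(1.0, abs=0.03)
    assert r.STi[1] == pytest.approx(0.0, abs=0.03)


def test_table_transform_semantics():
    """factor multiplies, addition shifts, value replaces -- checked by
    inspecting the perturbed case."""
    import coroflow as cf
    from coroflow.synthetic import CohortRecipe, generate_cohort
    case = generate_cohort(CohortRecipe(n_patients=1, seed=5))[0]
    vals = {"distal_location": 25.0, "cardiac_output": 1.2,
            "stenosis_degree": 10.0, "mean_arterial_pressure": 0.9}
    tree, patient = perturb_case(case, vals)
    assert patient.distal_location_mm == pytest.approx(25.0)
    assert patient.co_resistance_Lmin == pytest.approx(
        1.2 * case.patient.co_resistance_Lmin)
    assert patient.co_inlet_Lmin == pytest.approx(case.patient.co_inlet_Lmin)
    assert patient.map_mmHg == pytest.approx(0.9 * case.patient.map_mmHg)
    assert tree.stenoses[0].degree_pct == pytest.approx(
        case.stenosis.degree_pct + 10.0)
    # rs held fixed, ru re-derived
    assert tree.stenoses[0].rs_mm == pytest.approx(case.stenosis.rs_mm)
    assert tree.stenoses[0].ru_mm > case.stenosis.ru_mm


def test_degree_perturbation_clipped():
    import coroflow as cf
    from coroflow.synthetic import CohortRecipe, generate_cohort
    case = generate_cohort(CohortRecipe(n_patients=1, seed=5))[0]
    tree, _ = perturb_case(case, {"stenosis_degree": 500.0})
    assert tree.stenoses[0].degree_pct == pytest.approx(99.5)
    tree, _ = perturb_case(case, {"stenosis_degree": -500.0})
    assert tree.stenoses[0].degree_pct == pytest.approx(0.0)
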