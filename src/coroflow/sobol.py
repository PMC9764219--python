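"""Variance-based global uncertainty quantification of FFR.

Four clinical inputs carry uncertainty: the distal sampling location
(replacement value, N(30.0, 3.5) mm), cardiac output (multiplicative
factor, N(1, 0.153)), stenosis degree (additive percentage points,
N(0, 16.9)) and mean arterial pressure (factor, N(1, 0.056)).  A
second-order Saltelli design over these inputs drives repeated FFR
simulations; first-, second- and total-order Sobol indices are estimated
with the Saltelli-2010 / Jansen estimator pair, with percentile bootstrap
confidence intervals over the base sample rows.  Indices above 0.05 are
considered significant; the index set is considered converged when the
95% CI width of every main and total effect is below 10% of the largest
index.

The reclassification study re-samples only the cardiac-output and
stenosis-degree distributions at increasing standard-deviation
multipliers and tracks the within-case FFR range and the proportion of
the cohort whose ischemic classification (threshold 0.80) flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateError, DesignError, PipelineError
from .geometry import StenosisSpec

SIGNIFICANCE_THRESHOLD = 0.05
CI_WIDTH_FRACTION = 0.10
DEGREE_CLIP = (0.0, 99.5)
FACTOR_CLIP = 0.05


@dataclass(frozen=True)
class UncertainInput:
    """One uncertain clinical input with a normal uncertainty model.

    ``kind`` states how a sampled value z perturbs the baseline b:
    ``value`` replaces (b -> z), ``factor`` multiplies (b -> z*b),
    ``addition`` adds percentage points (b -> b + z).
    """

    name: str
    kind: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.kind not in ("value", "factor", "addition"):
            raise DesignError(f"unknown input kind {self.kind!r}")
        if self.sigma <= 0:
            raise DesignError("sigma must be > 0")


#: Default uncertainty model of the four clinical inputs.
CLINICAL_INPUTS: Tuple[UncertainInput, ...] = (
    UncertainInput("distal_location", "value", 30.0, 3.5),
    UncertainInput("cardiac_output", "factor", 1.0, 0.153),
    UncertainInput("stenosis_degree", "addition", 0.0, 16.9),
    UncertainInput("mean_arterial_pressure", "factor", 1.0, 0.056),
)


def distal_location_cv(inp: UncertainInput = CLINICAL_INPUTS[0]) -> float:
    """Coefficient of variation sigma/mu of the distal-location input."""
    return inp.sigma / inp.mu


# ---------------------------------------------------------------------------
# Saltelli design
# ---------------------------------------------------------------------------

def saltelli_sample(inputs: Sequence[UncertainInput], n: int,
                    seed: int = 0) -> np.ndarray:
    """Second-order (radial) Saltelli design with normal marginals.

    Returns an ``(n*(2k+2), k)`` matrix of parameter vectors ordered as
    the blocks ``[A, B, AB_1..AB_k, BA_1..BA_k]`` where ``AB_i`` is A
    with column i taken from B and vice versa.  The base points come from
    a scrambled Sobol low-discrepancy sequence in 2k dimensions, mapped
    through the normal inverse CDF.  Deterministic for a fixed seed.
    """
    k = len(inputs)
    if k < 2:
        raise DesignError("need at least 2 uncertain inputs")
    if n < 2:
        raise DesignError("base sample size must be >= 2")
    if n & (n - 1):
        warnings.warn("base sample size is not a power of 2; the Sobol "
                      "sequence balance degrades", stacklevel=2)
    eng = stats.qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    u = eng.random(n)
    # keep strictly inside (0,1) for the inverse CDF
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    z = stats.norm.ppf(u)
    mus = np.array([inp.mu for inp in inputs])
    sds = np.array([inp.sigma for inp in inputs])
    a = mus + sds * z[:, :k]
    b = mus + sds * z[:, k:]
    blocks = [a, b]
    for i in range(k):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    for i in range(k):
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    return np.vstack(blocks)


# ---------------------------------------------------------------------------
# index estimation
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    names: List[str]
    Si: np.ndarray
    STi: np.ndarray
    Si_ci: np.ndarray            # (k, 2) percentile bootstrap bounds
    STi_ci: np.ndarray
    Sij: Dict[Tuple[str, str], float]
    var_Y: float
    n: int
    converged: bool
    significant: List[str]

    def summary(self) -> str:
        lines = [f"{'input':>24s} {'Si':>8s} {'STi':>8s}   95% CI (STi)"]
        for i, name in enumerate(self.names):
            lines.append(
                f"{name:>24s} {self.Si[i]:8.3f} {self.STi[i]:8.3f}   "
                f"[{self.STi_ci[i, 0]:.3f}, {self.STi_ci[i, 1]:.3f}]")
        lines.append(f"variance of output: {self.var_Y:.3e}; "
                     f"converged: {self.converged}; "
                     f"significant: {self.significant}")
        return "\n".join(lines)


def _estimate(yA, yB, yAB, yBA):
    """Saltelli-2010 main effects, Jansen total effects, Saltelli-2002
    closed second-order effects; shapes yA/yB (n,), yAB/yBA (k, n)."""
    k = yAB.shape[0]
    all_y = np.concatenate([yA, yB])
    V = np.var(all_y)
    Si = np.array([np.mean(yB * (yAB[i] - yA)) for i in range(k)]) / V
    STi = np.array([0.5 * np.mean((yA - yAB[i]) ** 2)
                    for i in range(k)]) / V
    closed = np.full((k, k), np.nan)
    f02 = np.mean(yA * yB)
    for i in range(k):
        for j in range(i + 1, k):
            closed[i, j] = (np.mean(yBA[i] * yAB[j]) - f02) / V
    return V, Si, STi, closed


def sobol_indices(Y: np.ndarray, k: int, n: int,
                  names: Optional[Sequence[str]] = None,
                  bootstrap_B: int = 1000, seed: int = 0,
                  ci_level: float = 0.95,
                  threshold: float = SIGNIFICANCE_THRESHOLD) -> SobolResult:
    """Sobol indices from model outputs ordered per the Saltelli design.

    ``Y`` has length ``n*(2k+2)`` in the block order produced by
    :func:`saltelli_sample` (possibly concatenated over several cases,
    in which case ``n`` is the total number of base rows).  Raises
    :class:`DegenerateError` for zero output variance.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != n * (2 * k + 2):
        raise DesignError(f"Y has length {Y.shape[0]}, expected "
                          f"n*(2k+2) = {n * (2 * k + 2)}")
    if not np.all(np.isfinite(Y)):
        raise DesignError("Y contains non-finite values")
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    yA = Y[:n]
    yB = Y[n:2 * n]
    yAB = Y[2 * n:(2 + k) * n].reshape(k, n)
    yBA = Y[(2 + k) * n:].reshape(k, n)

    if np.var(np.concatenate([yA, yB])) <= 0.0:
        raise DegenerateError("output variance is zero; Sobol indices "
                              "are undefined")
    V, Si, STi, closed = _estimate(yA, yB, yAB, yBA)
    Sij = {}
    for i in range(k):
        for j in range(i + 1, k):
            Sij[(names[i], names[j])] = float(closed[i, j] - Si[i] - Si[j])

    rng = np.random.default_rng(seed)
    bs_Si = np.empty((bootstrap_B, k))
    bs_STi = np.empty((bootstrap_B, k))
    for b in range(bootstrap_B):
        idx = rng.integers(0, n, size=n)
        _, s, st, _ = _estimate(yA[idx], yB[idx], yAB[:, idx], yBA[:, idx])
        bs_Si[b] = s
        bs_STi[b] = st
    q = [(1.0 - ci_level) / 2.0 * 100.0, (1.0 + ci_level) / 2.0 * 100.0]
    Si_ci = np.percentile(bs_Si, q, axis=0).T
    STi_ci = np.percentile(bs_STi, q, axis=0).T

    max_index = max(float(np.max(Si)), float(np.max(STi)), 1e-300)
    widths = np.concatenate([Si_ci[:, 1] - Si_ci[:, 0],
                             STi_ci[:, 1] - STi_ci[:, 0]])
    converged = bool(np.max(widths) < CI_WIDTH_FRACTION * max_index)
    significant = [names[i] for i in range(k)
                   if max(Si[i], STi[i]) > threshold]
    return SobolResult(names=names, Si=Si, STi=STi, Si_ci=Si_ci,
                       STi_ci=STi_ci, Sij=Sij, var_Y=float(V), n=n,
                       converged=converged, significant=significant)


# ---------------------------------------------------------------------------
# FFR perturbation pipeline
# ---------------------------------------------------------------------------

def perturb_case(case, values: Dict[str, float]):
    """Apply one sampled parameter vector to a cohort case.

    Returns ``(tree, patient)`` with: the distal location replaced by the
    sampled value (clamped to the reachable downstream length), the
    resistance-side cardiac output multiplied by the sampled factor (the
    inlet-side CO stays at baseline, which the streamlined analysis
    treats as patient-generalized), MAP multiplied by its factor, and the
    stenosis degree shifted by the sampled percentage points with the
    minimal luminal radius held fixed (the unstenosed reference radius is
    re-derived from the perturbed degree).
    """
    from .ffr import downstream_reach

    tree = case.tree
    st = tree.stenoses[0]
    patient = case.patient

    deg = float(np.clip(st.degree_pct + values.get("stenosis_degree", 0.0),
                        *DEGREE_CLIP))
    new_st = StenosisSpec(segment_id=st.segment_id,
                         position_mm=st.position_mm,
                         length_mm=st.length_mm,
                         rs_mm=st.rs_mm, degree_pct=deg)
    new_tree = replace(tree, stenoses=[new_st] + tree.stenoses[1:])

    co_f = max(values.get("cardiac_output", 1.0), FACTOR_CLIP)
    map_f = max(values.get("mean_arterial_pressure", 1.0), FACTOR_CLIP)
    distal = values.get("distal_location", patient.distal_location_mm)
    distal = float(np.clip(distal, 1.0,
                           downstream_reach(new_tree, new_st) - 0.5))
    new_patient = replace(
        patient,
        map_mmHg=patient.map_mmHg * map_f,
        distal_location_mm=distal,
        co_inlet_Lmin=patient.co_inlet_Lmin,
        co_resistance_Lmin=patient.co_resistance_Lmin * co_f)
    return new_tree, new_patient


def uq_pipeline(cases: Sequence, inputs: Sequence[UncertainInput]
                = CLINICAL_INPUTS, n: int = 64, seed: int = 0,
                controls=None, bootstrap_B: int = 1000,
                max_failure_fraction: float = 0.01,
                progress: Optional[Callable[[int, int], None]] = None
                ) -> SobolResult:
    """Sobol indices of FFR over a cohort.

    Every sampled parameter vector of the second-order Saltelli design is
    applied to every case and FFR recomputed; indices are estimated on
    the aggregate of all FFR values (per-case blocks concatenated so the
    between-case variability enters the output variance).  Individual
    simulation failures are logged and their base rows excluded; more
    than ``max_failure_fraction`` failures aborts.
    """
    from .ffr import simulate_ffr
    from .solver import SolverControls

    controls = controls or SolverControls()
    k = len(inputs)
    names = [inp.name for inp in inputs]
    design = saltelli_sample(inputs, n, seed)
    nrow = design.shape[0]

    Y = np.empty((len(cases), nrow))
    failures = 0
    done = 0
    for ci, case in enumerate(cases):
        for r in range(nrow):
            values = dict(zip(names, design[r]))
            try:
                tree, patient = perturb_case(case, values)
                Y[ci, r] = simulate_ffr(tree, patient,
                                        controls=controls).FFR
            except Exception as exc:  # logged, excluded below
                warnings.warn(f"simulation failed for {case.case_id} row "
                              f"{r}: {exc}", stacklevel=2)
                Y[ci, r] = np.nan
                failures += 1
            done += 1
            if progress is not None:
                progress(done, nrow * len(cases))
    if failures > max_failure_fraction * nrow * len(cases):
        raise PipelineError(f"{failures} failed simulations out of "
                            f"{nrow * len(cases)}")

    # drop base rows with any failure in any block / case
    per_row = Y.reshape(len(cases), 2 * k + 2, n)
    good = np.all(np.isfinite(per_row), axis=(0, 1))
    if not np.all(good):
        per_row = per_row[:, :, good]
    n_eff = per_row.shape[2]
    # concatenate cases blockwise: block b rows = [case0 rows, case1 rows...]
    y_agg = np.concatenate(
        [np.concatenate([per_row[c, b] for c in range(len(cases))])
         for b in range(2 * k + 2)])
    return sobol_indices(y_agg, k, n_eff * len(cases), names=names,
                         bootstrap_B=bootstrap_B, seed=seed + 1)


# ---------------------------------------------------------------------------
# reclassification study
# ---------------------------------------------------------------------------

@dataclass
class ReclassificationCurve:
    sd_multipliers: np.ndarray
    mean_ffr_range: np.ndarray
    reclassification_proportion: np.ndarray
    by_side: Dict[str, "ReclassificationCurve"] = field(default_factory=dict)


def reclassification_study(cases: Sequence,
                           sd_multipliers: Sequence[float] = (0.0, 0.5, 1.0,
                                                              2.0, 3.0),
                           m: int = 16, seed: int = 0, controls=None,
                           co_sigma: float = 0.153,
                           degree_sigma: float = 16.9,
                           threshold: float = 0.80,
                           by_side: bool = False) -> ReclassificationCurve:
    """FFR range and reclassification proportion under re-sampled
    cardiac-output and stenosis-degree uncertainty.

    Per case, ``m`` standard-normal draws are fixed once (nested design):
    at multiplier ``lam`` the perturbations are ``1 + lam*sigma_CO*z1``
    (factor) and ``lam*sigma_deg*z2`` (percentage points); distal
    location and MAP stay at their patient baselines.  Reclassification
    is cumulative over increasing multipliers, so the proportion is
    non-decreasing by construction.
    """
    from .ffr import simulate_ffr
    from .solver import SolverControls

    if m < 2:
        raise DesignError("need at least 2 draws per level")
    controls = controls or SolverControls()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(cases), m, 2))
    lams = np.asarray(sd_multipliers, dtype=float)

    base_ffr = np.array([simulate_ffr(c.tree, c.patient,
                                      controls=controls).FFR
                         for c in cases])
    base_cls = base_ffr <= threshold

    ranges = np.zeros((len(lams), len(cases)))
    reclass = np.zeros((len(lams), len(cases)), dtype=bool)
    crossed = np.zeros(len(cases), dtype=bool)
    for li, lam in enumerate(lams):
        for ci, case in enumerate(cases):
            if lam == 0.0:
                ranges[li, ci] = 0.0
                continue
            vals = [base_ffr[ci]]
            for d in range(m):
                values = {"cardiac_output": 1.0 + lam * co_sigma
                          * z[ci, d, 0],
                          "stenosis_degree": lam * degree_sigma
                          * z[ci, d, 1]}
                tree, patient = perturb_case(case, values)
                try:
                    vals.append(simulate_ffr(tree, patient,
                                             controls=controls).FFR)
                except Exception as exc:
                    warnings.warn(f"draw failed for {case.case_id}: {exc}",
                                  stacklevel=2)
            vals = np.asarray(vals)
            ranges[li, ci] = float(vals.max() - vals.min())
            if np.any((vals <= threshold) != base_cls[ci]):
                crossed[ci] = True
        reclass[li] = crossed.copy()

    def curve(sel: np.ndarray) -> ReclassificationCurve:
        return ReclassificationCurve(
            sd_multipliers=lams,
            mean_ffr_range=ranges[:, sel].mean(axis=1),
            reclassification_proportion=reclass[:, sel].mean(axis=1))

    result = curve(np.ones(len(cases), dtype=bool))
    if by_side:
        for side, label in (("left", "LCA"), ("right", "RCA")):
            sel = np.array([c.patient.side == side for c in cases])
            if np.any(sel):
                result.by_side[label] = curve(sel)
    return result
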