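import math

import numpy as np
import pytest

import coroflow as cf
from conftest import hyperemic_setup
from coroflow.errors import InstabilityError


def _zero_inflow(T=0.85):
    return cf.InflowWaveform(t_s=np.linspace(0.0, T, 5), q_m3s=np.zeros(5))


def test_rest_state_is_equilibrium(single_tree, blood, wall):
    """Uniform unforced state (A=A0, Q=0, zero Windkessel pressure) is a
    fixed point of the full scheme including boundary couplings."""
    out = cf.WindkesselOutlet("v0", Rp=1e9)
    state = cf.initialize_state(single_tree, blood, wall, _zero_inflow(),
                                [out], cf.SolverControls())
    A_before = state.A.copy()
    cf.maccormack_step(state, nsteps=50)
    assert np.allclose(state.A, A_before, rtol=1e-13, atol=0)
    assert np.max(np.abs(state.Q)) < 1e-18


def test_zero_flow_junction_equilibrium(bifurcating_tree, blood, wall):
    outs = [cf.WindkesselOutlet("a", Rp=1e9),
            cf.WindkesselOutlet("b", Rp=1e9)]
    state = cf.initialize_state(bifurcating_tree, blood, wall,
                                _zero_inflow(), outs, cf.SolverControls())
    cf.maccormack_step(state, nsteps=50)
    assert np.max(np.abs(state.Q)) < 1e-18
    assert np.allclose(state.pressures(), 0.0, atol=1e-10)


def test_closed_domain_volume_conservation(blood, wall):
    """With reflective (closed) ends, total lumen volume is conserved to
    round-off while a pressure bump sloshes back and forth."""
    tree = cf.single_vessel(length_mm=40.0, radius_mm=1.8)
    out = cf.WindkesselOutlet("v0", Rp=1e9)
    state = cf.initialize_state(tree, blood, wall, _zero_inflow(), [out],
                                cf.SolverControls())
    state.closed_ends = True
    n = len(state.A)
    bump = 1.0 + 0.02 * np.exp(-0.5 * ((np.arange(n) - n / 2) / 6.0) ** 2)
    state.A = state.A * bump
    v0 = state.volume()
    cf.maccormack_step(state, nsteps=2000)
    assert state.volume() == pytest.approx(v0, rel=1e-12)
    assert np.max(np.abs(state.A / state.mesh.A0 - 1.0)) > 1e-3  # still alive


def test_cfl_violation_refuses_to_start(single_tree, blood, wall):
    out = cf.WindkesselOutlet("v0", Rp=1e9)
    with pytest.raises(InstabilityError, match="maximum stable dt"):
        cf.initialize_state(single_tree, blood, wall, _zero_inflow(), [out],
                            cf.SolverControls(dt_s=1e-3))


def test_symmetric_junction_splits_evenly(bifurcating_tree):
    blood, inflow, outlets = hyperemic_setup(bifurcating_tree)
    hist, rep, _ = cf.run_simulation(bifurcating_tree, blood, cf.WallLaw(),
                                     inflow, outlets,
                                     cf.SolverControls(dt_s=None,
                                                       max_cycles=8,
                                                       min_cycles=2))
    assert rep.converged
    qa = hist["terminal:a"].mean_Q
    qb = hist["terminal:b"].mean_Q
    assert qa == pytest.approx(qb, rel=1e-6)
    assert np.allclose(hist["terminal:a"].Q_m3s, hist["terminal:b"].Q_m3s,
                       rtol=1e-6)


def test_repeat_run_is_bitwise_identical(single_tree):
    blood, inflow, outlets = hyperemic_setup(single_tree)
    ctrl = cf.SolverControls(dt_s=None, max_cycles=4, min_cycles=2)
    h1, _, _ = cf.run_simulation(single_tree, blood, cf.WallLaw(), inflow,
                                 outlets, ctrl)
    h2, _, _ = cf.run_simulation(single_tree, blood, cf.WallLaw(), inflow,
                                 outlets, ctrl)
    assert np.array_equal(h1["inlet"].P_Pa, h2["inlet"].P_Pa)
    assert np.array_equal(h1["terminal:v0"].Q_m3s, h2["terminal:v0"].Q_m3s)


def test_convergence_flag_stays_converged(single_tree):
    """With periodic forcing, once the cycle-to-cycle L2 metric drops
    below tolerance it stays below on subsequent cycles."""
    blood, inflow, outlets = hyperemic_setup(single_tree)
    hist, rep, _ = cf.run_simulation(
        single_tree, blood, cf.WallLaw(), inflow, outlets,
        cf.SolverControls(max_cycles=8, min_cycles=8))
    l2 = np.asarray(rep.L2_history)
    below = np.nonzero(l2 < 1e-3)[0]
    assert len(below) > 0
    assert np.all(l2[below[0]:] < 1e-3)


def test_refinement_changes_distal_pressure_little(single_tree):
    """Halving dx and dt changes the last-cycle mean distal pressure by
    well under 0.5%."""
    blood, inflow, outlets = hyperemic_setup(single_tree)
    probes = {"distal": ("v0", 40.0)}
    means = []
    for dx, dt in [(500.0, 1e-5), (250.0, 5e-6)]:
        hist, rep, _ = cf.run_simulation(
            single_tree, blood, cf.WallLaw(), inflow, outlets,
            cf.SolverControls(dt_s=dt, dx_um=dx, max_cycles=6,
                              min_cycles=2), probes=probes)
        assert rep.converged
        means.append(hist["distal"].mean_P)
    assert abs(means[1] - means[0]) / means[0] < 0.005
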