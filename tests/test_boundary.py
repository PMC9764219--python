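import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coroflow as cf
from coroflow.boundary import (HYPEREMIC_RESISTANCE_FACTOR, PerfusionPlan,
                               ostial_mean_flow)
from coroflow.errors import ConfigError
from coroflow.units import LMIN_TO_M3S, MMHG_TO_PA

MLMIN = 1e-6 / 60.0


def test_inflow_rest_and_hyperemic_means():
    # left side, right-dominant, CO 4.5 L/min, fraction 0.04, split 0.7
    rest = cf.build_inflow(4.5, 70.8, "right", "left", "rest")
    assert rest.mean_m3s == pytest.approx(126.0 * MLMIN, rel=1e-9)
    hyp = cf.build_inflow(4.5, 70.8, "right", "left", "hyperemia")
    assert hyp.mean_m3s == pytest.approx(504.0 * MLMIN, rel=1e-9)


def test_right_side_hyperemia_ratio_is_three():
    rest = ostial_mean_flow(4.5, "right", "right", "rest")
    hyp = ostial_mean_flow(4.5, "right", "right", "hyperemia")
    assert hyp / rest == pytest.approx(3.0, rel=1e-12)


def test_doubling_hr_halves_period_keeps_mean():
    w1 = cf.build_inflow(4.5, 60.0, "right", "left", "rest")
    w2 = cf.build_inflow(4.5, 120.0, "right", "left", "rest")
    assert w2.period_s == pytest.approx(w1.period_s / 2)
    assert w2.mean_m3s == pytest.approx(w1.mean_m3s, rel=1e-9)


@given(hr=st.floats(40.0, 140.0), co=st.floats(2.0, 8.0))
@settings(deadline=None, derandomize=True, max_examples=30)
def test_inflow_mean_matches_target_for_any_hr(hr, co):
    w = cf.build_inflow(co, hr, "left", "left", "rest")
    target = ostial_mean_flow(co, "left", "left", "rest")
    assert w.mean_m3s == pytest.approx(target, rel=1e-9)


def test_unknown_dominance_is_config_error():
    with pytest.raises(ConfigError):
        cf.build_inflow(4.5, 70.0, "bilateral", "left")


def test_two_equal_terminals_resistance():
    plan = PerfusionPlan(Pmean_mmHg=90.0, Qostial_Lmin=0.18,
                         terminal_radii_mm={"a": 1.3, "b": 1.3})
    outs = {o.terminal_id: o for o in cf.distribute_resistances(plan)}
    rtot = 90.0 * MMHG_TO_PA / (0.18 * LMIN_TO_M3S)
    assert outs["a"].Rp == pytest.approx(2 * rtot, rel=1e-12)
    assert outs["b"].Rp == pytest.approx(2 * rtot, rel=1e-12)


def test_radii_two_one_weights():
    plan = PerfusionPlan(Pmean_mmHg=90.0, Qostial_Lmin=0.18,
                         terminal_radii_mm={"a": 2.0, "b": 1.0})
    outs = {o.terminal_id: o for o in cf.distribute_resistances(plan)}
    rtot = 90.0 * MMHG_TO_PA / (0.18 * LMIN_TO_M3S)
    assert outs["a"].Rp == pytest.approx(9.0 / 8.0 * rtot, rel=1e-12)
    assert outs["b"].Rp == pytest.approx(9.0 * rtot, rel=1e-12)


def test_hyperemic_ratio_per_terminal():
    plan = PerfusionPlan(Pmean_mmHg=85.0, Qostial_Lmin=0.15,
                         terminal_radii_mm={"a": 1.7, "b": 0.9, "c": 1.2})
    rest = {o.terminal_id: o.Rp for o in cf.distribute_resistances(plan)}
    hyp = {o.terminal_id: o.Rp
           for o in cf.distribute_resistances(plan, "hyperemia")}
    for tid in rest:
        assert hyp[tid] / rest[tid] == pytest.approx(
            HYPEREMIC_RESISTANCE_FACTOR, rel=1e-15)


@given(radii=st.lists(st.floats(0.5, 3.0), min_size=1, max_size=8))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_parallel_combination_identity(radii):
    plan = PerfusionPlan(Pmean_mmHg=90.0, Qostial_Lmin=0.18,
                         terminal_radii_mm={f"t{i}": r
                                            for i, r in enumerate(radii)})
    outs = cf.distribute_resistances(plan)
    g = sum(1.0 / o.Rp for o in outs)
    rtot = 90.0 * MMHG_TO_PA / (0.18 * LMIN_TO_M3S)
    assert 1.0 / g == pytest.approx(rtot, rel=1e-12)


def test_windkessel_steady_state():
    out = cf.WindkesselOutlet("t", Rp=1.0e9, C=9e-11)
    P, Q, dt = 0.0, 1.0e-5, 1e-4
    tau = out.Rp * out.C
    for _ in range(int(10 * tau / dt)):
        P = cf.windkessel_update(P, Q, out, dt)
    assert P == pytest.approx(Q * out.Rp, rel=1e-3)


def test_windkessel_decay_time_constant():
    out = cf.WindkesselOutlet("t", Rp=1.0e9, C=9e-11)
    tau = out.Rp * out.C
    dt = tau / 20000.0
    P0 = 1000.0
    P = P0
    t = 0.0
    while P > P0 / 2:
        P = cf.windkessel_update(P, 0.0, out, dt)
        t += dt
    assert t == pytest.approx(math.log(2) * tau, rel=1e-2)


def test_windkessel_large_compliance_freezes_pressure():
    out = cf.WindkesselOutlet("t", Rp=1.0e9, C=1e-3)
    P = 1.0e4
    for _ in range(1000):
        P = cf.windkessel_update(P, 0.0, out, 1e-3)
    assert P == pytest.approx(1.0e4, rel=1e-2)


def test_patient_record_roundtrip(tmp_path):
    rec = cf.PatientRecord(map_mmHg=92.0, co_Lmin=5.1, hr_bpm=64.0,
                           hematocrit_pct=41.0, dominance="left",
                           side="right", distal_location_mm=22.0)
    path = tmp_path / "p.json"
    cf.save_patient(rec, path)
    back = cf.load_patient(path)
    assert back.to_dict() == rec.to_dict()
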