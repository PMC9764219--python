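import numpy as np
import pytest

import coroflow as cf


@pytest.fixture(scope="session")
def blood():
    return cf.BloodProperties()


@pytest.fixture(scope="session")
def wall():
    return cf.WallLaw()


@pytest.fixture()
def single_tree():
    return cf.single_vessel(length_mm=50.0, radius_mm=1.95)


@pytest.fixture()
def bifurcating_tree():
    """Symmetric Murray-consistent bifurcation (3 segments)."""
    r_child = 2.0 / 2.0 ** (1.0 / 3.0)
    segs = {
        "p": cf.VesselSegment("p", None, 30.0, radius_mm=(2.0, 2.0)),
        "a": cf.VesselSegment("a", "p", 25.0, radius_mm=(r_child, r_child),
                              terminal=True),
        "b": cf.VesselSegment("b", "p", 25.0, radius_mm=(r_child, r_child),
                              terminal=True),
    }
    return cf.CoronaryTree(segments=segs)


@pytest.fixture()
def stenosed_tree():
    st = cf.StenosisSpec("v0", position_mm=17.5, length_mm=10.0,
                         ru_mm=1.95, degree_pct=55.6)
    return cf.single_vessel(length_mm=50.0, radius_mm=1.95, stenosis=st)


def hyperemic_setup(tree, patient=None):
    """Inflow + outlets for a hyperemic run of one tree."""
    from coroflow.boundary import perfusion_plan_for
    patient = patient or cf.PatientRecord()
    blood = cf.BloodProperties(hematocrit=patient.hematocrit_pct / 100.0)
    inflow = cf.build_inflow(patient.co_inlet_Lmin, patient.hr_bpm,
                             patient.dominance, patient.side, "hyperemia")
    outlets = cf.distribute_resistances(perfusion_plan_for(tree, patient),
                                        "hyperemia")
    return blood, inflow, outlets
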