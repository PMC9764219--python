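"""FFR extraction: distal-probe placement and the Pd/Pa ratio.

Fractional flow reserve is the ratio of the time-averaged pressure at a
physician-chosen location distal to the stenosis to the time-averaged
ostial (aortic) pressure, under hyperemia; FFR <= 0.80 is considered
ischemic.  The distal location is specified as an arc length downstream
of the distal end of the stenosis; when the walk crosses a bifurcation it
follows the child with the larger proximal radius (the main-branch
continuation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .boundary import (PatientRecord, build_inflow, distribute_resistances,
                       perfusion_plan_for)
from .constitutive import BloodProperties, WallLaw
from .errors import ConvergenceError, DomainError, PlacementError
from .geometry import CoronaryTree, StenosisSpec
from .solver import (ConvergenceReport, ProbeTrace, SolverControls,
                     run_simulation)
from .units import PA_TO_MMHG

ISCHEMIC_THRESHOLD = 0.80


@dataclass
class FFRResult:
    FFR: float
    Pd_mean_mmHg: float
    Pa_mean_mmHg: float
    distal_probe: Tuple[str, float]      # (segment id, arc length mm)
    ischemic: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FFR = {self.FFR:.3f} (Pd {self.Pd_mean_mmHg:.1f} / "
                f"Pa {self.Pa_mean_mmHg:.1f} mmHg) -> "
                f"{'ischemic' if self.ischemic else 'non-ischemic'}")


def _main_child(tree: CoronaryTree, seg_id: str):
    ch = tree.children_of(seg_id)
    if not ch:
        return None
    return max(ch, key=lambda s: (s.proximal_radius_mm, s.id))


def downstream_reach(tree: CoronaryTree, stenosis: StenosisSpec) -> float:
    """Arc length (mm) available downstream of the stenosis distal end,
    following the larger-radius child at every bifurcation."""
    seg = tree.segments[stenosis.segment_id]
    reach = seg.length_mm - stenosis.distal_end_mm
    child = _main_child(tree, seg.id)
    while child is not None:
        reach += child.length_mm
        child = _main_child(tree, child.id)
    return reach


def locate_distal_probe(tree: CoronaryTree, stenosis: StenosisSpec,
                        L_distal_mm: float) -> Tuple[str, float]:
    """Walk ``L_distal_mm`` downstream from the stenosis distal end.

    Returns ``(segment_id, arc_mm)`` of the probe point.
    """
    if L_distal_mm <= 0:
        raise DomainError("distal distance must be > 0")
    seg = tree.segments[stenosis.segment_id]
    arc = stenosis.distal_end_mm
    remaining = L_distal_mm
    while True:
        avail = seg.length_mm - arc
        if remaining <= avail + 1e-12:
            return seg.id, arc + remaining
        remaining -= avail
        child = _main_child(tree, seg.id)
        if child is None:
            reach = downstream_reach(tree, stenosis)
            raise PlacementError(
                f"distal location {L_distal_mm} mm exceeds downstream tree "
                f"(maximum reachable {reach:.1f} mm)")
        seg = child
        arc = 0.0


def compute_ffr(history, report: ConvergenceReport,
                inlet_probe: str = "inlet", distal_probe: str = "distal",
                probe_location: Optional[Tuple[str, float]] = None,
                threshold: float = ISCHEMIC_THRESHOLD) -> FFRResult:
    """FFR = cycle-mean distal pressure / cycle-mean inlet pressure."""
    if not report.converged:
        raise ConvergenceError(
            "simulation did not reach periodic convergence; increase "
            "max_cycles or check the configuration before computing FFR")
    pa: ProbeTrace = history[inlet_probe]
    pd: ProbeTrace = history[distal_probe]
    ffr = pd.mean_P / pa.mean_P
    return FFRResult(FFR=ffr,
                     Pd_mean_mmHg=pd.mean_P * PA_TO_MMHG,
                     Pa_mean_mmHg=pa.mean_P * PA_TO_MMHG,
                     distal_probe=probe_location or ("", float("nan")),
                     ischemic=ffr <= threshold)


def simulate_ffr(tree: CoronaryTree, patient: PatientRecord,
                 blood: Optional[BloodProperties] = None,
                 wall: WallLaw = WallLaw(),
                 controls: SolverControls = SolverControls(),
                 state: str = "hyperemia",
                 return_details: bool = False):
    """End-to-end FFR for one case: personalized boundary conditions,
    hyperemic simulation, distal probe, Pd/Pa.

    Blood viscosity is derived from the patient's hematocrit unless an
    explicit :class:`BloodProperties` is given.  Returns the
    :class:`FFRResult`, or ``(result, history, report)`` when
    ``return_details`` is set.
    """
    if blood is None:
        blood = BloodProperties(hematocrit=patient.hematocrit_pct / 100.0)
    inflow = build_inflow(patient.co_inlet_Lmin, patient.hr_bpm,
                          patient.dominance, patient.side, state)
    plan = perfusion_plan_for(tree, patient)
    outlets = distribute_resistances(plan, state)
    if tree.stenoses:
        probe_loc = locate_distal_probe(tree, tree.stenoses[0],
                                        patient.distal_location_mm)
    else:
        # healthy tree: walk from the ostium instead
        pseudo = None
        seg = tree.root
        arc = 0.0
        remaining = patient.distal_location_mm
        while True:
            avail = seg.length_mm - arc
            if remaining <= avail + 1e-12:
                probe_loc = (seg.id, arc + remaining)
                break
            remaining -= avail
            child = _main_child(tree, seg.id)
            if child is None:
                raise PlacementError(
                    f"distal location {patient.distal_location_mm} mm "
                    "exceeds the tree")
            seg, arc = child, 0.0
    history, report, _ = run_simulation(
        tree, blood, wall, inflow, outlets, controls,
        probes={"distal": probe_loc}, convergence_probe="distal")
    result = compute_ffr(history, report, probe_location=probe_loc)
    if return_details:
        return result, history, report
    return result
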