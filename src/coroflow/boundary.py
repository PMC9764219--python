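"""Inlet waveforms and Windkessel outlet boundary conditions.

The ostial (inlet) flow is a pulsatile waveform whose mean equals a
dominance-dependent fraction of cardiac output; hyperemia (adenosine) is
modeled by scaling the left inflow 4x and the right 3x while peripheral
resistances drop to 0.22x of rest.  Each terminal vessel carries a
2-element Windkessel (peripheral resistance Rp, compliance C) with Rp
distributed among terminals by the cube of the terminal radius:

    Ri = (Pmean / Qostial) * (sum_j rj^3) / ri^3

so the parallel combination of all terminals equals Pmean/Qostial exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ConfigError, DomainError, ParseError
from .units import CM4S2G_TO_M3PA, LMIN_TO_M3S, MMHG_TO_PA

#: Fraction of cardiac output perfusing the coronary circulation.
CORONARY_FRACTION = 0.04

#: (left, right) split of coronary flow by dominance.
DOMINANCE_SPLIT = {
    "right": (0.70, 0.30),
    "left": (0.80, 0.20),
    "co-dominant": (0.75, 0.25),
}

#: Hyperemic inlet-flow scale factors by side.
HYPEREMIC_FLOW_FACTOR = {"left": 4.0, "right": 3.0}

#: Hyperemic peripheral-resistance scale factor.
HYPEREMIC_RESISTANCE_FACTOR = 0.22

#: Terminal Windkessel compliance, 9 u-cm^4 s^2 g^-1 in SI (m^3/Pa).
WINDKESSEL_C_SI = 9.0e-6 * CM4S2G_TO_M3PA


@dataclass
class PatientRecord:
    """Clinical scalars parameterizing one simulation case."""

    map_mmHg: float = 87.3
    co_Lmin: float = 4.5
    hr_bpm: float = 70.8
    hematocrit_pct: float = 39.2
    dominance: str = "right"
    side: str = "left"
    distal_location_mm: float = 30.0
    # cardiac output enters the model twice: as the inlet-flow scale and as
    # Qostial in the resistance distribution; streamlined configs may
    # generalize one but not the other.
    co_inlet_Lmin: Optional[float] = None
    co_resistance_Lmin: Optional[float] = None

    def __post_init__(self) -> None:
        if self.co_inlet_Lmin is None:
            self.co_inlet_Lmin = self.co_Lmin
        if self.co_resistance_Lmin is None:
            self.co_resistance_Lmin = self.co_Lmin
        if min(self.map_mmHg, self.co_Lmin, self.hr_bpm) <= 0:
            raise DomainError("MAP, CO and HR must be > 0")
        if not 0.0 <= self.hematocrit_pct < 100.0:
            raise DomainError("hematocrit % outside [0, 100)")
        if self.dominance not in DOMINANCE_SPLIT:
            raise ConfigError(f"unknown dominance {self.dominance!r}")
        if self.side not in ("left", "right"):
            raise ConfigError(f"unknown side {self.side!r}")

    def to_dict(self) -> dict:
        return {"MAP_mmHg": self.map_mmHg, "CO_Lmin": self.co_Lmin,
                "HR_bpm": self.hr_bpm, "hematocrit_pct": self.hematocrit_pct,
                "dominance": self.dominance, "side": self.side,
                "distal_location_mm": self.distal_location_mm}

    @classmethod
    def from_dict(cls, d: dict) -> "PatientRecord":
        try:
            return cls(map_mmHg=float(d["MAP_mmHg"]),
                       co_Lmin=float(d["CO_Lmin"]),
                       hr_bpm=float(d["HR_bpm"]),
                       hematocrit_pct=float(d["hematocrit_pct"]),
                       dominance=d["dominance"], side=d["side"],
                       distal_location_mm=float(d["distal_location_mm"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed patient record: {exc!r}") from exc


def load_patient(path) -> PatientRecord:
    with open(path) as fh:
        return PatientRecord.from_dict(json.load(fh))


def save_patient(rec: PatientRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(rec.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# inflow
# ---------------------------------------------------------------------------

@dataclass
class InflowWaveform:
    """One period of ostial flow, periodic samples (first == last)."""

    t_s: np.ndarray
    q_m3s: np.ndarray
    side: str = "left"
    physiologic_state: str = "rest"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.q_m3s = np.asarray(self.q_m3s, float)
        if len(self.t_s) != len(self.q_m3s) or len(self.t_s) < 3:
            raise DomainError("waveform needs matching t/q samples (>= 3)")
        if abs(self.q_m3s[0] - self.q_m3s[-1]) > 1e-12 * max(
                1e-30, abs(self.q_m3s[0])):
            raise DomainError("waveform must be periodic (first == last)")

    @property
    def period_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    @property
    def mean_m3s(self) -> float:
        return float(np.trapezoid(self.q_m3s, self.t_s) / self.period_s)


def load_waveform_csv(path) -> tuple:
    """Read a sampled waveform CSV with columns (t_s, Q_mLmin).

    Returns a ``(t_frac, q)`` shape tuple usable by :func:`build_inflow`
    (the absolute scale and period are discarded on rescaling).
    """
    import csv as _csv

    t, q = [], []
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        need = {"t_s", "Q_mLmin"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ParseError(f"{path}: waveform CSV needs columns "
                             f"{sorted(need)}")
        for row in reader:
            t.append(float(row["t_s"]))
            q.append(float(row["Q_mLmin"]))
    if len(t) < 3:
        raise ParseError(f"{path}: need at least 3 samples")
    t = np.asarray(t)
    q = np.asarray(q)
    if abs(q[0] - q[-1]) > 1e-9 * max(1.0, abs(q[0])):
        raise ParseError(f"{path}: waveform must be periodic "
                         "(first == last sample)")
    return (t - t[0]) / (t[-1] - t[0]), q


def ostial_mean_flow(co_Lmin: float, dominance: str, side: str,
                     state: str = "rest",
                     coronary_fraction: float = CORONARY_FRACTION) -> float:
    """Mean ostial flow (m^3/s) for one coronary side."""
    if dominance not in DOMINANCE_SPLIT:
        raise ConfigError(f"unknown dominance {dominance!r}")
    if side not in ("left", "right"):
        raise ConfigError(f"unknown side {side!r}")
    if state not in ("rest", "hyperemia"):
        raise ConfigError(f"unknown physiologic state {state!r}")
    split = DOMINANCE_SPLIT[dominance][0 if side == "left" else 1]
    q = co_Lmin * LMIN_TO_M3S * coronary_fraction * split
    if state == "hyperemia":
        q *= HYPEREMIC_FLOW_FACTOR[side]
    return q


def build_inflow(co_Lmin: float, hr_bpm: float, dominance: str, side: str,
                 state: str = "rest",
                 shape: Optional[Sequence[Sequence[float]]] = None,
                 coronary_fraction: float = CORONARY_FRACTION,
                 n_samples: int = 401) -> InflowWaveform:
    """Build a scaled inlet waveform.

    ``shape`` is an optional user waveform as ``(t_frac, q_arbitrary)``
    sample arrays over one period (periodic); by default the canonical
    analytic left/right shape is used.  The shape is rescaled in time to
    period 60/HR and in amplitude so the trapezoid mean over the period
    equals the target ostial mean flow exactly.
    """
    if co_Lmin <= 0 or hr_bpm <= 0:
        raise DomainError("CO and HR must be > 0")
    target = ostial_mean_flow(co_Lmin, dominance, side, state,
                              coronary_fraction)
    if shape is None:
        from .synthetic import canonical_waveform
        frac, q = canonical_waveform(side, n_samples=n_samples)
    else:
        frac = np.asarray(shape[0], float)
        q = np.asarray(shape[1], float)
    T = 60.0 / hr_bpm
    mean = np.trapezoid(q, frac) / (frac[-1] - frac[0])
    if mean <= 0:
        raise DomainError("waveform shape must have positive mean")
    return InflowWaveform(t_s=frac * T, q_m3s=q * (target / mean),
                          side=side, physiologic_state=state)


# ---------------------------------------------------------------------------
# Windkessel outlets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindkesselOutlet:
    """2-element Windkessel at one terminal vessel (SI units)."""

    terminal_id: str
    Rp: float                    # Pa*s/m^3
    C: float = WINDKESSEL_C_SI   # m^3/Pa

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.C <= 0:
            raise DomainError("Rp and C must be > 0")


@dataclass
class PerfusionPlan:
    """Inputs of the terminal-resistance distribution rule."""

    Pmean_mmHg: float
    Qostial_Lmin: float
    terminal_radii_mm: Dict[str, float]
    hyperemic_resistance_factor: float = HYPEREMIC_RESISTANCE_FACTOR
    compliance_SI: float = WINDKESSEL_C_SI

    def __post_init__(self) -> None:
        if not self.terminal_radii_mm:
            raise DomainError("need at least one terminal")
        if any(r <= 0 for r in self.terminal_radii_mm.values()):
            raise DomainError("terminal radii must be > 0")
        if self.Pmean_mmHg <= 0 or self.Qostial_Lmin <= 0:
            raise DomainError("Pmean and Qostial must be > 0")


def distribute_resistances(plan: PerfusionPlan,
                           state: str = "rest") -> List[WindkesselOutlet]:
    """Distribute peripheral resistance over terminals by r^3.

    At rest ``Ri = (Pmean/Qostial) * (sum_j rj^3) / ri^3``; under
    hyperemia every Ri is additionally scaled by the hyperemic resistance
    factor (0.22 by default).
    """
    if state not in ("rest", "hyperemia"):
        raise ConfigError(f"unknown physiologic state {state!r}")
    p_si = plan.Pmean_mmHg * MMHG_TO_PA
    q_si = plan.Qostial_Lmin * LMIN_TO_M3S
    r3sum = sum(r ** 3 for r in plan.terminal_radii_mm.values())
    factor = plan.hyperemic_resistance_factor if state == "hyperemia" else 1.0
    return [WindkesselOutlet(terminal_id=tid,
                             Rp=factor * (p_si / q_si) * r3sum / r ** 3,
                             C=plan.compliance_SI)
            for tid, r in plan.terminal_radii_mm.items()]


def windkessel_update(P: float, Q: float, outlet: WindkesselOutlet,
                      dt: float) -> float:
    """One implicit-Euler step of ``C dP/dt = Q - P/Rp``; returns next P."""
    if dt <= 0:
        raise DomainError("dt must be > 0")
    return (outlet.C / dt * P + Q) / (outlet.C / dt + 1.0 / outlet.Rp)


def perfusion_plan_for(tree, patient: PatientRecord,
                       coronary_fraction: float = CORONARY_FRACTION,
                       compliance_SI: float = WINDKESSEL_C_SI) -> PerfusionPlan:
    """Assemble the resistance-distribution inputs for one case.

    Qostial in the resistance rule is the *resting* ostial flow derived
    from the patient's resistance-CO (cardiac output as it pertains to
    peripheral resistance); terminal radii come from the tree's gridded
    geometry (mean lumen radius of each terminal segment).
    """
    q_rest = ostial_mean_flow(patient.co_resistance_Lmin, patient.dominance,
                              patient.side, "rest", coronary_fraction)
    radii = {s.id: float(np.mean(s.radius_at(
        np.linspace(0.0, s.length_mm, 11))))
        for s in tree.segments.values() if s.terminal}
    return PerfusionPlan(Pmean_mmHg=patient.map_mmHg,
                         Qostial_Lmin=q_rest / LMIN_TO_M3S,
                         terminal_radii_mm=radii,
                         compliance_SI=compliance_SI)
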