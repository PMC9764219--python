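"""Diagnostic evaluation of FFR model variants.

Compares predicted FFR vectors against a reference (invasive or baseline
simulation) through the standard toolkit of categorical FFR validation:
confusion-matrix rates with exact (Clopper-Pearson) confidence
intervals, Pearson correlation, Bland-Altman agreement, and the ROC
curve with trapezoidal AUC and Youden-optimal threshold recovery
(reported as the interval between adjacent empirical cutpoints).
Ischemia is positive at FFR <= 0.80, ties classify as ischemic.

Also defines the streamlined model configurations: which clinical inputs
stay patient-specific and which are replaced by cohort-generalized
values (MAP 87.3 mmHg, HR 70.8 bpm, CO 4.5 L/min, hematocrit 39.2%,
ostial diameter 3.9 mm, distal location 30 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .boundary import PatientRecord
from .errors import ConfigError, DomainError

THRESHOLD = 0.80

#: Cohort-generalized clinical input values.
GENERALIZED = {
    "map_mmHg": 87.3,
    "hr_bpm": 70.8,
    "co_Lmin": 4.5,
    "hematocrit_pct": 39.2,
    "ostial_diameter_mm": 3.9,
    "distal_location_mm": 30.0,
}

_INPUT_NAMES = ("map", "hr", "hematocrit", "inlet_co", "resistance_co",
                "distal_location", "waveform", "ostial_diameter")


@dataclass
class ModelConfig:
    """Per-input patient-specific vs patient-generalized flags."""

    variant: str
    flags: Dict[str, str]
    generalized: Dict[str, float] = field(default_factory=lambda:
                                          dict(GENERALIZED))

    def apply(self, patient: PatientRecord) -> PatientRecord:
        """Return the patient record this configuration simulates."""
        g = self.generalized
        kw = {}
        if self.flags["map"] == "generalized":
            kw["map_mmHg"] = g["map_mmHg"]
        if self.flags["hr"] == "generalized":
            kw["hr_bpm"] = g["hr_bpm"]
        if self.flags["hematocrit"] == "generalized":
            kw["hematocrit_pct"] = g["hematocrit_pct"]
        if self.flags["distal_location"] == "generalized":
            kw["distal_location_mm"] = g["distal_location_mm"]
        kw["co_inlet_Lmin"] = (g["co_Lmin"]
                               if self.flags["inlet_co"] == "generalized"
                               else patient.co_Lmin)
        kw["co_resistance_Lmin"] = (g["co_Lmin"]
                                    if self.flags["resistance_co"]
                                    == "generalized"
                                    else patient.co_Lmin)
        return replace(patient, **kw)


def build_model_config(variant: str,
                       generalized: Optional[Dict[str, float]] = None
                       ) -> ModelConfig:
    """Assemble the baseline / semi-streamlined / streamlined variants.

    The baseline keeps every input patient-specific.  The
    semi-streamlined variant generalizes MAP, heart rate, hematocrit, the
    inlet-side cardiac output, the inflow waveform shape and the ostial
    diameter while keeping the resistance-side cardiac output, stenosis,
    tree and distal location patient-specific; the streamlined variant
    additionally generalizes the distal location (30 mm).
    """
    if variant == "baseline":
        flags = {name: "patient_specific" for name in _INPUT_NAMES}
    elif variant in ("semi-streamlined", "streamlined"):
        flags = {name: "generalized" for name in _INPUT_NAMES}
        flags["resistance_co"] = "patient_specific"
        flags["distal_location"] = ("generalized"
                                    if variant == "streamlined"
                                    else "patient_specific")
    else:
        raise ConfigError(f"unknown model variant {variant!r}")
    cfg = ModelConfig(variant=variant, flags=flags)
    if generalized:
        cfg.generalized.update(generalized)
    return cfg


# ---------------------------------------------------------------------------
# diagnostic statistics
# ---------------------------------------------------------------------------

def _clopper_pearson(x: int, n: int, level: float = 0.95
                     ) -> Tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    a = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(a / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - a / 2, x + 1, n - x))
    return (100.0 * lo, 100.0 * hi)


@dataclass
class DiagnosticReport:
    n: int
    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    ci: Dict[str, Tuple[float, float]]
    pearson_r: float
    bland_altman_mean: float
    bland_altman_sd: float
    limits_of_agreement: Tuple[float, float]
    auc: Optional[float]
    optimal_threshold: Optional[Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n": self.n, "TP": self.TP, "FP": self.FP, "TN": self.TN,
            "FN": self.FN, "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity, "PPV_pct": self.ppv,
            "NPV_pct": self.npv, "accuracy_pct": self.accuracy,
            "ci_pct": {k: list(v) for k, v in self.ci.items()},
            "pearson_r": self.pearson_r,
            "bland_altman_mean": self.bland_altman_mean,
            "bland_altman_sd": self.bland_altman_sd,
            "limits_of_agreement": list(self.limits_of_agreement),
            "auc": self.auc,
            "optimal_threshold": (list(self.optimal_threshold)
                                  if self.optimal_threshold else None),
        }


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def classify_and_score(predicted, reference,
                       threshold: float = THRESHOLD) -> DiagnosticReport:
    """Full diagnostic comparison of predicted vs reference FFR.

    Positive (ischemic) means reference <= threshold; predictions
    classify the same way.  Rates are percentages with exact
    Clopper-Pearson 95% CIs; Bland-Altman differences are predicted
    minus reference.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise DomainError("predicted and reference must be equal-length "
                          "1D vectors")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise DomainError("FFR vectors contain NaN/inf")

    pos = r <= threshold
    ppos = p <= threshold
    TP = int(np.sum(pos & ppos))
    FN = int(np.sum(pos & ~ppos))
    TN = int(np.sum(~pos & ~ppos))
    FP = int(np.sum(~pos & ppos))
    n = len(p)

    ci = {
        "sensitivity": _clopper_pearson(TP, TP + FN),
        "specificity": _clopper_pearson(TN, TN + FP),
        "ppv": _clopper_pearson(TP, TP + FP),
        "npv": _clopper_pearson(TN, TN + FN),
        "accuracy": _clopper_pearson(TP + TN, n),
    }

    if np.std(p) > 0 and np.std(r) > 0:
        pearson = float(stats.pearsonr(p, r).statistic)
    else:
        pearson = float("nan")
    d = p - r
    ba_mean = float(np.mean(d))
    ba_sd = float(np.std(d, ddof=1)) if n > 1 else 0.0

    auc = opt = None
    if 0 < np.sum(pos) < n:
        roc = roc_threshold_recovery(p, r, threshold)
        auc, opt = roc.auc, roc.optimal_interval

    return DiagnosticReport(
        n=n, TP=TP, FP=FP, TN=TN, FN=FN,
        sensitivity=_rate(TP, TP + FN), specificity=_rate(TN, TN + FP),
        ppv=_rate(TP, TP + FP), npv=_rate(TN, TN + FN),
        accuracy=_rate(TP + TN, n), ci=ci, pearson_r=pearson,
        bland_altman_mean=ba_mean, bland_altman_sd=ba_sd,
        limits_of_agreement=(ba_mean - 1.96 * ba_sd,
                             ba_mean + 1.96 * ba_sd),
        auc=auc, optimal_threshold=opt)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    cutpoints: np.ndarray
    optimal_interval: Tuple[float, float]
    youden: float


def roc_threshold_recovery(predicted, reference,
                           threshold: float = THRESHOLD) -> ROCResult:
    """Empirical ROC over all predicted-FFR cutpoints.

    A case is called positive at cutpoint c when predicted <= c.  AUC is
    the trapezoid integral of TPR over FPR; the optimal operating point
    maximizes the Youden index (TPR - FPR) and is reported as the
    interval between that cutpoint and the next larger predicted value
    (any threshold inside classifies the sample identically).
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    pos = r <= threshold
    npos = int(np.sum(pos))
    nneg = len(p) - npos
    if npos == 0 or nneg == 0:
        raise DomainError("ROC undefined: reference has a single class")

    cuts = np.unique(p)
    tpr = np.array([np.sum(pos & (p <= c)) / npos for c in cuts])
    fpr = np.array([np.sum(~pos & (p <= c)) / nneg for c in cuts])
    fpr_full = np.concatenate([[0.0], fpr])
    tpr_full = np.concatenate([[0.0], tpr])
    auc = float(np.trapezoid(tpr_full, fpr_full))

    youden = tpr - fpr
    best = int(np.argmax(youden))
    upper = cuts[best + 1] if best + 1 < len(cuts) else cuts[best]
    return ROCResult(auc=auc, fpr=fpr_full, tpr=tpr_full, cutpoints=cuts,
                     optimal_interval=(float(cuts[best]), float(upper)),
                     youden=float(youden[best]))
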