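"""Synthetic study material: Murray-law trees, canonical inflow shapes,
and patient cohorts with the clinical covariate structure of an
angiographic coronary-disease population.

The generator exists so that every stage of the pipeline (geometry ->
boundary conditions -> simulation -> FFR -> UQ -> evaluation) is testable
without any external data.  Trees are strictly bifurcating with radii
obeying Murray's law (r_parent^3 = r_major^3 + r_minor^3); cohort scalars
follow the published population moments (cardiac output 4.5 +/- 1.5
L/min, heart rate 70.8 +/- 13.7 bpm, systolic/diastolic pressure
125.8 +/- 25.8 / 67.1 +/- 12.7 mmHg, stenosis degree 55.6 +/- 17.2 %
truncated to [20, 95]); the canonical inflow shapes are analytic
two-phase (systolic/diastolic) stand-ins, diastolic-dominant for the left
coronary artery, since the measured waveform shapes are not published as
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .boundary import PatientRecord
from .errors import ConfigError, DomainError
from .geometry import CoronaryTree, StenosisSpec, VesselSegment

#: Fraction of the cardiac period spent in systole.
SYSTOLE_FRACTION = 0.35

MIN_RADIUS_MM = 0.5


@dataclass
class TreeRecipe:
    """Recipe for a Murray-law bifurcating tree."""

    depth: int = 3                  # generations of segments
    ostial_radius_mm: float = 1.95  # 3.9 mm ostial diameter
    murray_exponent: float = 3.0
    gamma: float = 0.85             # r_minor / r_major at bifurcations
    length_ratio: float = 18.0      # segment length / proximal radius
    length_jitter: float = 0.08     # lognormal-ish relative jitter
    side: str = "left"
    dominance: str = "right"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigError("gamma must be in (0, 1]")
        if self.ostial_radius_mm <= 0 or self.length_ratio <= 0:
            raise DomainError("radii and length ratio must be > 0")


def generate_tree(recipe: TreeRecipe = TreeRecipe(),
                  seed: int = 0) -> CoronaryTree:
    """Deterministic Murray-law tree for a given seed.

    Children with radius below the reconstruction limit (0.5 mm) are
    pruned in pairs (the parent becomes terminal) with a warning.
    """
    rng = np.random.default_rng(seed)
    segments = {}
    counter = [0]
    pruned = [0]

    def add(parent_id: Optional[str], radius: float, gen: int) -> None:
        sid = f"s{counter[0]}"
        counter[0] += 1
        jit = 1.0 + recipe.length_jitter * float(rng.standard_normal())
        length = recipe.length_ratio * radius * max(0.5, jit)
        is_term = gen >= recipe.depth
        if not is_term:
            r_major = radius / (1.0 + recipe.gamma
                                ** recipe.murray_exponent) ** (
                1.0 / recipe.murray_exponent)
            r_minor = recipe.gamma * r_major
            if r_minor < MIN_RADIUS_MM:
                is_term = True
                pruned[0] += 1
        segments[sid] = VesselSegment(
            id=sid, parent_id=parent_id, length_mm=length,
            radius_mm=(radius, radius), terminal=is_term, side=recipe.side)
        if not is_term:
            add(sid, r_major, gen + 1)
            add(sid, r_minor, gen + 1)

    add(None, recipe.ostial_radius_mm, 1)
    if pruned[0]:
        warnings.warn(f"pruned {pruned[0]} bifurcation(s) below "
                      f"{MIN_RADIUS_MM} mm radius", stacklevel=2)
    return CoronaryTree(segments=segments, dominance=recipe.dominance,
                        ostial_diameter_mm=2.0 * recipe.ostial_radius_mm)


def canonical_waveform(side: str = "left",
                       n_samples: int = 401
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic unit-mean coronary inflow shape over one period.

    Returns ``(t_frac, q)`` with t_frac in [0, 1], periodic samples
    (first == last) and exact unit trapezoid mean.  The left shape is
    diastolic-dominant (most of the flow-time integral falls after
    systole, reflecting systolic myocardial compression of the left
    coronary bed); the right shape carries comparable systolic and
    diastolic flow.
    """
    if side not in ("left", "right"):
        raise ConfigError(f"unknown side {side!r}")
    t = np.linspace(0.0, 1.0, n_samples)

    def pulse(center, width):
        y = np.zeros_like(t)
        m = np.abs(t - center) < width / 2.0
        y[m] = np.sin(np.pi * (t[m] - center + width / 2.0) / width) ** 2
        return y

    if side == "left":
        base, ws, wd = 0.25, 0.7, 2.2
    else:
        base, ws, wd = 0.30, 1.3, 1.2
    q = base + ws * pulse(0.20, 0.30) + wd * pulse(0.665, 0.55)
    q[-1] = q[0]
    mean = np.trapezoid(q, t)  # period is 1
    return t, q / mean


@dataclass
class CohortRecipe:
    """Sampling recipe for a synthetic patient cohort."""

    n_patients: int = 10
    seed: int = 0
    tree: TreeRecipe = field(default_factory=TreeRecipe)
    co_mean_sd: Tuple[float, float] = (4.5, 1.5)         # L/min
    hr_mean_sd: Tuple[float, float] = (70.8, 13.7)       # bpm
    sbp_mean_sd: Tuple[float, float] = (125.8, 25.8)     # mmHg
    dbp_mean_sd: Tuple[float, float] = (67.1, 12.7)      # mmHg
    hct_mean_sd: Tuple[float, float] = (39.2, 4.0)       # %
    degree_mean_sd: Tuple[float, float] = (55.6, 17.2)   # %
    degree_bounds: Tuple[float, float] = (20.0, 95.0)
    stenosis_len_mean_sd: Tuple[float, float] = (10.0, 3.0)  # mm
    stenosis_len_bounds: Tuple[float, float] = (3.0, 20.0)
    distal_bounds: Tuple[float, float] = (5.0, 65.0)     # mm
    dominance_probs: Tuple[float, float, float] = (0.796, 0.122, 0.082)
    p_left_side: float = 0.735

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for mu, sd in (self.co_mean_sd, self.hr_mean_sd, self.sbp_mean_sd,
                       self.dbp_mean_sd, self.hct_mean_sd,
                       self.degree_mean_sd, self.stenosis_len_mean_sd):
            if sd <= 0 or mu <= 0:
                raise ConfigError("distribution parameters must be > 0")


@dataclass
class CohortCase:
    case_id: str
    tree: CoronaryTree
    patient: PatientRecord

    @property
    def stenosis(self) -> StenosisSpec:
        return self.tree.stenoses[0]


def _truncated_normal(rng, mu, sd, lo, hi) -> float:
    for _ in range(1000):
        x = mu + sd * float(rng.standard_normal())
        if lo <= x <= hi:
            return x
    return float(np.clip(mu, lo, hi))


def generate_cohort(recipe: CohortRecipe = CohortRecipe()
                    ) -> List[CohortCase]:
    """Sample a deterministic synthetic cohort.

    Each case gets a Murray tree, one focal mid-segment stenosis on the
    root (non-terminal when depth > 1) branch, and clinical scalars drawn
    from the recipe distributions.  MAP is derived from sampled
    systolic/diastolic pressure as (SBP + 2 DBP)/3.  The distal sampling
    location is uniform on the recipe bounds, clamped to the arc length
    actually reachable downstream in the generated tree.
    """
    rng = np.random.default_rng(recipe.seed)
    from .ffr import downstream_reach  # local import to avoid cycle

    cases = []
    for i in range(recipe.n_patients):
        dom = ("right", "left", "co-dominant")[
            int(rng.choice(3, p=np.asarray(recipe.dominance_probs)
                           / sum(recipe.dominance_probs)))]
        side = "left" if rng.random() < recipe.p_left_side else "right"
        tree_recipe = replace(recipe.tree, side=side, dominance=dom)
        tree = generate_tree(tree_recipe, seed=int(rng.integers(2 ** 31)))

        # lesion host: the major child of the root when the tree is deep
        # enough (a proximal main-branch lesion distal to the first
        # bifurcation, so part of the ostial flow bypasses it), else the
        # root itself
        root_children = tree.children_of(tree.root.id)
        if root_children:
            host = max(root_children, key=lambda s: s.proximal_radius_mm)
        else:
            host = tree.root
        degree = _truncated_normal(rng, *recipe.degree_mean_sd,
                                   *recipe.degree_bounds)
        ls_hi = min(recipe.stenosis_len_bounds[1], 0.6 * host.length_mm)
        ls = _truncated_normal(rng, *recipe.stenosis_len_mean_sd,
                               recipe.stenosis_len_bounds[0], ls_hi)
        pos = 0.5 * host.length_mm - 0.5 * ls
        ru = float(host.radius_at(pos + 0.5 * ls))
        sten = StenosisSpec(segment_id=host.id, position_mm=pos,
                            length_mm=ls, ru_mm=ru, degree_pct=degree)
        tree.stenoses.append(sten)
        tree.validate()

        sbp = _truncated_normal(rng, *recipe.sbp_mean_sd, 70.0, 220.0)
        dbp = _truncated_normal(rng, *recipe.dbp_mean_sd, 35.0,
                                max(40.0, sbp - 10.0))
        mapp = (sbp + 2.0 * dbp) / 3.0
        co = _truncated_normal(rng, *recipe.co_mean_sd, 1.5, 10.0)
        hr = _truncated_normal(rng, *recipe.hr_mean_sd, 40.0, 130.0)
        hct = _truncated_normal(rng, *recipe.hct_mean_sd, 20.0, 60.0)
        distal = recipe.distal_bounds[0] + float(rng.random()) * (
            recipe.distal_bounds[1] - recipe.distal_bounds[0])
        reach = downstream_reach(tree, sten)
        distal = min(distal, reach - 1.0)

        patient = PatientRecord(map_mmHg=mapp, co_Lmin=co, hr_bpm=hr,
                                hematocrit_pct=hct, dominance=dom, side=side,
                                distal_location_mm=distal)
        cases.append(CohortCase(case_id=f"case{i:03d}", tree=tree,
                                patient=patient))
    return cases
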