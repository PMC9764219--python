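"""Coronary tree geometry: segments, stenoses, validation, I/O, gridding.

A coronary tree is a rooted, strictly bifurcating network of 1D vessel
segments.  Each segment carries a radius profile, either a linear taper
between a proximal and a distal radius or a table of sampled centerline
points (arc length, radius) that is linearly interpolated.  Focal stenoses
are annotations on a host segment: they do not narrow the meshed lumen but
are realized by the solver as zero-length pressure-loss interfaces.

The canonical storage format is a versioned JSON document (``tree-json``);
a flat centerline CSV (segment_id, parent_id, arclength_mm, radius_mm) is
accepted as an import dialect and converted on load.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (ConsistencyError, DiscretizationError, DomainError,
                     ParseError, TopologyError)

TREE_JSON_VERSION = 1

#: Default empirical stenosis loss coefficients ("turbulent" and inertial).
KT_DEFAULT = 1.52
KU_DEFAULT = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """One 1D vessel segment.

    Radius profile: either ``radius_mm=(proximal, distal)`` with linear
    taper, or ``centerline`` as a sequence of ``(s_mm, r_mm)`` samples with
    0 <= s <= length_mm.
    """

    id: str
    parent_id: Optional[str]
    length_mm: float
    radius_mm: Optional[Tuple[float, float]] = None
    centerline: Optional[List[Tuple[float, float]]] = None
    terminal: bool = False
    side: str = "left"

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise DomainError(f"segment {self.id!r}: length must be > 0")
        if (self.radius_mm is None) == (self.centerline is None):
            raise ParseError(
                f"segment {self.id!r}: exactly one of radius_mm / centerline "
                "must be given")
        if self.radius_mm is not None:
            rp, rd = self.radius_mm
            if rp <= 0 or rd <= 0:
                raise DomainError(f"segment {self.id!r}: radii must be > 0")
        else:
            pts = sorted((float(s), float(r)) for s, r in self.centerline)
            if any(r <= 0 for _, r in pts):
                raise DomainError(f"segment {self.id!r}: radii must be > 0")
            if len(pts) < 2:
                raise ParseError(
                    f"segment {self.id!r}: centerline needs >= 2 points")
            self.centerline = pts

    def radius_at(self, s_mm) -> np.ndarray:
        """Lumen radius (mm) at arc length(s) ``s_mm`` from the proximal end."""
        s = np.atleast_1d(np.asarray(s_mm, dtype=float))
        if self.radius_mm is not None:
            rp, rd = self.radius_mm
            r = rp + (rd - rp) * np.clip(s / self.length_mm, 0.0, 1.0)
        else:
            xs = np.array([p[0] for p in self.centerline])
            rs = np.array([p[1] for p in self.centerline])
            r = np.interp(s, xs, rs)
        return r if np.ndim(s_mm) else float(r[0])

    @property
    def proximal_radius_mm(self) -> float:
        return float(self.radius_at(0.0))

    @property
    def distal_radius_mm(self) -> float:
        return float(self.radius_at(self.length_mm))


def stenosis_geometry(degree_pct: Optional[float] = None,
                      rs_mm: Optional[float] = None,
                      ru_mm: Optional[float] = None,
                      rtol: float = 1e-6) -> Tuple[float, float, float]:
    """Complete / check the (degree, rs, ru) triple.

    Stenosis degree is the percent radius reduction,
    ``degree = (1 - rs/ru) * 100``.  Given any two of the three quantities
    the third is computed; if all three are given they must agree to
    relative tolerance ``rtol``.

    Returns ``(degree_pct, rs_mm, ru_mm)``.
    """
    given = [v is not None for v in (degree_pct, rs_mm, ru_mm)]
    if sum(given) < 2:
        raise ConsistencyError(
            "at least two of {degree, rs, ru} must be provided")
    if degree_pct is not None and not (0.0 <= degree_pct < 100.0):
        raise DomainError(f"stenosis degree {degree_pct} outside [0, 100)")
    if rs_mm is not None and rs_mm <= 0:
        raise DomainError("rs must be > 0")
    if ru_mm is not None and ru_mm <= 0:
        raise DomainError("ru must be > 0")

    if degree_pct is None:
        if rs_mm > ru_mm:
            raise DomainError("rs must be <= ru")
        degree_pct = (1.0 - rs_mm / ru_mm) * 100.0
    elif rs_mm is None:
        rs_mm = ru_mm * (1.0 - degree_pct / 100.0)
    elif ru_mm is None:
        ru_mm = rs_mm / (1.0 - degree_pct / 100.0)
    else:
        implied = (1.0 - rs_mm / ru_mm) * 100.0
        scale = max(abs(degree_pct), abs(implied), 1.0)
        if abs(implied - degree_pct) > rtol * scale:
            raise ConsistencyError(
                f"degree {degree_pct}% inconsistent with rs/ru "
                f"(implies {implied:.6f}%)")
    return float(degree_pct), float(rs_mm), float(ru_mm)


@dataclass
class StenosisSpec:
    """A focal stenosis on a host segment.

    ``position_mm`` is the arc length of the proximal end of the lesion
    from the proximal end of the host segment; ``length_mm`` (Ls) is the
    lesion length.  ``rs_mm`` is the minimal luminal radius and ``ru_mm``
    the unstenosed reference radius; ``degree_pct`` the percent radius
    reduction.  Any missing member of the (degree, rs, ru) triple is
    completed on construction.
    """

    segment_id: str
    position_mm: float
    length_mm: float
    rs_mm: Optional[float] = None
    ru_mm: Optional[float] = None
    degree_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise DomainError("stenosis length Ls must be > 0")
        if self.position_mm < 0:
            raise DomainError("stenosis position must be >= 0")
        self.degree_pct, self.rs_mm, self.ru_mm = stenosis_geometry(
            self.degree_pct, self.rs_mm, self.ru_mm)
        if not self.rs_mm <= self.ru_mm:
            raise DomainError("rs must be <= ru")

    # derived diameters / areas (mm, mm^2)
    @property
    def Du_mm(self) -> float:
        return 2.0 * self.ru_mm

    @property
    def Ds_mm(self) -> float:
        return 2.0 * self.rs_mm

    @property
    def Au_mm2(self) -> float:
        return math.pi * self.ru_mm ** 2

    @property
    def As_mm2(self) -> float:
        return math.pi * self.rs_mm ** 2

    @property
    def distal_end_mm(self) -> float:
        return self.position_mm + self.length_mm

    @property
    def center_mm(self) -> float:
        return self.position_mm + 0.5 * self.length_mm


@dataclass(frozen=True)
class StenosisCoefficients:
    """Empirical loss coefficients of the stenosis pressure-drop element."""

    Kv: float
    Kt: float = KT_DEFAULT
    Ku: float = KU_DEFAULT

    def __post_init__(self) -> None:
        if self.Kv <= 0:
            raise DomainError("Kv must be > 0")


def stenosis_coefficients(spec: StenosisSpec,
                          Kt: float = KT_DEFAULT,
                          Ku: float = KU_DEFAULT) -> StenosisCoefficients:
    """Viscous/turbulent/inertial coefficients for a focal stenosis.

    ``Kv = 32 (0.83 Ls + 1.64 Ds) (Au/As)^2 / Du`` with all lengths in the
    same unit (mm here, the ratio is dimensionless); Kt and Ku are
    empirical constants (1.52 and 1.2 by default).
    """
    area_ratio = spec.Au_mm2 / spec.As_mm2
    kv = 32.0 * (0.83 * spec.length_mm + 1.64 * spec.Ds_mm) \
        * area_ratio ** 2 / spec.Du_mm
    return StenosisCoefficients(Kv=kv, Kt=Kt, Ku=Ku)


@dataclass
class CoronaryTree:
    """A rooted, strictly bifurcating coronary tree with stenoses."""

    segments: Dict[str, VesselSegment]
    stenoses: List[StenosisSpec] = field(default_factory=list)
    ostial_diameter_mm: Optional[float] = None
    dominance: str = "right"

    def __post_init__(self) -> None:
        self.validate()
        if self.ostial_diameter_mm is None:
            self.ostial_diameter_mm = 2.0 * self.root.proximal_radius_mm

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> VesselSegment:
        return self.segments[self._root_id]

    def children_of(self, seg_id: str) -> List[VesselSegment]:
        return [s for s in self.segments.values() if s.parent_id == seg_id]

    @property
    def terminals(self) -> List[VesselSegment]:
        return [s for s in self.segments.values() if s.terminal]

    def validate(self) -> None:
        if not self.segments:
            raise TopologyError("tree has no segments")
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(
                f"tree must have exactly one root (ostium), found "
                f"{len(roots)}: {[s.id for s in roots]}")
        self._root_id = roots[0].id
        for s in self.segments.values():
            if s.parent_id is not None and s.parent_id not in self.segments:
                raise TopologyError(
                    f"segment {s.id!r} references missing parent "
                    f"{s.parent_id!r}")
        # reachability (cycles / orphans)
        seen = set()
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise TopologyError(f"cycle detected at segment {sid!r}")
            seen.add(sid)
            stack.extend(c.id for c in self.children_of(sid))
        if seen != set(self.segments):
            raise TopologyError(
                f"segments not reachable from root: {set(self.segments) - seen}")
        # strictly bifurcating
        for s in self.segments.values():
            nc = len(self.children_of(s.id))
            if s.terminal and nc != 0:
                raise TopologyError(
                    f"terminal segment {s.id!r} has {nc} children")
            if not s.terminal and nc != 2:
                raise TopologyError(
                    f"non-terminal segment {s.id!r} has {nc} children "
                    "(tree must be strictly bifurcating)")
        for st in self.stenoses:
            if st.segment_id not in self.segments:
                raise TopologyError(
                    f"stenosis references missing segment {st.segment_id!r}")
            host = self.segments[st.segment_id]
            if st.distal_end_mm > host.length_mm:
                raise TopologyError(
                    f"stenosis on {st.segment_id!r} extends beyond segment "
                    f"({st.distal_end_mm:.2f} > {host.length_mm:.2f} mm)")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        segs = []
        for s in self.segments.values():
            d = {"id": s.id, "parent": s.parent_id,
                 "length_mm": s.length_mm, "terminal": s.terminal,
                 "side": s.side}
            if s.radius_mm is not None:
                d["radius_mm"] = list(s.radius_mm)
            else:
                d["centerline"] = [list(p) for p in s.centerline]
            segs.append(d)
        stens = [{"segment": st.segment_id, "position_mm": st.position_mm,
                  "length_mm": st.length_mm, "rs_mm": st.rs_mm,
                  "degree_pct": st.degree_pct}
                 for st in self.stenoses]
        return {"version": TREE_JSON_VERSION, "dominance": self.dominance,
                "ostial_diameter_mm": self.ostial_diameter_mm,
                "segments": segs, "stenoses": stens}

    @classmethod
    def from_dict(cls, doc: dict) -> "CoronaryTree":
        try:
            segs = {}
            for d in doc["segments"]:
                seg = VesselSegment(
                    id=str(d["id"]),
                    parent_id=None if d.get("parent") is None else str(d["parent"]),
                    length_mm=float(d["length_mm"]),
                    radius_mm=tuple(d["radius_mm"]) if "radius_mm" in d else None,
                    centerline=[tuple(p) for p in d["centerline"]]
                    if "centerline" in d else None,
                    terminal=bool(d.get("terminal", False)),
                    side=d.get("side", "left"))
                if seg.id in segs:
                    raise ParseError(f"duplicate segment id {seg.id!r}")
                segs[seg.id] = seg
            stens = [StenosisSpec(segment_id=str(d["segment"]),
                                  position_mm=float(d["position_mm"]),
                                  length_mm=float(d["length_mm"]),
                                  rs_mm=d.get("rs_mm"),
                                  ru_mm=d.get("ru_mm"),
                                  degree_pct=d.get("degree_pct"))
                     for d in doc.get("stenoses", [])]
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed tree document: {exc!r}") from exc
        return cls(segments=segs, stenoses=stens,
                   ostial_diameter_mm=doc.get("ostial_diameter_mm"),
                   dominance=doc.get("dominance", "right"))


def save_tree(tree: CoronaryTree, path) -> None:
    """Write a tree-json document."""
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1)


def load_tree(path, format: str = "tree-json") -> CoronaryTree:
    """Load a coronary tree from ``tree-json`` or ``centerline-csv``.

    The JSON round trip (save_tree -> load_tree) is lossless; the CSV
    dialect is converted to centerline-sampled segments on load.
    """
    if format == "tree-json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        return CoronaryTree.from_dict(doc)
    if format == "centerline-csv":
        return _load_centerline_csv(path)
    raise ParseError(f"unknown tree format {format!r}")


def _load_centerline_csv(path) -> CoronaryTree:
    rows: Dict[str, List[Tuple[float, float]]] = {}
    parents: Dict[str, Optional[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"segment_id", "parent_id", "arclength_mm", "radius_mm"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: centerline CSV must have columns {sorted(need)}")
        for i, row in enumerate(reader):
            try:
                sid = row["segment_id"].strip()
                pid = row["parent_id"].strip() or None
                s = float(row["arclength_mm"])
                r = float(row["radius_mm"])
            except (AttributeError, ValueError) as exc:
                raise ParseError(f"{path}: bad record on data row {i + 1}: "
                                 f"{row!r}") from exc
            rows.setdefault(sid, []).append((s, r))
            parents.setdefault(sid, pid)
    segs = {}
    has_children = {p for p in parents.values() if p is not None}
    for sid, pts in rows.items():
        pts = sorted(pts)
        segs[sid] = VesselSegment(
            id=sid, parent_id=parents[sid], length_mm=pts[-1][0],
            centerline=pts, terminal=sid not in has_children)
    return CoronaryTree(segments=segs)


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

@dataclass
class GriddedSegment:
    """Uniform 1D grid on one vessel segment (mm units)."""

    id: str
    parent_id: Optional[str]
    terminal: bool
    x_mm: np.ndarray        # node arc lengths, x[0]=0, x[-1]=L
    r_mm: np.ndarray        # lumen radius at nodes

    @property
    def n(self) -> int:
        return len(self.x_mm)

    @property
    def dx_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])

    @property
    def A0_mm2(self) -> np.ndarray:
        return np.pi * self.r_mm ** 2


@dataclass
class GriddedTree:
    """Discretized coronary tree ready for the 1D solver."""

    tree: CoronaryTree
    segments: Dict[str, GriddedSegment]
    dx_um: float


def discretize(tree: CoronaryTree, dx_um: float = 500.0) -> GriddedTree:
    """Grid every segment with uniform spacing <= ``dx_um``.

    The node count per segment is ``ceil(L/dx) + 1`` so end nodes fall
    exactly on the segment boundaries and the actual spacing shrinks to
    ``L / ceil(L/dx)``.
    """
    if dx_um <= 0:
        raise DiscretizationError("dx must be > 0")
    dx_mm = dx_um * 1e-3
    gsegs = {}
    for s in tree.segments.values():
        if s.length_mm < 2.0 * dx_mm:
            raise DiscretizationError(
                f"segment {s.id!r} ({s.length_mm} mm) shorter than 2*dx "
                f"({2 * dx_mm} mm); use a smaller dx "
                f"(<= {s.length_mm / 2 * 1e3:.0f} um)")
        ncell = math.ceil(s.length_mm / dx_mm - 1e-12)
        x = np.linspace(0.0, s.length_mm, ncell + 1)
        gsegs[s.id] = GriddedSegment(
            id=s.id, parent_id=s.parent_id, terminal=s.terminal,
            x_mm=x, r_mm=np.asarray(s.radius_at(x), dtype=float))
    return GriddedTree(tree=tree, segments=gsegs, dx_um=dx_um)


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def single_vessel(length_mm: float = 50.0, radius_mm: float = 1.95,
                  side: str = "left", stenosis: Optional[StenosisSpec] = None,
                  dominance: str = "right") -> CoronaryTree:
    """One straight terminal vessel (optionally with a focal stenosis)."""
    seg = VesselSegment(id="v0", parent_id=None, length_mm=length_mm,
                        radius_mm=(radius_mm, radius_mm), terminal=True,
                        side=side)
    return CoronaryTree(segments={"v0": seg},
                        stenoses=[stenosis] if stenosis else [],
                        dominance=dominance)
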