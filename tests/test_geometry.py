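import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coroflow as cf
from coroflow.errors import (ConsistencyError, DiscretizationError,
                             DomainError, ParseError, TopologyError)


# ---------------------------------------------------------------------------
# tree I/O and topology
# ---------------------------------------------------------------------------

def test_single_segment_roundtrip(tmp_path, single_tree):
    path = tmp_path / "t.json"
    cf.save_tree(single_tree, path)
    back = cf.load_tree(path)
    assert len(back.segments) == 1
    assert back.stenoses == []
    assert back.to_dict() == single_tree.to_dict()


def test_seven_segment_tree_counts(tmp_path):
    tree = cf.generate_tree(cf.TreeRecipe(depth=3, gamma=1.0), seed=1)
    assert len(tree.segments) == 7
    assert len(tree.terminals) == 4
    path = tmp_path / "t.json"
    cf.save_tree(tree, path)
    assert cf.load_tree(path).to_dict() == tree.to_dict()


def test_missing_parent_is_topology_error(tmp_path):
    doc = {"version": 1, "segments": [
        {"id": "a", "parent": None, "length_mm": 10, "radius_mm": [1, 1],
         "terminal": False},
        {"id": "b", "parent": "ghost", "length_mm": 10, "radius_mm": [1, 1],
         "terminal": True}]}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(TopologyError, match="ghost"):
        cf.load_tree(path)


def test_multiple_roots_rejected():
    segs = {
        "a": cf.VesselSegment("a", None, 10, radius_mm=(1, 1), terminal=True),
        "b": cf.VesselSegment("b", None, 10, radius_mm=(1, 1), terminal=True),
    }
    with pytest.raises(TopologyError, match="root"):
        cf.CoronaryTree(segments=segs)


def test_non_bifurcating_rejected():
    segs = {
        "a": cf.VesselSegment("a", None, 10, radius_mm=(1, 1)),
        "b": cf.VesselSegment("b", "a", 10, radius_mm=(1, 1), terminal=True),
    }
    with pytest.raises(TopologyError, match="bifurcating"):
        cf.CoronaryTree(segments=segs)


def test_malformed_json_names_offender(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("{not json")
    with pytest.raises(ParseError):
        cf.load_tree(path)


def test_centerline_csv_import(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(
        "segment_id,parent_id,arclength_mm,radius_mm\n"
        "r,,0,2.0\nr,,15,1.8\n"
        "a,r,0,1.5\na,r,12,1.4\n"
        "b,r,0,1.2\nb,r,10,1.1\n")
    tree = cf.load_tree(path, "centerline-csv")
    assert len(tree.segments) == 3
    assert tree.root.id == "r"
    assert {t.id for t in tree.terminals} == {"a", "b"}
    assert tree.segments["r"].radius_at(7.5) == pytest.approx(1.9)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_node_counts(single_tree):
    g = cf.discretize(single_tree, 500.0)
    seg = g.segments["v0"]
    assert seg.n == 101
    assert np.allclose(seg.A0_mm2, math.pi * 1.95 ** 2)


def test_discretize_ceiling_rule():
    tree = cf.single_vessel(length_mm=10.3, radius_mm=1.0)
    seg = cf.discretize(tree, 500.0).segments["v0"]
    assert seg.n == 22
    assert seg.dx_mm == pytest.approx(10.3 / 21)
    assert seg.x_mm[0] == 0.0 and seg.x_mm[-1] == pytest.approx(10.3)


def test_discretize_too_short_errors():
    tree = cf.single_vessel(length_mm=0.8, radius_mm=1.0)
    with pytest.raises(DiscretizationError, match="smaller dx"):
        cf.discretize(tree, 500.0)


@given(L=st.floats(2.0, 120.0), dx=st.floats(100.0, 900.0))
@settings(deadline=None, derandomize=True, max_examples=40)
def test_discretize_preserves_length(L, dx):
    tree = cf.single_vessel(length_mm=L, radius_mm=1.5)
    seg = cf.discretize(tree, dx).segments["v0"]
    assert seg.x_mm[-1] == pytest.approx(L, rel=1e-9)
    assert seg.dx_mm <= dx * 1e-3 + 1e-12


# ---------------------------------------------------------------------------
# stenosis geometry (degree / rs / ru closure)
# ---------------------------------------------------------------------------

def test_degree_from_radii():
    deg, rs, ru = cf.stenosis_geometry(rs_mm=1.0, ru_mm=2.0)
    assert deg == pytest.approx(50.0)


def test_ru_from_degree_and_rs():
    deg, rs, ru = cf.stenosis_geometry(degree_pct=55.6, rs_mm=0.7)
    assert ru == pytest.approx(0.7 / 0.444, rel=1e-9)
    # round trip
    deg2, _, _ = cf.stenosis_geometry(rs_mm=rs, ru_mm=ru)
    assert deg2 == pytest.approx(55.6, rel=1e-9)


def test_zero_degree_identity():
    deg, rs, ru = cf.stenosis_geometry(degree_pct=0.0, ru_mm=1.5)
    assert rs == pytest.approx(1.5)
    spec = cf.StenosisSpec("v0", 5, 5, ru_mm=1.5, degree_pct=0.0)
    assert spec.As_mm2 == pytest.approx(spec.Au_mm2)


def test_inconsistent_triple_rejected():
    with pytest.raises(ConsistencyError):
        cf.stenosis_geometry(degree_pct=50.0, rs_mm=1.0, ru_mm=3.0)
    with pytest.raises(DomainError):
        cf.stenosis_geometry(degree_pct=120.0, rs_mm=1.0)


@given(ru=st.floats(0.6, 4.0), frac=st.floats(0.05, 0.95))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_degree_roundtrip_property(ru, frac):
    rs = ru * frac
    deg, _, _ = cf.stenosis_geometry(rs_mm=rs, ru_mm=ru)
    _, _, ru_back = cf.stenosis_geometry(degree_pct=deg, rs_mm=rs)
    assert ru_back == pytest.approx(ru, rel=1e-9)


# ---------------------------------------------------------------------------
# stenosis loss coefficients
# ---------------------------------------------------------------------------

def test_kv_worked_examples():
    # Au/As = 4  <->  Ds = Du/2
    spec = cf.StenosisSpec("v0", 0, 10.0, ru_mm=1.5, rs_mm=0.75)
    co = cf.stenosis_coefficients(spec)
    assert co.Kv == pytest.approx(32 * (0.83 * 10 + 1.64 * 1.5) * 16 / 3,
                                  rel=1e-12)
    assert co.Kv == pytest.approx(1836.5, rel=1e-3)
    spec0 = cf.StenosisSpec("v0", 0, 5.0, ru_mm=1.5, degree_pct=0.0)
    co0 = cf.stenosis_coefficients(spec0)
    assert co0.Kv == pytest.approx(32 * (0.83 * 5 + 1.64 * 3.0) / 3.0,
                                   rel=1e-12)
    assert co0.Kv == pytest.approx(96.75, abs=0.05)
    assert co.Kt == 1.52 and co.Ku == 1.2


def test_kv_monotone_in_length_and_degree():
    degs = [10.0, 30.0, 50.0, 70.0, 90.0]
    lens = [2.0, 5.0, 10.0, 15.0]
    for ls in lens:
        kvs = [cf.stenosis_coefficients(
            cf.StenosisSpec("v0", 0, ls, ru_mm=1.8, degree_pct=d)).Kv
            for d in degs]
        assert np.all(np.diff(kvs) > 0)
    for d in degs:
        kvs = [cf.stenosis_coefficients(
            cf.StenosisSpec("v0", 0, ls, ru_mm=1.8, degree_pct=d)).Kv
            for ls in lens]
        assert np.all(np.diff(kvs) > 0)


def test_stenosis_beyond_segment_rejected():
    st_ = cf.StenosisSpec("v0", position_mm=45.0, length_mm=10.0,
                          ru_mm=1.95, degree_pct=50.0)
    with pytest.raises(TopologyError, match="beyond"):
        cf.single_vessel(length_mm=50.0, stenosis=st_)
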