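import numpy as np
import pytest

from hullmass import (
    ExpansionPolicy,
    ScalingModel,
    build_model_set,
    expand_segment,
    hull_all,
    load_factor_table,
)
from hullmass.expansion import SELLERS_FACTOR, ExpansionError
from hullmass.hulling import SegmentHull
from hullmass.skeleton_io import SegmentClass, SegmentMesh, SkeletonManifest
from hullmass.synthetic_data import box_vertices, default_body_plan, generate_skeleton


def _hull(cls="torso", volume=1.0, side="midline"):
    return SegmentHull(
        segment_class=SegmentClass(cls),
        side=side,
        hull_vertices=box_vertices((0, 0, 0), (1, 1, 1)),
        hull_volume=volume,
        hull_centroid=np.zeros(3),
    )


def test_sellers21_uniform_expansion():
    policy = ExpansionPolicy(model_set_name="sellers21")
    out = expand_segment(_hull(volume=1.0), None, policy)
    assert out.point_volume == pytest.approx(1.21)
    assert SELLERS_FACTOR == 1.21  # minimal hulls underestimate mass by ~21%


def test_allometric_exponent_one_reduces_to_isometric():
    k = 1.7
    iso = ScalingModel("torso", "NAS", "isometric", k=k)
    allo = ScalingModel("torso", "NAS", "allometric", a=float(np.log10(k)), b=1.0)
    policy = ExpansionPolicy(model_set_name="NAS_allometric")
    v = 2.345
    assert expand_segment(_hull(volume=v), allo, policy).point_volume == pytest.approx(
        expand_segment(_hull(volume=v), iso, policy).point_volume, rel=1e-12
    )
    assert allo.predict(v) == pytest.approx(k * v, rel=1e-12)


def test_neck_floor_rule_sets_minimum_and_flag():
    # model predicting 0.8 m^3 from a 1.0 m^3 neck hull: hull is a hard floor
    model = ScalingModel("neck", "bird", "isometric", k=0.8)
    policy = ExpansionPolicy(model_set_name="bird_isometric")
    out = expand_segment(_hull(cls="neck", volume=1.0), model, policy)
    assert out.point_volume == pytest.approx(1.0)
    assert out.floored
    assert out.lower_volume >= 1.0


def test_mppe_bounds_direct_arithmetic():
    model = ScalingModel("torso", "NAS", "isometric", k=1.5, mppe=0.10)
    policy = ExpansionPolicy(model_set_name="NAS_isometric")
    out = expand_segment(_hull(volume=2.0), model, policy)
    assert out.point_volume == pytest.approx(3.0)
    assert out.lower_volume == pytest.approx(2.7)
    assert out.upper_volume == pytest.approx(3.3)


def test_exempt_classes_keep_hull_volume_with_zero_mppe():
    policy = ExpansionPolicy(model_set_name="NAS_isometric")
    for cls in ("ornament", "osteoderm", "sail"):
        out = expand_segment(_hull(cls=cls, volume=0.4), None, policy)
        assert out.point_volume == pytest.approx(0.4)
        assert out.lower_volume == out.upper_volume == out.point_volume


def _mini_manifest(classes, tail_in_torso=False):
    segs = [
        SegmentMesh(SegmentClass(cls), "midline", box_vertices((i * 3.0, 0, 0), (1, 1, 1)))
        for i, cls in enumerate(classes)
    ]
    return SkeletonManifest(
        taxon="taxonX",
        segments=segs,
        acetabulum=np.zeros(3),
        glenoid=np.array([1.0, 0.0, 0.2]),
        tail_in_torso=tail_in_torso,
    )


def _table():
    return [
        ScalingModel("torso", "bird", "isometric", k=1.3),
        ScalingModel("torso", "NAS", "isometric", k=1.6),
        ScalingModel("tail", "NAS", "isometric", k=1.5),
        ScalingModel("tail", "bird", "isometric", k=9.9),  # must never be picked
        ScalingModel("neck", "NAS", "isometric", k=1.6),
        ScalingModel("neck", "bird", "isometric", k=1.2),
    ]


def test_bird_model_set_uses_nas_tail_factors():
    manifest = _mini_manifest(["torso", "tail"])
    hulls = hull_all(manifest)
    policy = ExpansionPolicy(model_set_name="bird_isometric")
    out = build_model_set(hulls, policy, _table(), manifest)
    by_class = {o.segment_class: o for o in out}
    assert by_class["torso"].point_volume == pytest.approx(1.3)
    assert by_class["tail"].point_volume == pytest.approx(1.5)  # NAS k, not bird
    assert by_class["tail"].source == "NAS"


def test_tail_in_torso_suppresses_tail_expansion():
    manifest = _mini_manifest(["torso", "tail"], tail_in_torso=True)
    out = build_model_set(
        hull_all(manifest), ExpansionPolicy(model_set_name="NAS_isometric"), _table(), manifest
    )
    by_class = {o.segment_class: o for o in out}
    assert by_class["tail"].point_volume == pytest.approx(by_class["tail"].hull_volume)


def test_per_segment_override_swaps_single_class():
    manifest = _mini_manifest(["torso", "neck"])
    policy = ExpansionPolicy(
        model_set_name="NAS_isometric",
        per_segment_overrides={("taxonX", "neck"): ("bird", "isometric")},
    )
    out = build_model_set(hull_all(manifest), policy, _table(), manifest)
    by_class = {o.segment_class: o for o in out}
    assert by_class["torso"].source == "NAS"
    assert by_class["neck"].source == "bird"
    assert by_class["neck"].point_volume == pytest.approx(1.2)

    # empty override map reproduces the uniform set
    uniform = build_model_set(
        hull_all(manifest), ExpansionPolicy(model_set_name="NAS_isometric"), _table(), manifest
    )
    overridden = build_model_set(
        hull_all(manifest),
        ExpansionPolicy(model_set_name="NAS_isometric", per_segment_overrides={}),
        _table(),
        manifest,
    )
    for a, b in zip(uniform, overridden):
        assert a.point_volume == b.point_volume


def test_missing_factor_lists_class():
    manifest = _mini_manifest(["torso", "neck"])
    with pytest.raises(ExpansionError, match="neck"):
        build_model_set(
            hull_all(manifest),
            ExpansionPolicy(model_set_name="NAS_isometric"),
            [ScalingModel("torso", "NAS", "isometric", k=1.6)],
            manifest,
        )


def test_isometric_scale_consistency(box_skeleton, factor_table):
    # doubling every coordinate multiplies every isometric volume by 8
    manifest, _ = box_skeleton
    policy = ExpansionPolicy(model_set_name="NAS_isometric")
    base = build_model_set(hull_all(manifest), policy, factor_table, manifest)

    big, _ = generate_skeleton(default_body_plan(2.4))  # 2x the fixture's scale
    scaled = build_model_set(hull_all(big), policy, factor_table, taxon="big")
    for a, b in zip(base, scaled):
        assert b.point_volume == pytest.approx(8.0 * a.point_volume, rel=1e-9)


def test_sellers21_total_volume_identity(box_skeleton):
    manifest, _ = box_skeleton
    hulls = hull_all(manifest)
    policy = ExpansionPolicy(model_set_name="sellers21")
    out = build_model_set(hulls, policy, None, manifest)
    exempt = policy.exempt_classes
    hull_nonexempt = sum(h.hull_volume for h in hulls if h.segment_class.name not in exempt)
    hull_exempt = sum(h.hull_volume for h in hulls if h.segment_class.name in exempt)
    total = sum(o.point_volume for o in out)
    assert total == pytest.approx(1.21 * hull_nonexempt + hull_exempt, rel=1e-12)


def test_factor_table_csv_round_trip(tmp_path, factor_table):
    import pandas as pd

    rows = [
        {
            "segment_class": m.segment_class,
            "source": m.source,
            "mode": m.mode,
            "a": m.a,
            "b": m.b,
            "k": m.k,
            "mppe": m.mppe,
        }
        for m in factor_table
    ]
    path = tmp_path / "factors.csv"
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    back = load_factor_table(path)
    assert len(back) == len(factor_table)
    key = lambda m: (m.segment_class, m.source, m.mode)
    for a, b in zip(sorted(factor_table, key=key), sorted(back, key=key)):
        assert key(a) == key(b)
        assert b.mppe == pytest.approx(a.mppe, rel=1e-12)
        assert b.predict(2.0) == pytest.approx(a.predict(2.0), rel=1e-12)


def test_placeholder_table_covers_all_fleshy_classes(factor_table):
    keys = {(m.segment_class, m.source, m.mode) for m in factor_table}
    for cls in ("head", "neck", "torso", "tail", "thigh", "metatarsus"):
        for source in ("NAS", "bird"):
            for mode in ("allometric", "isometric"):
                assert (cls, source, mode) in keys
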