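import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pelvimetry3d as p
from pelvimetry3d.measures import (
    ANGLE_MEASURES,
    DISTANCE_MEASURES,
    MEASURE_REGISTRY,
    MeasureConfig,
    compute_pelvimetry,
    derived_points,
    line_axis_angle,
    point_distance,
    three_point_angle,
)

finite = st.floats(-500, 500, allow_nan=False, allow_infinity=False)
point = st.tuples(finite, finite, finite)


def test_registry_has_21_measures():
    assert len(MEASURE_REGISTRY) == 21
    assert len(DISTANCE_MEASURES) == 14
    assert len(ANGLE_MEASURES) == 6


def test_point_distance_basics():
    assert point_distance((1, 2, 3), (1, 2, 3)) == 0.0
    assert point_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)


def test_obstetric_conjugate_is_symphysis_to_promontory(female_template):
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    assert rec.obstetric_conjugate == pytest.approx(
        point_distance(lset["PS_SUP"], lset["SACRAL_PROMONTORY"])
    )


def test_three_point_angle_degenerate_and_right():
    assert three_point_angle((1, 0, 0), (0, 0, 0), (-2, 0, 0)) == pytest.approx(180.0)
    assert three_point_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
    with pytest.raises(ValueError, match="coincides"):
        three_point_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


def test_three_point_angle_matches_law_of_cosines_oracle():
    """1000 random triples agree with the law-of-cosines reconstruction."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        a, v, b = rng.normal(0, 100, (3, 3))
        if np.linalg.norm(a - v) < 1e-6 or np.linalg.norm(b - v) < 1e-6:
            continue
        ang = three_point_angle(a, v, b)
        # oracle: cos C = (a² + b² − c²) / 2ab on the triangle side lengths
        la, lb = np.linalg.norm(a - v), np.linalg.norm(b - v)
        lc = np.linalg.norm(a - b)
        oracle = np.degrees(np.arccos(np.clip((la**2 + lb**2 - lc**2) / (2 * la * lb), -1, 1)))
        assert ang == pytest.approx(oracle, abs=1e-9)


def test_line_axis_angle_limits_and_oracle():
    z = (0.0, 0.0, 1.0)
    assert line_axis_angle((0, 0, 0), (1, 1, 0), z) == pytest.approx(0.0)
    assert line_axis_angle((0, 0, 0), (0, 0, 5), z) == pytest.approx(90.0)
    rng = np.random.default_rng(1)
    for _ in range(500):
        pq = rng.normal(0, 50, (2, 3))
        d = pq[1] - pq[0]
        if np.linalg.norm(d) < 1e-6:
            continue
        got = line_axis_angle(pq[0], pq[1], z)
        oracle = np.degrees(np.arcsin(abs(d[2]) / np.linalg.norm(d)))
        assert got == pytest.approx(oracle, abs=1e-9)
    with pytest.raises(ValueError, match="zero-length"):
        line_axis_angle((1, 2, 3), (1, 2, 3), z)
    with pytest.raises(ValueError, match="unit"):
        line_axis_angle((0, 0, 0), (1, 0, 0), (0, 0, 2))


def test_derived_points(female_template):
    lset, _ = female_template
    aux = derived_points(lset)
    assert np.allclose(
        aux["inlet_midpoint"], (lset["PS_SUP"] + lset["SACRAL_PROMONTORY"]) / 2
    )
    # symmetric template: femoral centre sits on the mid-sagittal plane
    assert abs(aux["femoral_centre"][0]) < 1e-6
    # switching the conjugate moves the midpoint by half the PS offset
    aux_true = derived_points(lset, MeasureConfig(inlet_conjugate="true"))
    shift = aux_true["inlet_midpoint"] - aux["inlet_midpoint"]
    assert np.allclose(shift, (lset["PS_MID"] - lset["PS_SUP"]) / 2, atol=1e-12)


def test_all_21_measures_finite_and_positive(female_template):
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    vals = rec.as_dict()
    assert len(vals) == 21
    assert all(np.isfinite(v) for v in vals.values())
    assert all(vals[m] > 0 for m in DISTANCE_MEASURES)
    assert all(0 < vals[m] < 180 for m in ANGLE_MEASURES)
    assert vals["inlet_depth_ratio"] > 0


def test_ratio_uses_obstetric_conjugate(female_template):
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    assert rec.inlet_depth_ratio == pytest.approx(rec.obstetric_conjugate / rec.pelvic_depth)


def _rigid_transform(lset, rotation, translation):
    return lset.transformed(lambda v: rotation @ v + translation)


def _rotation_about(axis, theta):
    axis = np.asarray(axis, float)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def test_rigid_motion_invariance(female_template):
    """All measures except the two axis-referenced angles survive any rigid
    motion; pelvic tilt and inlet β survive rotations about their own axes."""
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    rng = np.random.default_rng(7)
    axis_free = [m for m in MEASURE_REGISTRY if m not in ("pelvic_tilt", "inlet_beta")]
    for _ in range(5):
        rot = _rotation_about(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
        t = rng.normal(0, 200, 3)
        rec2 = compute_pelvimetry(_rigid_transform(lset, rot, t))
        for m in axis_free:
            assert rec2[m] == pytest.approx(rec[m], abs=1e-9), m
    # vertical-axis rotations + translations preserve pelvic tilt
    for theta in (0.3, 1.2, 4.0):
        roty = _rotation_about((0, 1, 0), theta)
        rec3 = compute_pelvimetry(_rigid_transform(lset, roty, rng.normal(0, 100, 3)))
        assert rec3["pelvic_tilt"] == pytest.approx(rec["pelvic_tilt"], abs=1e-9)
    # transverse-axis rotations preserve inlet β
    for theta in (0.4, 2.5):
        rotz = _rotation_about((0, 0, 1), theta)
        rec4 = compute_pelvimetry(_rigid_transform(lset, rotz, rng.normal(0, 100, 3)))
        assert rec4["inlet_beta"] == pytest.approx(rec["inlet_beta"], abs=1e-9)


def test_scale_equivariance(female_template):
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    s = 1.7
    rec_s = compute_pelvimetry(lset.transformed(lambda v: s * v))
    for m in DISTANCE_MEASURES:
        assert rec_s[m] == pytest.approx(s * rec[m], rel=1e-12)
    for m in ANGLE_MEASURES + ("inlet_depth_ratio",):
        assert rec_s[m] == pytest.approx(rec[m], rel=1e-12)


def test_triangle_consistency(female_template, male_template):
    for lset, _ in (female_template, male_template):
        rec = compute_pelvimetry(lset)
        assert rec.promontory_to_coccyx <= rec.promontory_to_s3s4 + rec.s3s4_to_coccyx + 1e-9


def test_chi_triangle_angles_sum_to_180(female_template):
    lset, _ = female_template
    rec = compute_pelvimetry(lset)
    at_ps = three_point_angle(lset["SACRAL_PROMONTORY"], lset["PS_SUP"], lset["COCCYX_TIP"])
    at_coccyx = three_point_angle(lset["PS_SUP"], lset["COCCYX_TIP"], lset["SACRAL_PROMONTORY"])
    assert rec.angle_chi + at_ps + at_coccyx == pytest.approx(180.0, abs=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(a=point, v=point, b=point)
def test_three_point_angle_symmetry_property(a, v, b):
    """angle(a, v, b) == angle(b, v, a) whenever defined."""
    a, v, b = np.array(a), np.array(v), np.array(b)
    if np.linalg.norm(a - v) < 1e-6 or np.linalg.norm(b - v) < 1e-6:
        return
    assert three_point_angle(a, v, b) == pytest.approx(three_point_angle(b, v, a), abs=1e-9)
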