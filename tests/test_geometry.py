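"""Vertebral geometry, apex detection and Cobb measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoliopred.geometry import (
    CurveMeasure,
    GeometryError,
    LandmarkInputError,
    LandmarkSet,
    VertebraGeometry,
    VertebraLandmarks,
    find_apices,
    fit_spine_curve,
    measure_all,
    measure_curve,
    normalize_coordinates,
    vertebra_geometry,
)
from scoliopred.simulate import SpineSimConfig, generate_spine_landmarks

from conftest import rectangle_landmarks


# ---------------------------------------------------------------------------
# vertebra_geometry
# ---------------------------------------------------------------------------


def test_axis_aligned_rectangle_geometry():
    g = vertebra_geometry(rectangle_landmarks(centre=(20.0, 10.0)))
    assert np.allclose(g.centroid, [20.0, 10.0])
    assert g.orientation == pytest.approx(0.0, abs=1e-9)
    assert g.wedge == pytest.approx(0.0, abs=1e-9)
    assert not g.isotropic


@pytest.mark.parametrize("angle", [7.0, -7.0, 33.5, -60.0, 89.0])
def test_rectangle_orientation_equals_rotation(angle):
    # analytic oracle: the principal axis of a rotated rectangle's area
    # moments co-rotates with the rectangle
    g = vertebra_geometry(rectangle_landmarks(angle_deg=angle))
    assert g.orientation == pytest.approx(angle, abs=1e-6)
    assert g.wedge == pytest.approx(0.0, abs=1e-6)


def test_trapezoid_wedge_angle():
    # superior endplate sloped +3 deg, inferior sloped -3 deg -> wedge 6 deg
    w = 40.0
    s, t = math.tan(math.radians(3.0)), math.tan(math.radians(-3.0))
    corners = np.array(
        [
            [-w / 2, 10 - s * w / 2],
            [w / 2, 10 + s * w / 2],
            [w / 2, -10 + t * w / 2],
            [-w / 2, -10 - t * w / 2],
        ]
    )
    g = vertebra_geometry(VertebraLandmarks("T8", corners))
    # brute-force oracle: angle between the two endplate direction vectors
    u = corners[1] - corners[0]
    v = corners[2] - corners[3]
    expect = math.degrees(
        math.acos(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    )
    assert expect == pytest.approx(6.0, abs=1e-9)
    assert g.wedge == pytest.approx(expect, abs=1e-9)


def test_square_falls_back_to_superior_endplate():
    g = vertebra_geometry(rectangle_landmarks(width=20, height=20, angle_deg=10))
    assert g.isotropic
    assert g.orientation == pytest.approx(10.0, abs=1e-6)


def test_degenerate_and_crossed_polygons_error():
    flat = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
    with pytest.raises(GeometryError):
        VertebraLandmarks("T1", flat)
    crossed = np.array([[0, 1], [1, 0], [1, 1], [0, 0]], dtype=float)  # bowtie
    with pytest.raises(LandmarkInputError):
        VertebraLandmarks("T1", crossed)


# ---------------------------------------------------------------------------
# normalize_coordinates
# ---------------------------------------------------------------------------


def _small_spine(n=5):
    verts = [
        rectangle_landmarks(level=f"T{i + 1}", centre=(0.0, (n - 1 - i) * 40.0))
        for i in range(n)
    ]
    return LandmarkSet("p", 0, "standing-frontal", tuple(verts))


def _to_pixels(s, height=200.0):
    """Image-pixel version of a y-up spine: every y becomes height - y,
    corner labels unchanged (so superior corners get the smaller pixel y)."""
    return LandmarkSet(
        s.patient_id,
        s.visit,
        s.view,
        tuple(
            VertebraLandmarks(
                v.level,
                np.column_stack([v.corners[:, 0], height - v.corners[:, 1]]),
            )
            for v in s.vertebrae
        ),
    )


def test_normalize_is_idempotent():
    s = _small_spine()
    out = normalize_coordinates(normalize_coordinates(s))
    for a, b in zip(out.vertebrae, s.vertebrae):
        assert np.allclose(a.corners, b.corners)


def test_normalize_flips_pixel_rows():
    s = _small_spine()
    pixels = _to_pixels(s, 200.0)
    out = normalize_coordinates(pixels, y_down=True, image_height=200.0)
    for a, b in zip(out.vertebrae, s.vertebrae):
        assert np.allclose(a.corners, b.corners)


def test_normalize_rejects_inverted_corner_labels():
    # pixel input read as if already y-up: superior corners end up caudal
    with pytest.raises(LandmarkInputError):
        normalize_coordinates(_to_pixels(_small_spine()))


# ---------------------------------------------------------------------------
# fit_spine_curve / find_apices
# ---------------------------------------------------------------------------


def _geoms_from_centroids(xs, ys, orientations=None):
    orientations = orientations or [0.0] * len(xs)
    levels = [f"T{i + 1}" if i < 12 else f"L{i - 11}" for i in range(len(xs))]
    return [
        VertebraGeometry(lv, np.array([x, y]), o, 0.0)
        for lv, x, y, o in zip(levels, xs, ys, orientations)
    ]


def test_collinear_centroids_have_no_extrema():
    ys = np.linspace(600, 0, 10)
    curve = fit_spine_curve(_geoms_from_centroids(np.zeros(10), ys))
    assert curve.extrema == ()
    assert find_apices(curve, _geoms_from_centroids(np.zeros(10), ys)) == []


def test_single_bump_extremum_near_analytic_peak():
    L = 680.0
    ys = np.linspace(L, 0, 17)
    xs = 50.0 * np.sin(np.pi * ys / L)  # peak at y = L/2
    curve = fit_spine_curve(_geoms_from_centroids(xs, ys))
    assert len(curve.extrema) == 1
    y_ext, x_ext = curve.extrema[0]
    assert y_ext == pytest.approx(L / 2, abs=2.0)
    assert x_ext == pytest.approx(50.0, abs=0.5)


def test_s_curve_has_two_opposite_extrema_cranial_first():
    L = 680.0
    ys = np.linspace(L, 0, 17)
    xs = 40.0 * np.sin(2 * np.pi * ys / L)  # extrema at 3L/4 (+) and L/4 (-)
    geoms = _geoms_from_centroids(xs, ys)
    curve = fit_spine_curve(geoms)
    assert len(curve.extrema) == 2
    (y1, x1), (y2, x2) = curve.extrema
    assert y1 > y2  # cranial-first
    assert x1 < 0 < x2  # opposite lateral sides
    apices = find_apices(curve, geoms)
    assert len(apices) == 2


def test_non_monotone_centroids_rejected():
    ys = np.array([600.0, 500.0, 550.0, 400.0])
    with pytest.raises(GeometryError, match="monotone"):
        fit_spine_curve(_geoms_from_centroids(np.zeros(4), ys))


def test_apex_is_nearest_centroid_to_extremum():
    lset, truth = generate_spine_landmarks(SpineSimConfig(cobb=40.0), seed=0)
    geoms = [vertebra_geometry(v) for v in lset.vertebrae]
    curve = fit_spine_curve(geoms)
    assert find_apices(curve, geoms) == ["T9"]  # middle of 17 vertebrae
    assert truth.apex == ("T9",)


# ---------------------------------------------------------------------------
# measure_curve / measure_all
# ---------------------------------------------------------------------------


def test_cobb_is_absolute_difference_of_end_tilts():
    ys = np.linspace(600, 0, 7)
    xs = 30 * np.sin(np.pi * ys / 600)
    tilts = [20.0, 12.0, 4.0, 0.0, -6.0, -15.0, -25.0]
    geoms = _geoms_from_centroids(xs, ys, tilts)
    m = measure_curve(geoms, geoms[3].level)
    assert m.cobb == pytest.approx(45.0)
    assert m.upper_end == geoms[0].level
    assert m.lower_end == geoms[6].level
    assert m.levels == 7


def test_zero_tilt_spine_measures_zero_cobb():
    ys = np.linspace(600, 0, 7)
    xs = 30 * np.sin(np.pi * ys / 600)
    geoms = _geoms_from_centroids(xs, ys)
    m = measure_curve(geoms, geoms[3].level)
    assert m.cobb == pytest.approx(0.0)


def test_tilt_ties_resolve_to_vertebra_farther_from_apex():
    ys = np.linspace(600, 0, 7)
    xs = 30 * np.sin(np.pi * ys / 600)
    tilts = [10.0, 10.0, 5.0, 0.0, -5.0, -10.0, -10.0]
    m = measure_curve(_geoms_from_centroids(xs, ys, tilts), "T4")
    assert (m.upper_end, m.lower_end) == ("T1", "T7")


def test_boundary_apex_rejected():
    ys = np.linspace(600, 0, 5)
    geoms = _geoms_from_centroids(np.zeros(5), ys)
    with pytest.raises(GeometryError, match="boundary"):
        measure_curve(geoms, geoms[0].level)


def test_straight_spine_yields_no_curves():
    lset, _ = generate_spine_landmarks(SpineSimConfig(cobb=0.0), seed=0)
    assert measure_all(lset) == []


def test_s_curve_major_flag_goes_to_larger_cobb():
    cfg = SpineSimConfig(shape="s-curve", cobb=50.0, cobb2=35.0)
    lset, truth = generate_spine_landmarks(cfg, seed=0)
    ms = measure_all(lset)
    assert len(ms) == 2
    major = [m for m in ms if m.major]
    assert len(major) == 1
    assert major[0].apex == truth.apex[0]  # the 50-degree thoracic curve
    assert major[0].cobb == pytest.approx(50.0, abs=2.0)


def test_mirror_flip_preserves_cobb_and_flips_side():
    lset, _ = generate_spine_landmarks(SpineSimConfig(cobb=45.0), seed=2)
    mirrored = LandmarkSet(
        lset.patient_id,
        lset.visit,
        lset.view,
        tuple(
            # negate x and swap left/right corner labels to keep SL on the left
            VertebraLandmarks(
                v.level,
                np.array(
                    [
                        [-v.corners[1, 0], v.corners[1, 1]],
                        [-v.corners[0, 0], v.corners[0, 1]],
                        [-v.corners[3, 0], v.corners[3, 1]],
                        [-v.corners[2, 0], v.corners[2, 1]],
                    ]
                ),
            )
            for v in lset.vertebrae
        ),
    )
    a, b = measure_all(lset)[0], measure_all(mirrored)[0]
    assert a.cobb == pytest.approx(b.cobb, abs=1e-9)
    assert {a.side, b.side} == {"left", "right"}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    phi=st.floats(-20.0, 20.0),
    tx=st.floats(-500.0, 500.0),
    ty=st.floats(-500.0, 500.0),
    scale=st.floats(0.25, 4.0),
)
def test_rigid_motion_and_scale_invariance(phi, tx, ty, scale):
    """Global rotation, translation and uniform scaling leave Cobb and wedge
    angles unchanged (the orientation offset cancels in the difference)."""
    lset, _ = generate_spine_landmarks(SpineSimConfig(cobb=35.0), seed=4)
    t = math.radians(phi)
    rot = scale * np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    moved = LandmarkSet(
        lset.patient_id,
        lset.visit,
        lset.view,
        tuple(
            VertebraLandmarks(v.level, v.corners @ rot.T + [tx, ty])
            for v in lset.vertebrae
        ),
    )
    a, b = measure_all(lset)[0], measure_all(moved)[0]
    assert b.cobb == pytest.approx(a.cobb, abs=1e-6)
    ga = [vertebra_geometry(v) for v in lset.vertebrae]
    gb = [vertebra_geometry(v) for v in moved.vertebrae]
    for va, vb in zip(ga, gb):
        assert vb.wedge == pytest.approx(va.wedge, abs=1e-6)


def test_cobb_error_degrades_monotonically_with_landmark_noise():
    def mean_abs_error(noise_sd):
        errs = []
        for seed in range(12):
            lset, truth = generate_spine_landmarks(
                SpineSimConfig(cobb=40.0, noise_sd=noise_sd), seed=seed
            )
            ms = measure_all(lset)
            assert ms, "curve should remain detectable at these noise levels"
            major = next(m for m in ms if m.major)
            errs.append(abs(major.cobb - truth.cobb[0]))
        return float(np.mean(errs))

    e0, e1, e2 = (mean_abs_error(s) for s in (0.0, 1.5, 4.0))
    assert e0 <= e1 + 0.05
    assert e1 <= e2 + 0.05


def test_curve_measure_invariants_enforced():
    with pytest.raises(GeometryError):
        CurveMeasure("T5", "T8", "T10", 30.0, 6, "left")  # upper end below apex
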