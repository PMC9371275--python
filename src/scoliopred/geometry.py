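"""Vertebral and curve-level geometry from radiographic landmark points.

Each vertebra is digitised as four corner landmarks on a frontal radiograph.
From these the module derives per-vertebra geometry (area centroid,
equivalent-ellipse orientation, endplate wedge angle), fits a cubic spline
through the centroids to locate curve apices, and measures each scoliotic
curve: end vertebrae (the most tilted above and below the apex), Cobb angle,
levels involved and convexity side.

Coordinate convention
---------------------
Internally x runs across the image (increasing toward the patient's left on
a PA film) and y increases caudally -> cranially, i.e. "up" anatomically.
Image-pixel input with y increasing downward is converted by
:func:`normalize_coordinates`. Angles are in degrees, positive
counter-clockwise, with vertebral orientation reported from the horizontal
in (-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SPINAL_LEVELS",
    "CORNER_ORDER",
    "VertebraLandmarks",
    "LandmarkSet",
    "VertebraGeometry",
    "CurveMeasure",
    "SpineCurve",
    "GeometryError",
    "LandmarkInputError",
    "normalize_coordinates",
    "vertebra_geometry",
    "fit_spine_curve",
    "find_apices",
    "measure_curve",
    "measure_all",
    "level_index",
]

#: Cranio-caudal order of measurable spinal levels (thoracic + lumbar).
SPINAL_LEVELS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)
_LEVEL_INDEX = {lv: i for i, lv in enumerate(SPINAL_LEVELS)}

#: Corner labels in canonical order: superior-left, superior-right,
#: inferior-right, inferior-left.
CORNER_ORDER: tuple[str, ...] = ("SL", "SR", "IR", "IL")

#: Minimum lateral deviation (px) of a spline extremum from the end-to-end
#: chord for it to count as a curve apex.
DEFAULT_MIN_DEVIATION = 2.0

#: Relative eigenvalue gap below which the moment tensor is treated as
#: isotropic (principal axes undefined, e.g. a square vertebra).
_ISOTROPY_RTOL = 1e-9


class GeometryError(ValueError):
    """Degenerate vertebral geometry (zero area, undefined axes...)."""


class LandmarkInputError(ValueError):
    """Landmark input inconsistent with the declared convention."""


def level_index(level: str) -> int:
    """Cranio-caudal ordinal of a spinal level (T1 -> 0 ... L5 -> 16)."""
    try:
        return _LEVEL_INDEX[level.strip().upper()]
    except KeyError:
        raise LandmarkInputError(
            f"unknown spinal level {level!r}; expected one of T1..T12, L1..L5"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VertebraLandmarks:
    """Four corner landmarks of one vertebra.

    Corners are ordered SL, SR, IR, IL (superior-left, superior-right,
    inferior-right, inferior-left) in the internal y-up convention.
    """

    level: str
    corners: np.ndarray  # shape (4, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.corners, dtype=float)
        if pts.shape != (4, 2):
            raise LandmarkInputError(
                f"{self.level}: expected 4 corner points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkInputError(f"{self.level}: non-finite landmark coordinates")
        object.__setattr__(self, "corners", pts)
        level_index(self.level)
        if _self_intersects(pts):
            raise LandmarkInputError(
                f"{self.level}: landmark polygon is self-intersecting; "
                "check the SL,SR,IR,IL corner ordering"
            )
        if abs(_signed_area(pts)) <= 0.0:
            raise GeometryError(f"{self.level}: landmark polygon has zero area")


@dataclass(frozen=True)
class LandmarkSet:
    """All digitised vertebrae of one (patient, visit, view) radiograph."""

    patient_id: str
    visit: int
    view: str  # standing-frontal | side-bending-left | side-bending-right
    vertebrae: tuple[VertebraLandmarks, ...]

    VIEWS = ("standing-frontal", "side-bending-left", "side-bending-right")

    def __post_init__(self) -> None:
        if self.view not in self.VIEWS:
            raise LandmarkInputError(
                f"unknown view {self.view!r}; expected one of {self.VIEWS}"
            )
        object.__setattr__(self, "vertebrae", tuple(self.vertebrae))
        idx = [level_index(v.level) for v in self.vertebrae]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise LandmarkInputError(
                "vertebra levels must strictly increase cranio-caudally "
                f"(got {[v.level for v in self.vertebrae]})"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(v.level for v in self.vertebrae)


@dataclass(frozen=True)
class VertebraGeometry:
    """Centroid, tilt and wedge of one vertebra.

    ``orientation`` is the angle of the equivalent ellipse's major axis from
    the horizontal, degrees in (-90, 90]; ``wedge`` is the angle between the
    superior and inferior endplate lines, degrees in [0, 90).
    ``isotropic`` flags vertebrae whose area moments had no unique major
    axis, where the superior endplate direction was used instead.
    """

    level: str
    centroid: np.ndarray  # (2,)
    orientation: float
    wedge: float
    isotropic: bool = False


@dataclass(frozen=True)
class CurveMeasure:
    """One measured scoliotic curve."""

    apex: str
    upper_end: str
    lower_end: str
    cobb: float
    levels: int
    side: str  # convexity: "left" | "right"
    major: bool = False

    def __post_init__(self) -> None:
        if not (
            level_index(self.upper_end) < level_index(self.apex) < level_index(self.lower_end)
        ):
            raise GeometryError(
                f"end vertebrae {self.upper_end}/{self.lower_end} must bracket "
                f"apex {self.apex}"
            )
        if self.cobb < 0:
            raise GeometryError("Cobb angle must be >= 0")


@dataclass(frozen=True)
class SpineCurve:
    """Cubic spline x(y) through the vertebral centroids plus its interior
    lateral extrema, ordered cranial-first."""

    spline: CubicSpline = field(repr=False)
    y_range: tuple[float, float]  # (caudal-most y, cranial-most y)
    extrema: tuple[tuple[float, float], ...]  # (y, x) pairs, cranial-first


# ---------------------------------------------------------------------------
# Polygon primitives
# ---------------------------------------------------------------------------


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _self_intersects(pts: np.ndarray) -> bool:
    # A quadrilateral is non-simple iff one pair of opposite edges crosses.
    return _segments_cross(pts[0], pts[1], pts[2], pts[3]) or _segments_cross(
        pts[1], pts[2], pts[3], pts[0]
    )


def _polygon_moments(pts: np.ndarray):
    """Area, centroid and second *central* area moments of a simple polygon.

    Returns (area, centroid, Sxx, Syy, Sxy) where Sxx = integral of (x-cx)^2
    over the area etc. Signed formulas; orientation sign cancels on division.
    """
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if a == 0.0:
        raise GeometryError("degenerate polygon: zero area")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    # second moments about the origin
    sxx = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    syy = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    sxy = float(np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross)) / 24.0
    # shift to centroid; normalise sign so moments are positive definite
    area = abs(a)
    sgn = math.copysign(1.0, a)
    sxx = sgn * sxx - area * cx * cx
    syy = sgn * syy - area * cy * cy
    sxy = sgn * sxy - area * cx * cy
    return area, np.array([cx, cy]), sxx, syy, sxy


def _wrap_orientation(deg: float) -> float:
    """Map an axis angle to the canonical (-90, 90] interval."""
    deg = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if deg == -90.0 else deg


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_coordinates(
    lset: LandmarkSet, *, y_down: bool = False, image_height: float | None = None
) -> LandmarkSet:
    """Convert a landmark set to the internal y-up convention and validate it.

    With ``y_down=True`` every y is replaced by ``H - y`` where ``H`` is
    ``image_height`` (default: the maximum y in the set). The function is
    idempotent on already-normalized input (``y_down=False``).

    Raises :class:`LandmarkInputError` if, after conversion, any vertebra's
    superior corners are not cranial to its inferior corners.
    """
    if not lset.vertebrae:
        raise LandmarkInputError("empty landmark set")
    verts = lset.vertebrae
    if y_down:
        h = image_height
        if h is None:
            h = max(float(v.corners[:, 1].max()) for v in verts)
        verts = tuple(
            VertebraLandmarks(v.level, np.column_stack([v.corners[:, 0], h - v.corners[:, 1]]))
            for v in verts
        )
    for v in verts:
        sup_y = v.corners[:2, 1].mean()  # SL, SR
        inf_y = v.corners[2:, 1].mean()  # IR, IL
        if not sup_y > inf_y:
            raise LandmarkInputError(
                f"{v.level}: superior corners are not cranial to inferior "
                "corners; input may be y-down (pass y_down=True) or corners "
                "are mislabeled"
            )
    return replace(lset, vertebrae=verts)


def vertebra_geometry(v: VertebraLandmarks) -> VertebraGeometry:
    """Centroid, equivalent-ellipse orientation and wedge of one vertebra.

    The "equivalent ellipse" is defined by the polygon's second central area
    moments; its major principal axis gives the vertebral tilt. For a
    rectangle this equals the rectangle's rotation angle exactly. When the
    moment tensor is isotropic (a square), the superior endplate direction
    is used and the result is flagged.
    """
    _, centroid, sxx, syy, sxy = _polygon_moments(v.corners)
    # covariance-style tensor of the area distribution
    tr, det_gap = sxx + syy, math.hypot(sxx - syy, 2.0 * sxy)
    isotropic = det_gap <= _ISOTROPY_RTOL * max(tr, 1e-300)
    if isotropic:
        d = v.corners[1] - v.corners[0]  # SL -> SR
        angle = math.degrees(math.atan2(d[1], d[0]))
    else:
        # principal axis of the larger eigenvalue
        angle = 0.5 * math.degrees(math.atan2(2.0 * sxy, sxx - syy))
    orientation = _wrap_orientation(angle)

    sup = v.corners[1] - v.corners[0]  # SL -> SR
    inf = v.corners[2] - v.corners[3]  # IL -> IR
    nu, ni = np.linalg.norm(sup), np.linalg.norm(inf)
    if nu == 0 or ni == 0:
        raise GeometryError(f"{v.level}: degenerate endplate (coincident corners)")
    # angle between the endplate *lines* via atan2 (well-conditioned near 0)
    cross = float(sup[0] * inf[1] - sup[1] * inf[0])
    dot = float(np.dot(sup, inf))
    wedge = math.degrees(math.atan2(abs(cross), abs(dot)))
    return VertebraGeometry(v.level, centroid, orientation, wedge, isotropic)


def fit_spine_curve(geoms: Sequence[VertebraGeometry]) -> SpineCurve:
    """Interpolating cubic spline of lateral position x against cranio-caudal
    position y through the centroids, with its interior extrema.

    Natural boundary conditions. Requires >= 4 centroids with strictly
    monotone y (the cranio-caudal coordinate).
    """
    if len(geoms) < 4:
        raise GeometryError("need >= 4 vertebrae to fit a spine curve")
    c = np.array([g.centroid for g in geoms], dtype=float)
    ys, xs = c[:, 1], c[:, 0]
    dy = np.diff(ys)
    if not (np.all(dy > 0) or np.all(dy < 0)):
        raise GeometryError(
            "centroid cranio-caudal coordinates are not strictly monotone; "
            "re-order the vertebrae or reject the set"
        )
    if dy[0] < 0:  # stored cranial-first (y decreasing): flip for the spline
        ys, xs = ys[::-1], xs[::-1]
    spline = CubicSpline(ys, xs, bc_type="natural")
    crit = spline.derivative().roots(extrapolate=False)
    crit = np.real(crit[np.isreal(crit)])
    crit = crit[np.isfinite(crit)]  # zero segments are reported as nan
    lo, hi = float(ys[0]), float(ys[-1])
    second = spline.derivative(2)
    extrema = [
        (float(t), float(spline(t)))
        for t in crit
        if lo < t < hi and abs(float(second(t))) > 0
    ]
    extrema.sort(key=lambda e: -e[0])  # cranial-first
    return SpineCurve(spline=spline, y_range=(lo, hi), extrema=tuple(extrema))


def _chord_deviation(curve: SpineCurve, geoms, y: float, x: float) -> float:
    """Signed lateral offset of point (x, y) from the end-to-end centroid
    chord, positive toward +x (patient's left)."""
    c0, c1 = geoms[0].centroid, geoms[-1].centroid
    # x of the chord at height y
    if c1[1] == c0[1]:
        raise GeometryError("endmost centroids share the same height")
    t = (y - c0[1]) / (c1[1] - c0[1])
    return float(x - (c0[0] + t * (c1[0] - c0[0])))


def find_apices(
    curve: SpineCurve,
    geoms: Sequence[VertebraGeometry],
    min_deviation: float = DEFAULT_MIN_DEVIATION,
) -> list[str]:
    """Apical levels: one per interior spline extremum whose lateral
    deviation from the end-to-end chord exceeds ``min_deviation`` pixels.

    The apex is the level of the centroid nearest (Euclidean) to the
    extremum; ties go to the more cranial level. A straight spine yields an
    empty list. Result is cranial-first and de-duplicated.
    """
    apices: list[str] = []
    for y, x in curve.extrema:
        if abs(_chord_deviation(curve, geoms, y, x)) <= min_deviation:
            continue
        pt = np.array([x, y])
        d = [float(np.linalg.norm(g.centroid - pt)) for g in geoms]
        best = min(range(len(geoms)), key=lambda i: (d[i], level_index(geoms[i].level)))
        lv = geoms[best].level
        if lv not in apices:
            apices.append(lv)
    apices.sort(key=level_index)
    return apices


def _most_tilted(geoms, indices, apex_idx) -> int:
    """Index with maximal |orientation|; ties -> farther from the apex."""
    best = None
    for i in indices:
        key = (abs(geoms[i].orientation), abs(i - apex_idx))
        if best is None or key > best[0]:
            best = (key, i)
    return best[1]


def measure_curve(
    geoms: Sequence[VertebraGeometry],
    apex: str,
    curve: SpineCurve | None = None,
) -> CurveMeasure:
    """Measure one curve around a given apical level.

    End vertebrae are the most tilted (max |orientation|) strictly above and
    strictly below the apex; ties go to the vertebra farther from the apex.
    Cobb angle is the absolute difference of the signed end-vertebra
    orientations. Convexity side comes from the sign of the apex centroid's
    lateral deviation from the end-to-end chord (+x = left on a PA film).
    """
    levels = [g.level for g in geoms]
    if apex not in levels:
        raise GeometryError(f"apex {apex} not among measured levels")
    a = levels.index(apex)
    if a == 0 or a == len(geoms) - 1:
        raise GeometryError(
            f"apex {apex} is at the boundary of the instrumented levels; "
            "cannot identify end vertebrae on both sides"
        )
    u = _most_tilted(geoms, range(0, a), a)
    l = _most_tilted(geoms, range(a + 1, len(geoms)), a)
    cobb = abs(geoms[u].orientation - geoms[l].orientation)
    if curve is not None:
        dev = _chord_deviation(curve, geoms, geoms[a].centroid[1], geoms[a].centroid[0])
    else:
        fitted = fit_spine_curve(geoms)
        dev = _chord_deviation(fitted, geoms, geoms[a].centroid[1], geoms[a].centroid[0])
    side = "left" if dev > 0 else "right"
    return CurveMeasure(
        apex=apex,
        upper_end=geoms[u].level,
        lower_end=geoms[l].level,
        cobb=cobb,
        levels=l - u + 1,
        side=side,
    )


def measure_all(
    lset: LandmarkSet, min_deviation: float = DEFAULT_MIN_DEVIATION
) -> list[CurveMeasure]:
    """Full measurement pipeline for one normalized radiograph.

    Runs per-vertebra geometry, the centroid spline, apex detection and
    per-apex curve measurement; flags the curve of maximal Cobb angle as
    major (tie -> more cranial apex). Returns [] for a straight spine.
    Apices falling on the endmost vertebrae are skipped (no end vertebra
    exists beyond them).
    """
    if len(lset.vertebrae) < 4:
        raise GeometryError("need >= 4 vertebrae to measure curves")
    geoms = [vertebra_geometry(v) for v in lset.vertebrae]
    curve = fit_spine_curve(geoms)
    boundary = {geoms[0].level, geoms[-1].level}
    measures = [
        measure_curve(geoms, apex, curve)
        for apex in find_apices(curve, geoms, min_deviation)
        if apex not in boundary
    ]
    if not measures:
        return []
    major_i = min(
        range(len(measures)),
        key=lambda i: (-measures[i].cobb, level_index(measures[i].apex)),
    )
    return [replace(m, major=(i == major_i)) for i, m in enumerate(measures)]
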