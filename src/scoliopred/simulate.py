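"""Synthetic scoliotic spines and patient cohorts with known ground truth.

Two generators make every other module testable without patient data:

* :func:`generate_spine_landmarks` builds a landmark-level spine whose true
  Cobb angle is known in closed form. The centerline of a single-bump curve
  is x(y) = A sin(pi y / L) with A = (L/pi) tan(theta*/2), so the maximal
  tangent angles are +/- theta*/2 and the analytic Cobb angle is exactly
  theta*. Vertebrae are rectangles placed at equal arc intervals, rotated
  to the local tangent, with optional isotropic Gaussian landmark noise.

* :func:`generate_cohort` draws tabular cohorts whose continuous marginals
  are truncated normals and whose categorical marginals follow configured
  frequencies (defaults emulate a surgical AIS cohort of 193 patients:
  initial major Cobb 48.9 +/- 13.9 deg, 169 F / 24 M, etc.). The outcome is
  generated by a stated linear progression model dominated by the initial
  Cobb angle and flexibility, so feature-selection and importance-ranking
  behaviour can be checked against a known effect ordering.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .features import FEATURE_NAMES, RISSER_GRADES
from .geometry import SPINAL_LEVELS, LandmarkSet, VertebraLandmarks

__all__ = [
    "SpineSimConfig",
    "CohortSimConfig",
    "SpineGroundTruth",
    "SimulationError",
    "generate_spine_landmarks",
    "generate_bending_set",
    "generate_cohort",
    "inject_null_features",
    "cohort_matrix",
]


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


# ---------------------------------------------------------------------------
# Spine generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineSimConfig:
    """Geometry of one simulated frontal radiograph.

    ``cobb`` is the true (analytic) Cobb angle in degrees; for the s-curve
    shape ``cobb2`` sets the caudal curve. ``apex_frac`` positions the apex
    along the spine (fraction of length from the caudal end; 0.5 puts it at
    the middle). Lengths in pixels; 17 vertebrae span T1-L5.
    """

    n_vertebrae: int = 17
    length: float = 680.0
    cobb: float = 40.0
    cobb2: float = 25.0
    apex_frac: float = 0.5
    shape: str = "single-bump"  # or "s-curve"
    width: float = 30.0
    height: float = 18.0
    noise_sd: float = 0.0
    patient_id: str = "sim"
    visit: int = 0
    view: str = "standing-frontal"

    def __post_init__(self) -> None:
        if self.n_vertebrae < 5:
            raise SimulationError("need at least 5 vertebrae")
        if not 0 <= self.cobb < 120 or not 0 <= self.cobb2 < 120:
            raise SimulationError("true Cobb must be in [0, 120)")
        if self.noise_sd < 0:
            raise SimulationError("landmark noise SD must be >= 0")
        if not 0.1 <= self.apex_frac <= 0.9:
            raise SimulationError("apex fraction must be in [0.1, 0.9]")
        if self.shape not in ("single-bump", "s-curve"):
            raise SimulationError("shape must be 'single-bump' or 's-curve'")


@dataclass(frozen=True)
class SpineGroundTruth:
    """Analytic truth for a generated spine: per-curve Cobb angle, apex
    level and end levels (cranial-first)."""

    cobb: tuple[float, ...]
    apex: tuple[str, ...]
    ends: tuple[tuple[str, str], ...]


def _single_bump(cobb_deg: float, length: float, apex_frac: float):
    """Centerline x(y) and slope dx/dy for one lateral bump.

    For an apex at the midpoint the amplitude has the closed form
    A = (L/pi) tan(theta*/2); off-centre apices use two quarter-waves and
    the amplitude solving atan(A pi / (2 ya)) + atan(A pi / (2 yb)) = theta*.
    """
    t = math.radians(cobb_deg)
    ya = apex_frac * length
    yb = length - ya
    if cobb_deg == 0:
        return (lambda y: 0.0 * y), (lambda y: 0.0 * y)
    if abs(apex_frac - 0.5) < 1e-12:
        amp = (length / math.pi) * math.tan(t / 2.0)

        def x(y):
            return amp * np.sin(np.pi * y / length)

        def dx(y):
            return amp * (np.pi / length) * np.cos(np.pi * y / length)

        return x, dx

    def total_angle(a):
        return (
            math.atan(a * math.pi / (2 * ya)) + math.atan(a * math.pi / (2 * yb)) - t
        )

    hi = 10.0 * length
    amp = brentq(total_angle, 0.0, hi)

    def x(y):
        y = np.asarray(y, dtype=float)
        lower = amp * np.sin(np.pi * y / (2 * ya))
        upper = amp * np.cos(np.pi * (y - ya) / (2 * yb))
        return np.where(y <= ya, lower, upper)

    def dx(y):
        y = np.asarray(y, dtype=float)
        lower = amp * (np.pi / (2 * ya)) * np.cos(np.pi * y / (2 * ya))
        upper = -amp * (np.pi / (2 * yb)) * np.sin(np.pi * (y - ya) / (2 * yb))
        return np.where(y <= ya, lower, upper)

    return x, dx


def _centerline(cfg: SpineSimConfig):
    """Returns (x(y), dx/dy, bump boundaries) with y in [0, L], y=0 caudal."""
    if cfg.shape == "single-bump":
        x, dx = _single_bump(cfg.cobb, cfg.length, cfg.apex_frac)
        return x, dx, [(0.0, cfg.length, cfg.cobb, +1)]
    # s-curve: cranial bump (convex +x) over the upper half, caudal bump
    # (convex -x) over the lower half, each a half-period sine.
    l2 = cfg.length / 2.0
    x1, dx1 = _single_bump(cfg.cobb, l2, 0.5)  # cranial curve
    x2, dx2 = _single_bump(cfg.cobb2, l2, 0.5)  # caudal curve

    def x(y):
        y = np.asarray(y, dtype=float)
        return np.where(y >= l2, x1(y - l2), -x2(y))

    def dx(y):
        y = np.asarray(y, dtype=float)
        return np.where(y >= l2, dx1(y - l2), -dx2(y))

    return x, dx, [(l2, cfg.length, cfg.cobb, +1), (0.0, l2, cfg.cobb2, -1)]


def generate_spine_landmarks(
    cfg: SpineSimConfig, seed: int | None = 0
) -> tuple[LandmarkSet, SpineGroundTruth]:
    """Generate one landmark set plus its analytic ground truth.

    Vertebral centres sit at equal arc-length intervals along the
    centerline; each vertebra is a width x height rectangle whose endplates
    are perpendicular to the local tangent. Landmark noise is isotropic
    Gaussian with SD ``cfg.noise_sd`` (seeded). Ground truth lists, per
    curve (cranial-first), the analytic Cobb angle, the level nearest the
    curve extremum and the levels nearest the maximal-tangent positions.
    """
    n = cfg.n_vertebrae
    if n > len(SPINAL_LEVELS):
        raise SimulationError(f"at most {len(SPINAL_LEVELS)} levels available")
    x_of, dx_of, bumps = _centerline(cfg)

    # equal arc-length placement via dense cumulative arc table
    ys = np.linspace(0.0, cfg.length, 4097)
    slope = np.asarray(dx_of(ys), dtype=float)
    seg = np.sqrt(1.0 + slope**2)
    arc = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) / 2 * np.diff(ys))])
    total = arc[-1]
    spacing = total / n
    if cfg.height >= spacing:
        raise SimulationError(
            f"vertebra height {cfg.height} exceeds arc spacing {spacing:.1f}; "
            "vertebrae would overlap"
        )
    targets = (np.arange(n) + 0.5) * spacing
    y_centres = np.interp(targets, arc, ys)  # caudal -> cranial

    rng = np.random.default_rng(seed)
    levels = SPINAL_LEVELS[: n]  # cranio-caudal labels
    verts = []
    for label, yc in zip(levels, y_centres[::-1]):  # cranial-first
        xc = float(np.asarray(x_of(yc)))
        s = float(np.asarray(dx_of(yc)))
        tang = np.array([s, 1.0]) / math.hypot(s, 1.0)  # along the spine, cranial
        wdir = np.array([1.0, -s]) / math.hypot(s, 1.0)  # endplate direction, +x-ish
        c = np.array([xc, yc])
        half_w, half_h = cfg.width / 2.0, cfg.height / 2.0
        corners = np.vstack(
            [
                c + half_h * tang - half_w * wdir,  # SL
                c + half_h * tang + half_w * wdir,  # SR
                c - half_h * tang + half_w * wdir,  # IR
                c - half_h * tang - half_w * wdir,  # IL
            ]
        )
        if cfg.noise_sd > 0:
            corners = corners + rng.normal(0.0, cfg.noise_sd, corners.shape)
        verts.append(VertebraLandmarks(label, corners))
    lset = LandmarkSet(cfg.patient_id, cfg.visit, cfg.view, tuple(verts))

    def nearest_level(y_target: float) -> str:
        i = int(np.argmin(np.abs(y_centres - y_target)))
        return levels[::-1][i]  # y_centres is caudal-first

    truths_cobb, truths_apex, truths_ends = [], [], []
    for y_lo, y_hi, theta, _sign in bumps:
        if theta == 0:
            continue
        frac = cfg.apex_frac if cfg.shape == "single-bump" else 0.5
        y_apex = y_lo + frac * (y_hi - y_lo)
        truths_cobb.append(float(theta))
        truths_apex.append(nearest_level(y_apex))
        truths_ends.append((nearest_level(y_hi), nearest_level(y_lo)))
    return lset, SpineGroundTruth(
        tuple(truths_cobb), tuple(truths_apex), tuple(truths_ends)
    )


def generate_bending_set(
    cfg: SpineSimConfig, flexibility: float, seed: int | None = 0
) -> tuple[LandmarkSet, SpineGroundTruth]:
    """Side-bending companion of a standing spine: the same geometry with
    every true Cobb angle scaled by (1 - flexibility/100)."""
    if not 0 <= flexibility <= 100:
        raise SimulationError("flexibility must be in [0, 100]")
    scale = 1.0 - flexibility / 100.0
    bent = SpineSimConfig(
        **{
            **cfg.__dict__,
            "cobb": cfg.cobb * scale,
            "cobb2": cfg.cobb2 * scale,
            "view": "side-bending-left",
        }
    )
    return generate_spine_landmarks(bent, seed)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: Continuous marginals: name -> (mean, sd, low, high). Truncated-normal
#: targets emulating a surgical AIS cohort. The apex wedge angle and
#: flexibility targets are anchored on the plausible clinical ranges
#: (wedge 0-21 deg; flexibility 5-99%), with SDs from the same cohort.
DEFAULT_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "initial_major_cobb": (48.9, 13.9, 10.9, 99.5),
    "initial_thoracic_kyphosis": (24.2, 10.9, 0.0, 51.3),
    "initial_lumbar_lordosis": (53.6, 12.1, 3.4, 87.1),
    "age_first_visit": (12.7, 1.7, 10.0, 17.8),
    "time_span": (0.9, 1.0, 0.08, 6.5),
    "apex_wedge_angle": (10.5, 4.1, 0.0, 21.0),
    "flexibility": (57.0, 19.3, 5.0, 99.0),
    "apex_axial_rotation": (20.9, 7.9, 0.02, 41.6),
}

#: Categorical marginals: name -> {value: count} (normalised internally).
DEFAULT_CATEGORICAL: dict[str, dict] = {
    "gender": {"F": 169, "M": 24},
    "lenke_type": {1: 116, 2: 11, 3: 38, 4: 1, 5: 15, 6: 12},
    "brace_status": {"brace": 143, "no-brace": 50},
    "apex_location": {
        "T6": 3, "T7": 14, "T8": 59, "T9": 61, "T10": 17,
        "T11": 7, "T12": 8, "L1": 14, "L2": 9, "L3": 1,
    },
    "levels_involved": {4: 2, 5: 7, 6: 44, 7: 76, 8: 44, 9: 12, 10: 8},
    "risser_plus": dict(zip(RISSER_GRADES, (74, 38, 10, 14, 13, 12, 16, 16))),
}

#: Standardised progression effects (degrees of final-Cobb change per SD of
#: the feature), ordered initial Cobb >> flexibility > lordosis ~ kyphosis
#: ~ age-at-last-visit > levels involved > Risser stage. Flexible and
#: skeletally mature curves progress less, hence the negative signs.
DEFAULT_EFFECTS: dict[str, float] = {
    "initial_major_cobb": 4.0,
    "flexibility": -2.0,
    "initial_lumbar_lordosis": 1.0,
    "initial_thoracic_kyphosis": 0.9,
    "age_last_visit": 0.8,
    "levels_involved": 0.6,
    "risser_plus": -0.45,
}

#: Mean progression (deg) of the emulated cohort (final 59.4 - initial 48.9).
DEFAULT_PROGRESSION_MEAN = 10.5


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator settings.

    ``effects`` are standardised coefficients (degrees per SD) of the
    linear progression model; ``sigma`` is the outcome noise SD in degrees;
    ``clip_floor`` floors the final Cobb angle (surgical-cohort floor;
    ``None`` disables, e.g. for exact coefficient-recovery checks).
    ``interaction`` optionally adds an initial-Cobb x flexibility term.
    """

    n_patients: int = 193
    continuous: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS)
    )
    categorical: Mapping[str, Mapping] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORICAL)
    )
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    progression_mean: float = DEFAULT_PROGRESSION_MEAN
    sigma: float = 4.0
    clip_floor: float | None = 25.0
    interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise SimulationError("cohort size must be >= 20")
        if not self.sigma > 0:
            raise SimulationError("outcome noise SD must be > 0")
        for name, (mean, sd, lo, hi) in self.continuous.items():
            if not (sd > 0 and lo < hi):
                raise SimulationError(f"{name}: infeasible truncation bounds")


def _truncnorm_sample(rng, mean, sd, lo, hi, n):
    """Exact inverse-CDF truncated-normal sampling (seedable)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)


def _categorical_stats(freq: Mapping) -> tuple[float, float]:
    vals = np.array([_numeric_cat(k) for k in freq], dtype=float)
    p = np.array(list(freq.values()), dtype=float)
    p = p / p.sum()
    m = float(np.sum(vals * p))
    v = float(np.sum(p * (vals - m) ** 2))
    return m, math.sqrt(v) if v > 0 else 1.0


_STR_CODES = {"F": 0.0, "M": 1.0, "no-brace": 0.0, "brace": 1.0}


def _numeric_cat(value) -> float:
    from .features import encode_risser_plus
    from .geometry import level_index

    if isinstance(value, str):
        if value in _STR_CODES:
            return _STR_CODES[value]
        if value in RISSER_GRADES:
            return float(encode_risser_plus(value))
        if value[0] in "TL" and value[1:].isdigit():
            return float(level_index(value))
    return float(value)


def generate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(), seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort table plus its generating ground truth.

    Continuous features come from truncated normals (inverse-CDF, exact);
    categoricals from the configured frequencies; the age at last visit is
    derived as age at first visit + time span. The outcome is

        final = initial + progression_mean + sum_i beta_i z_i
                [+ interaction * z_cobb * z_flex] + eps,   eps ~ N(0, sigma),

    with z the features standardised by their configured marginal mean/SD,
    optionally floored at ``clip_floor``. Returns (cohort DataFrame in
    human-readable units, truth dict with the standardised and raw-scale
    coefficients, intercept, sigma, and per-feature standardisation).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    cols: dict[str, np.ndarray | list] = {}
    for name, (mean, sd, lo, hi) in cfg.continuous.items():
        cols[name] = _truncnorm_sample(rng, mean, sd, lo, hi, n)
    for name, freq in cfg.categorical.items():
        keys = list(freq)
        p = np.array([freq[k] for k in keys], dtype=float)
        p = p / p.sum()
        draw = rng.choice(len(keys), size=n, p=p)
        cols[name] = [keys[i] for i in draw]
    cols["age_last_visit"] = cols["age_first_visit"] + cols["time_span"]

    # standardisation constants per feature (configured, not sample, values)
    scale: dict[str, tuple[float, float]] = {}
    for name, (mean, sd, _lo, _hi) in cfg.continuous.items():
        scale[name] = (mean, sd)
    af_m, af_s = cfg.continuous["age_first_visit"][:2]
    ts_m, ts_s = cfg.continuous["time_span"][:2]
    scale["age_last_visit"] = (af_m + ts_m, math.hypot(af_s, ts_s))
    for name, freq in cfg.categorical.items():
        scale[name] = _categorical_stats(freq)

    def z(name: str) -> np.ndarray:
        vals = cols[name]
        if isinstance(vals, list):
            vals = np.array([_numeric_cat(v) for v in vals])
        m, s = scale[name]
        return (np.asarray(vals, dtype=float) - m) / s

    delta = np.full(n, float(cfg.progression_mean))
    for name, beta in cfg.effects.items():
        delta = delta + beta * z(name)
    if cfg.interaction:
        delta = delta + cfg.interaction * z("initial_major_cobb") * z("flexibility")
    eps = rng.normal(0.0, cfg.sigma, n)
    final = np.asarray(cols["initial_major_cobb"], dtype=float) + delta + eps
    if cfg.clip_floor is not None:
        final = np.maximum(final, cfg.clip_floor)

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for name in FEATURE_NAMES:
        df[name] = cols[name]
    df["final_major_cobb"] = final

    raw_betas = {
        name: beta / scale[name][1] for name, beta in cfg.effects.items()
    }
    truth = {
        "effects_std": dict(cfg.effects),
        "effects_raw": raw_betas,
        "progression_mean": cfg.progression_mean,
        "sigma": cfg.sigma,
        "interaction": cfg.interaction,
        "standardisation": {k: list(v) for k, v in scale.items()},
        "clip_floor": cfg.clip_floor,
    }
    return df, truth


def inject_null_features(
    table: pd.DataFrame, m: int, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Append ``m`` independent standard-normal columns uncorrelated with
    the outcome by construction; returns (augmented table, null names)."""
    if m < 1:
        raise SimulationError("m must be >= 1")
    rng = np.random.default_rng(seed)
    out = table.copy()
    names = []
    for j in range(m):
        name = f"null_{j}"
        out[name] = rng.standard_normal(len(table))
        names.append(name)
    return out, names


def cohort_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric (X, y, column names) from a cohort table: the fixed
    15-feature encoding plus any injected extra columns, target
    ``final_major_cobb``."""
    extra = [
        c
        for c in df.columns
        if c not in FEATURE_NAMES and c not in ("patient_id", "final_major_cobb")
    ]
    names = list(FEATURE_NAMES) + extra
    cols = []
    for name in names:
        vals = df[name]
        if vals.dtype == object:
            cols.append(np.array([_numeric_cat(v) for v in vals], dtype=float))
        else:
            cols.append(np.asarray(vals, dtype=float))
    X = np.column_stack(cols)
    y = np.asarray(df["final_major_cobb"], dtype=float)
    return X, y, names
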