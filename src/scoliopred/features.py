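"""Clinical feature encodings for curve-progression modelling.

Derives the standard clinical quantities used as model inputs: bending
flexibility, the structural-curve rule (minor Cobb >= 80% of the major),
the six-type modified Lenke curve classification, the eight-grade
Risser "+" skeletal-maturity ordinal, and the fixed 15-element numeric
feature vector (with the final major Cobb angle as regression target).

The feature-index map is fixed and shared by every consumer (feature
selection, model training, prediction):

====  =================================  =========
idx   feature                            type
====  =================================  =========
0     initial lumbar lordosis (deg)      continuous
1     initial thoracic kyphosis (deg)    continuous
2     age at first visit (yr)            continuous
3     age at last visit (yr)             continuous
4     time span (yr)                     continuous
5     apex wedge angle (deg)             continuous
6     Lenke type (1-6)                   nominal
7     flexibility (%)                    continuous
8     apex axial rotation (deg)          continuous
9     initial major Cobb (deg)           continuous
10    brace status (no-brace 0/brace 1)  nominal
11    gender (F 0 / M 1)                 nominal
12    levels involved (count)            ordinal
13    apex location (T1 0 ... L5 16)     ordinal
14    Risser "+" grade (ordinal 0-7)     ordinal
====  =================================  =========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import SPINAL_LEVELS, CurveMeasure, level_index

__all__ = [
    "FEATURE_NAMES",
    "CONTINUOUS_FEATURES",
    "NOMINAL_FEATURES",
    "ORDINAL_FEATURES",
    "RISSER_GRADES",
    "PatientRecord",
    "FeatureEncodingError",
    "UnclassifiableCurveError",
    "flexibility",
    "is_structural",
    "structural_flags",
    "curve_region",
    "mlenke_type",
    "encode_risser_plus",
    "decode_risser_plus",
    "build_feature_vector",
    "decode_feature_vector",
]

FEATURE_NAMES: tuple[str, ...] = (
    "initial_lumbar_lordosis",
    "initial_thoracic_kyphosis",
    "age_first_visit",
    "age_last_visit",
    "time_span",
    "apex_wedge_angle",
    "lenke_type",
    "flexibility",
    "apex_axial_rotation",
    "initial_major_cobb",
    "brace_status",
    "gender",
    "levels_involved",
    "apex_location",
    "risser_plus",
)

CONTINUOUS_FEATURES = (0, 1, 2, 3, 4, 5, 7, 8, 9)
NOMINAL_FEATURES = (6, 10, 11)
ORDINAL_FEATURES = (12, 13, 14)

#: Risser "+" grades in increasing maturity order: open triradiate
#: cartilage, closed TRC, then iliac-apophysis coverage quartiles, start of
#: fusion, complete fusion.
RISSER_GRADES: tuple[str, ...] = ("0-", "0+", "1", "2", "3", "3/4", "4", "5")
_RISSER_CODE = {g: i for i, g in enumerate(RISSER_GRADES)}

_GENDER_CODE = {"F": 0, "M": 1}
_BRACE_CODE = {"no-brace": 0, "brace": 1}

#: Default apex bands of the modified Lenke regions (configurable).
DEFAULT_REGION_BANDS = {
    "proximal-thoracic": ("T2", "T5"),
    "main-thoracic": ("T6", "T11"),
    "thoracolumbar/lumbar": ("T12", "L4"),
}


class FeatureEncodingError(ValueError):
    """Invalid or incomplete clinical feature input."""


class UnclassifiableCurveError(FeatureEncodingError):
    """Structural-curve pattern matches no modified Lenke type."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's raw (human-readable) clinical record.

    Continuous angles in degrees, ages in years, flexibility in percent;
    categorical fields in their clinical vocabulary (gender "F"/"M", brace
    "brace"/"no-brace", Risser as one of :data:`RISSER_GRADES`, apex as a
    spinal level). ``final_major_cobb`` is the regression target.
    """

    patient_id: str
    initial_lumbar_lordosis: float
    initial_thoracic_kyphosis: float
    age_first_visit: float
    age_last_visit: float
    time_span: float
    apex_wedge_angle: float
    lenke_type: int
    flexibility: float
    apex_axial_rotation: float
    initial_major_cobb: float
    brace_status: str
    gender: str
    levels_involved: int
    apex_location: str
    risser_plus: str
    final_major_cobb: float

    def __post_init__(self) -> None:
        num = (
            self.initial_lumbar_lordosis,
            self.initial_thoracic_kyphosis,
            self.age_first_visit,
            self.age_last_visit,
            self.time_span,
            self.apex_wedge_angle,
            self.flexibility,
            self.apex_axial_rotation,
            self.initial_major_cobb,
            self.final_major_cobb,
        )
        if any(v is None or not np.isfinite(v) for v in num):
            raise FeatureEncodingError(f"{self.patient_id}: missing/non-finite value")
        if not self.time_span > 0:
            raise FeatureEncodingError(f"{self.patient_id}: time span must be > 0")
        if abs((self.age_last_visit - self.age_first_visit) - self.time_span) > 0.05:
            raise FeatureEncodingError(
                f"{self.patient_id}: time span inconsistent with visit ages"
            )
        if not 0 <= self.flexibility <= 100:
            raise FeatureEncodingError(f"{self.patient_id}: flexibility outside [0, 100]")
        if self.levels_involved < 2:
            raise FeatureEncodingError(f"{self.patient_id}: levels involved must be >= 2")
        if self.lenke_type not in range(1, 7):
            raise FeatureEncodingError(f"{self.patient_id}: Lenke type must be 1-6")
        if self.gender not in _GENDER_CODE:
            raise FeatureEncodingError(f"{self.patient_id}: gender must be F or M")
        if self.brace_status not in _BRACE_CODE:
            raise FeatureEncodingError(
                f"{self.patient_id}: brace status must be 'brace' or 'no-brace'"
            )
        level_index(self.apex_location)
        encode_risser_plus(self.risser_plus)


def flexibility(standing_cobb: float, bending_cobb: float) -> float:
    """Curve flexibility: percent reduction of the Cobb angle from the
    standing to the side-bending radiograph, 100*(standing-bending)/standing,
    clipped to [0, 100]."""
    if not standing_cobb > 0:
        raise FeatureEncodingError("standing Cobb must be > 0 to compute flexibility")
    if bending_cobb < 0:
        raise FeatureEncodingError("bending Cobb must be >= 0")
    if bending_cobb > standing_cobb:
        warnings.warn(
            "bending Cobb exceeds standing Cobb; flexibility clipped to 0%",
            stacklevel=2,
        )
    return float(np.clip(100.0 * (standing_cobb - bending_cobb) / standing_cobb, 0.0, 100.0))


def is_structural(major_cobb: float, minor_cobb: float) -> bool:
    """A minor curve is structural when its Cobb angle is >= 80% of the
    major curve's (boundary inclusive)."""
    if not 0 < minor_cobb <= major_cobb:
        raise FeatureEncodingError(
            f"expected 0 < minor ({minor_cobb}) <= major ({major_cobb}); "
            "curves may be mislabeled"
        )
    return minor_cobb >= 0.8 * major_cobb


def structural_flags(curves: Sequence[CurveMeasure]) -> list[bool]:
    """Structural flag per curve: the major curve is always structural; a
    minor curve is structural iff its Cobb is >= 80% of the major's."""
    if not curves:
        raise FeatureEncodingError("no curves supplied")
    majors = [c for c in curves if c.major]
    if len(majors) != 1:
        raise FeatureEncodingError("exactly one curve must be flagged major")
    major = majors[0]
    return [c.major or is_structural(major.cobb, c.cobb) for c in curves]


def curve_region(
    apex: str, bands: dict[str, tuple[str, str]] | None = None
) -> str:
    """Region of a curve from its apical level: proximal-thoracic (T2-T5),
    main-thoracic (T6-T11) or thoracolumbar/lumbar (T12-L4) by default."""
    idx = level_index(apex)
    for region, (lo, hi) in (bands or DEFAULT_REGION_BANDS).items():
        if level_index(lo) <= idx <= level_index(hi):
            return region
    raise FeatureEncodingError(
        f"apex {apex} falls outside every configured region band"
    )


def mlenke_type(
    curves: Sequence[CurveMeasure],
    structural: Sequence[bool] | None = None,
    bands: dict[str, tuple[str, str]] | None = None,
) -> int:
    """Modified Lenke type (1-6) from the structural curves' regions.

    1 main thoracic only; 2 double thoracic (PT+MT); 3 double major with
    the thoracic curve dominant; 4 triple major; 5 thoracolumbar/lumbar
    only; 6 double major with the thoracolumbar/lumbar curve dominant.
    A Cobb tie between MT and TL/L structural curves resolves to type 3.
    Patterns outside these six (e.g. proximal-thoracic alone) raise
    :class:`UnclassifiableCurveError`.
    """
    if structural is None:
        structural = structural_flags(curves)
    if len(structural) != len(curves):
        raise FeatureEncodingError("one structural flag required per curve")
    # largest structural Cobb per region
    by_region: dict[str, float] = {}
    for c, s in zip(curves, structural):
        if not s:
            continue
        r = curve_region(c.apex, bands)
        by_region[r] = max(by_region.get(r, 0.0), c.cobb)
    pt = "proximal-thoracic" in by_region
    mt = "main-thoracic" in by_region
    tl = "thoracolumbar/lumbar" in by_region
    if mt and not pt and not tl:
        return 1
    if pt and mt and not tl:
        return 2
    if pt and mt and tl:
        return 4
    if tl and not pt and not mt:
        return 5
    if mt and tl and not pt:
        if by_region["main-thoracic"] >= by_region["thoracolumbar/lumbar"]:
            return 3
        return 6
    raise UnclassifiableCurveError(
        f"structural pattern {sorted(by_region)} matches no modified Lenke type"
    )


def encode_risser_plus(grade: str) -> int:
    """Ordinal code 0-7 of a Risser "+" grade string (whitespace-tolerant)."""
    key = str(grade).strip()
    if key not in _RISSER_CODE:
        raise FeatureEncodingError(
            f"unknown Risser \"+\" grade {grade!r}; expected one of {RISSER_GRADES}"
        )
    return _RISSER_CODE[key]


def decode_risser_plus(code: int) -> str:
    if code not in range(len(RISSER_GRADES)):
        raise FeatureEncodingError(f"Risser ordinal code out of range: {code}")
    return RISSER_GRADES[code]


def build_feature_vector(rec: PatientRecord) -> tuple[np.ndarray, float]:
    """Encode a record as the fixed 15-element numeric vector plus target.

    Continuous features pass through unchanged; gender F->0/M->1, brace
    no-brace->0/brace->1, Lenke type as its 1-6 label, apex location as the
    cranio-caudal ordinal (T1->0 ... L5->16), Risser via its 0-7 ordinal.
    """
    vec = np.array(
        [
            rec.initial_lumbar_lordosis,
            rec.initial_thoracic_kyphosis,
            rec.age_first_visit,
            rec.age_last_visit,
            rec.time_span,
            rec.apex_wedge_angle,
            float(rec.lenke_type),
            rec.flexibility,
            rec.apex_axial_rotation,
            rec.initial_major_cobb,
            float(_BRACE_CODE[rec.brace_status]),
            float(_GENDER_CODE[rec.gender]),
            float(rec.levels_involved),
            float(level_index(rec.apex_location)),
            float(encode_risser_plus(rec.risser_plus)),
        ],
        dtype=float,
    )
    return vec, float(rec.final_major_cobb)


def decode_feature_vector(
    vec: np.ndarray, target: float, patient_id: str = "decoded"
) -> PatientRecord:
    """Inverse of :func:`build_feature_vector` (encodings are bijective)."""
    v = np.asarray(vec, dtype=float)
    if v.shape != (len(FEATURE_NAMES),):
        raise FeatureEncodingError(f"expected a {len(FEATURE_NAMES)}-vector")
    gender = {v: k for k, v in _GENDER_CODE.items()}[int(v[11])]
    brace = {v: k for k, v in _BRACE_CODE.items()}[int(v[10])]
    return PatientRecord(
        patient_id=patient_id,
        initial_lumbar_lordosis=float(v[0]),
        initial_thoracic_kyphosis=float(v[1]),
        age_first_visit=float(v[2]),
        age_last_visit=float(v[3]),
        time_span=float(v[4]),
        apex_wedge_angle=float(v[5]),
        lenke_type=int(v[6]),
        flexibility=float(v[7]),
        apex_axial_rotation=float(v[8]),
        initial_major_cobb=float(v[9]),
        brace_status=brace,
        gender=gender,
        levels_involved=int(v[12]),
        apex_location=SPINAL_LEVELS[int(v[13])],
        risser_plus=decode_risser_plus(int(v[14])),
        final_major_cobb=float(target),
    )
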