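"""Readers, writers, validation, configuration and the pipeline runner.

File formats are deliberately plain:

* Landmark CSV (long format): one row per corner with columns
  ``patient_id, visit, view, level, corner, x, y`` and corner labels
  SL/SR/IR/IL.
* Cohort CSV: one row per patient, columns named exactly after the fixed
  feature map (snake_case) plus ``patient_id`` and ``final_major_cobb``;
  Risser grades and categorical values in their clinical vocabulary.
* Reports and provenance as JSON with sorted keys (byte-reproducible).

Validation collects every failure in a file (with row numbers) and reports
them together; rows failing record invariants are excluded with logged
reasons rather than imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import model as _model
from . import sbfs as _sbfs
from . import simulate as _sim
from .features import FEATURE_NAMES, PatientRecord, FeatureEncodingError, build_feature_vector
from .geometry import CORNER_ORDER, LandmarkSet, VertebraLandmarks, level_index

__all__ = [
    "PipelineConfig",
    "ValidationError",
    "stage_seed",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "records_to_matrix",
    "load_config",
    "save_config",
    "run_pipeline",
]

logger = logging.getLogger("scoliopred")


class ValidationError(ValueError):
    """Input file failed validation; message lists every failure found."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single top-level seed
    (first 4 bytes of sha256("<seed>:<stage>"), masked below 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------

_LANDMARK_COLUMNS = ["patient_id", "visit", "view", "level", "corner", "x", "y"]


def read_landmarks(path) -> list[LandmarkSet]:
    """Read landmark sets from the long-format CSV, grouped by
    (patient, visit, view), corners assembled in SL,SR,IR,IL order.

    All validation failures (missing/duplicate corners, unknown levels or
    corner labels) are collected and raised together with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    errors: list[str] = []
    for row_no, corner in zip(df.index, df["corner"]):
        if corner not in CORNER_ORDER:
            errors.append(f"row {row_no + 2}: unknown corner label {corner!r}")
    for row_no, level in zip(df.index, df["level"]):
        try:
            level_index(str(level))
        except Exception:
            errors.append(f"row {row_no + 2}: unknown level {level!r}")
    sets: list[LandmarkSet] = []
    if not errors:
        for (pid, visit, view), grp in df.groupby(
            ["patient_id", "visit", "view"], sort=True
        ):
            verts = []
            for level, vgrp in sorted(
                grp.groupby("level"), key=lambda kv: level_index(str(kv[0]))
            ):
                corners = {}
                for _, r in vgrp.iterrows():
                    if r["corner"] in corners:
                        errors.append(
                            f"{pid}/{visit}/{view} {level}: duplicate corner {r['corner']}"
                        )
                    corners[r["corner"]] = (float(r["x"]), float(r["y"]))
                absent = [c for c in CORNER_ORDER if c not in corners]
                if absent:
                    errors.append(
                        f"{pid}/{visit}/{view} {level}: missing corner(s) {absent}"
                    )
                    continue
                verts.append(
                    VertebraLandmarks(
                        str(level), np.array([corners[c] for c in CORNER_ORDER])
                    )
                )
            if verts and not errors:
                sets.append(LandmarkSet(str(pid), int(visit), str(view), tuple(verts)))
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(sorted(errors)))
    return sets


def write_landmarks(sets: Sequence[LandmarkSet], path) -> None:
    """Write landmark sets to the canonical long-format CSV."""
    rows = []
    for s in sets:
        for v in s.vertebrae:
            for corner, (x, y) in zip(CORNER_ORDER, v.corners):
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "visit": s.visit,
                        "view": s.view,
                        "level": v.level,
                        "corner": corner,
                        "x": repr(float(x)),
                        "y": repr(float(y)),
                    }
                )
    pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = ["patient_id", *FEATURE_NAMES, "final_major_cobb"]


def read_cohort(path) -> tuple[list[PatientRecord], list[tuple[int, str]]]:
    """Read a cohort CSV into typed records.

    Returns (accepted records, rejections) where each rejection is
    (1-based data row number, reason). Rows violating record invariants
    (unknown Risser grade, inconsistent visit ages, ...) are excluded, the
    count is logged; no imputation is attempted. Unknown or missing columns
    are a hard error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty cohort file")
    unknown = [c for c in df.columns if c not in _COHORT_COLUMNS]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            if row.isna().any():
                bad = list(df.columns[row.isna()])
                raise FeatureEncodingError(f"missing value(s) in {bad}")
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    initial_lumbar_lordosis=float(row["initial_lumbar_lordosis"]),
                    initial_thoracic_kyphosis=float(row["initial_thoracic_kyphosis"]),
                    age_first_visit=float(row["age_first_visit"]),
                    age_last_visit=float(row["age_last_visit"]),
                    time_span=float(row["time_span"]),
                    apex_wedge_angle=float(row["apex_wedge_angle"]),
                    lenke_type=int(row["lenke_type"]),
                    flexibility=float(row["flexibility"]),
                    apex_axial_rotation=float(row["apex_axial_rotation"]),
                    initial_major_cobb=float(row["initial_major_cobb"]),
                    brace_status=str(row["brace_status"]).strip(),
                    gender=str(row["gender"]).strip(),
                    levels_involved=int(row["levels_involved"]),
                    apex_location=str(row["apex_location"]).strip(),
                    risser_plus=str(row["risser_plus"]).strip(),
                    final_major_cobb=float(row["final_major_cobb"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append((int(i) + 1, str(exc)))
    if rejected:
        logger.warning(
            "%s: rejected %d of %d rows", path, len(rejected), len(df)
        )
    return records, rejected


def write_cohort(table: pd.DataFrame | Sequence[PatientRecord], path) -> None:
    """Write a cohort table (DataFrame or records) to the canonical CSV."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([dataclasses.asdict(r) for r in table])
    table.to_csv(path, index=False)


def records_to_matrix(records: Sequence[PatientRecord]):
    """(X, y) numeric matrix/target from typed records (fixed index map)."""
    pairs = [build_feature_vector(r) for r in records]
    X = np.vstack([v for v, _ in pairs])
    y = np.array([t for _, t in pairs])
    return X, y


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; every stage seed derives from ``seed``.

    With ``cohort_csv`` unset, a synthetic cohort of ``n_patients`` is
    generated. SBFS runs on the training split by default
    (``sbfs_on_full_cohort`` mimics selection on all rows instead).
    """

    seed: int = 0
    cohort_csv: str | None = None
    n_patients: int = 193
    cohort_sim: dict = field(default_factory=dict)  # CohortSimConfig overrides
    test_fraction: float = 0.25
    folds: int = 5
    ci_multiplier: float = _sbfs.DEFAULT_CI_MULTIPLIER
    families: tuple[str, ...] = ("rf",)
    rf_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in _model.DEFAULT_GRIDS["rf"].items()})
    sbfs_n_estimators: int = 20
    sbfs_on_full_cohort: bool = False
    min_subset_size: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Features -> split -> SBFS -> grid search -> final fit -> evaluation.

    Writes into ``out_dir``: the (possibly generated) cohort, the SBFS
    trace table, the fitted model bundle, an evaluation report and a
    provenance record (config hash, seed, versions) sufficient to re-run
    bit-identically. Returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for fam in cfg.families:
        if fam not in _model.MODEL_FAMILIES:
            raise ValidationError(f"unknown model family {fam!r}")

    if cfg.cohort_csv:
        records, _ = read_cohort(cfg.cohort_csv)
        X, y = records_to_matrix(records)
        cohort_path = cfg.cohort_csv
    else:
        df, _truth = _sim.generate_cohort(
            _sim.CohortSimConfig(n_patients=cfg.n_patients, **cfg.cohort_sim),
            seed=stage_seed(cfg.seed, "cohort"),
        )
        X, y, _names = _sim.cohort_matrix(df)
        cohort_path = "cohort.csv"  # relative to the run directory
        write_cohort(df, out / cohort_path)

    spec = _model.SplitSpec(cfg.test_fraction, stage_seed(cfg.seed, "split"))
    (Xtr, ytr), (Xte, yte) = _model.split_cohort(X, y, spec)

    sel_X, sel_y = (X, y) if cfg.sbfs_on_full_cohort else (Xtr, ytr)
    sbfs_seed = stage_seed(cfg.seed, "sbfs")

    def rf_factory():
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(
            n_estimators=cfg.sbfs_n_estimators, random_state=sbfs_seed, n_jobs=1
        )

    best, traces = _sbfs.sbfs_select(
        sel_X,
        sel_y,
        rf_factory,
        k=cfg.folds,
        seed=sbfs_seed,
        min_size=cfg.min_subset_size,
        ci_multiplier=cfg.ci_multiplier,
    )
    _sbfs.trace_report(traces).to_csv(out / "traces.csv", index=False)

    subset = list(best.features)
    params, cv_mae_val, _table = _model.grid_search(
        "rf",
        cfg.rf_grid,
        Xtr[:, subset],
        ytr,
        k=cfg.folds,
        seed=stage_seed(cfg.seed, "grid"),
        feature_indices=subset,
    )
    bundle = _model.train_final(
        "rf",
        params,
        Xtr[:, subset],
        ytr,
        seed=stage_seed(cfg.seed, "train"),
        feature_indices=subset,
    )
    _model.save_bundle(bundle, out / "model.bundle")
    report_eval = _model.evaluate(bundle, Xte[:, subset], yte)

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s) for s in ("cohort", "split", "sbfs", "grid", "train")
        },
        "versions": _versions(),
        "cohort": cohort_path,
    }
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "selected_features": subset,
        "selected_feature_names": [
            FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else f"x{i}" for i in subset
        ],
        "sbfs_best_cv_mae": best.mean_mae,
        "rf_hyperparams": {k: v for k, v in sorted(params.items())},
        "grid_cv_mae": cv_mae_val,
        "train_cv_mae": bundle.train_cv_mae,
        "test_mae": report_eval.mae,
        "n_train": int(len(ytr)),
        "n_test": int(len(yte)),
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (out / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=1))
    return report


def headline_test_mae(seed: int, n_patients: int = 193) -> dict:
    """Held-out test MAE of the full default pipeline for one seed.

    Generates the default synthetic cohort, splits 75/25, runs SBFS on the
    training split, grid-tunes the random forest and evaluates on the
    held-out quarter. Returns {"test_mae", "n", "selected_features"}.
    """
    df, _ = _sim.generate_cohort(
        _sim.CohortSimConfig(n_patients=n_patients), seed=stage_seed(seed, "cohort")
    )
    X, y, _names = _sim.cohort_matrix(df)
    spec = _model.SplitSpec(0.25, stage_seed(seed, "split"))
    (Xtr, ytr), (Xte, yte) = _model.split_cohort(X, y, spec)
    sbfs_seed = stage_seed(seed, "sbfs")

    def rf_factory():
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=20, random_state=sbfs_seed, n_jobs=1)

    best, _traces = _sbfs.sbfs_select(Xtr, ytr, rf_factory, k=5, seed=sbfs_seed)
    subset = list(best.features)
    params, _cv, _tbl = _model.grid_search(
        "rf",
        _model.DEFAULT_GRIDS["rf"],
        Xtr[:, subset],
        ytr,
        seed=stage_seed(seed, "grid"),
        feature_indices=subset,
    )
    bundle = _model.train_final(
        "rf", params, Xtr[:, subset], ytr,
        seed=stage_seed(seed, "train"), feature_indices=subset,
    )
    test_mae = _model.mae(yte, bundle.estimator.predict(Xte[:, subset]))
    return {"test_mae": test_mae, "n": n_patients, "selected_features": subset}


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__

    return {
        "scoliopred": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
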