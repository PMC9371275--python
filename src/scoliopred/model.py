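"""Regression models predicting the final major Cobb angle.

Covers the modelling stages downstream of feature selection: a seeded
75/25 cohort split, exhaustive hyperparameter grid search under 5-fold
cross-validated MAE, final model fitting (random forest by default, with
support-vector, neural-network and optional gradient-boosting adapters),
impurity-based feature-importance ranking, held-out evaluation with a
residual histogram, and single-patient prediction with an error band.

Estimators are delegated to scikit-learn; this module owns the pipeline:
index bookkeeping against the fixed 15-feature map, the preprocessing
policy (one-hot + standardisation for distance-based families only), and
deterministic seeding throughout.
"""

from __future__ import annotations

import itertools
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVR

from . import features as _feat
from .sbfs import _make_folds

__all__ = [
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "SplitSpec",
    "ModelBundle",
    "EvaluationReport",
    "PredictionResult",
    "ModelError",
    "split_cohort",
    "mae",
    "grid_search",
    "make_estimator",
    "train_final",
    "feature_importance_rank",
    "compare_models",
    "evaluate",
    "predict_final_cobb",
    "save_bundle",
    "load_bundle",
]

_BUNDLE_VERSION = 1

MODEL_FAMILIES = ("rf", "svm", "ann", "gbr")

#: Default hyperparameter grids. Values sit inside the published tuning
#: ranges for this problem (trees 100-500, max_features 1-7, depth 1-50,
#: min_samples_split 2-11, min_samples_leaf 1-11; SVR epsilon/gamma decades;
#: NN batch size/epochs tens), sampled coarsely so an exhaustive search
#: stays desk-scale.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [100, 300],
        "max_features": [3, 5, 7],
        "max_depth": [30],
        "min_samples_split": [2, 7],
        "min_samples_leaf": [1, 2],
    },
    "svm": {
        "epsilon": [0, 1, 10, 100, 1000],
        "gamma": [1, 0.1, 0.001, 0.0001],
    },
    "ann": {
        "batch_size": [10, 30, 50],
        "epochs": [10, 30, 50],
        "optimizer": ["adam", "sgd"],
    },
    "gbr": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3],
    },
}

#: Hyperparameters used for the tuned random forest when no grid search is
#: wanted (the published selected values for this pipeline).
RF_REFERENCE_PARAMS = {
    "n_estimators": 291,
    "max_features": 5,
    "max_depth": 30,
    "min_samples_split": 7,
    "min_samples_leaf": 2,
}


class ModelError(ValueError):
    """Invalid modelling input or bundle mismatch."""


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: held-out fraction and shuffle seed."""

    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ModelError("test fraction must be in (0, 1)")


@dataclass
class ModelBundle:
    """A fitted model plus everything needed to apply it consistently."""

    family: str
    estimator: object = field(repr=False)
    feature_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    hyperparams: dict
    train_cv_mae: float
    seed: int
    feature_ranges: np.ndarray = field(repr=False)  # (2, n_features) min/max
    importances: np.ndarray | None = field(default=None, repr=False)
    version: int = _BUNDLE_VERSION


@dataclass(frozen=True)
class EvaluationReport:
    """Held-out evaluation: per-patient residuals (predicted - actual, in
    degrees), their MAE, and a residual histogram (2-degree bins)."""

    residuals: np.ndarray
    mae: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray


@dataclass(frozen=True)
class PredictionResult:
    """Point prediction (degrees) with a +/- band equal to the model's
    training cross-validation MAE, plus any out-of-range warnings."""

    prediction: float
    band: float
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Split and metric
# ---------------------------------------------------------------------------


def split_cohort(
    X: np.ndarray, y: np.ndarray, spec: SplitSpec
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffle split into train/test; test gets floor(fraction * n).

    Returns ((X_train, y_train), (X_test, y_test)); membership is disjoint
    and exhaustive and identical for identical seeds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ModelError("need at least 8 samples to split")
    n_test = int(np.floor(spec.test_fraction * n))
    idx = np.random.default_rng(spec.seed).permutation(n)
    te, tr = idx[:n_test], idx[n_test:]
    return (X[tr], y[tr]), (X[te], y[te])


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error (1/n) * sum |y_j - yhat_j| in degrees."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ModelError("targets and predictions must have equal nonzero length")
    return float(np.mean(np.abs(y - yhat)))


# ---------------------------------------------------------------------------
# Estimator construction
# ---------------------------------------------------------------------------


def _preprocessor(feature_indices: Sequence[int] | None, n_features: int):
    """One-hot nominal features and standardise the rest (for distance-based
    families). ``feature_indices`` maps matrix columns to the fixed
    15-feature index space; unknown mapping treats all columns as numeric."""
    if feature_indices is None:
        return StandardScaler()
    nominal_cols = [
        c for c, f in enumerate(feature_indices) if f in _feat.NOMINAL_FEATURES
    ]
    other = [c for c in range(n_features) if c not in nominal_cols]
    return ColumnTransformer(
        [
            ("onehot", OneHotEncoder(handle_unknown="ignore"), nominal_cols),
            ("scale", StandardScaler(), other),
        ]
    )


def make_estimator(
    family: str,
    hyperparams: Mapping,
    seed: int = 0,
    n_features: int | None = None,
    feature_indices: Sequence[int] | None = None,
):
    """Build an unfitted estimator for one model family.

    rf/gbr consume the feature matrix raw; svm/ann are wrapped in a
    preprocessing pipeline (one-hot for nominal features, standardisation
    for the rest). SVR uses an RBF kernel with C=1.0; epsilon 0 is mapped
    to a small positive tube (1e-3). The neural network is a single hidden
    layer of 16 rectified units (batch size / epochs / optimizer tunable).
    """
    hp = dict(hyperparams)
    if family == "rf":
        if n_features is not None and "max_features" in hp and isinstance(hp["max_features"], int):
            hp["max_features"] = min(hp["max_features"], n_features)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if family == "gbr":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if family == "svm":
        eps = float(hp.pop("epsilon", 0.1))
        est = SVR(
            kernel=hp.pop("kernel", "rbf"),
            C=float(hp.pop("C", 1.0)),
            gamma=hp.pop("gamma", "scale"),
            epsilon=max(eps, 1e-3),
            **hp,
        )
    elif family == "ann":
        solver = {"adam": "adam", "sgd": "sgd", "lbfgs": "lbfgs"}[
            hp.pop("optimizer", "adam")
        ]
        est = MLPRegressor(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (16,)),
            solver=solver,
            batch_size=hp.pop("batch_size", "auto"),
            max_iter=int(hp.pop("epochs", 200)),
            random_state=seed,
            **hp,
        )
    else:
        raise ModelError(f"unknown model family {family!r}; expected {MODEL_FAMILIES}")
    nf = n_features if n_features is not None else 0
    return Pipeline(
        [("prep", _preprocessor(feature_indices, nf)), ("model", est)]
    )


# ---------------------------------------------------------------------------
# Grid search and training
# ---------------------------------------------------------------------------


def _cv_mae_estimator(build, X, y, folds) -> float:
    scores = []
    for tr, te in folds:
        est = build()
        est.fit(X[tr], y[tr])
        scores.append(mae(y[te], est.predict(X[te])))
    return float(np.mean(scores))


def grid_search(
    family: str,
    grid: Mapping[str, Sequence],
    X_train: np.ndarray,
    y_train: np.ndarray,
    k: int = 5,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
) -> tuple[dict, float, pd.DataFrame]:
    """Exhaustive Cartesian hyperparameter search under seeded k-fold CV MAE.

    Returns (best parameters, their CV MAE, full results table). Ties go to
    the first combination in deterministic iteration order (sorted parameter
    names, values in listed order). A combination whose estimator fails is
    scored +inf with a warning rather than aborting the search.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ModelError("hyperparameter grid must be non-empty")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    folds = _make_folds(len(y_train), k, seed)
    names = sorted(grid)
    rows = []
    seen: set[tuple] = set()
    best: tuple[float, int, dict] | None = None
    for i, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        params = dict(zip(names, combo))
        eff = dict(params)
        if family == "rf" and isinstance(eff.get("max_features"), int):
            eff["max_features"] = min(eff["max_features"], X_train.shape[1])
        key = tuple(sorted(eff.items()))
        if key in seen:  # clamping can alias combinations
            continue
        seen.add(key)
        try:
            score = _cv_mae_estimator(
                lambda: make_estimator(
                    family, eff, seed, X_train.shape[1], feature_indices
                ),
                X_train,
                y_train,
                folds,
            )
        except Exception as exc:  # noqa: BLE001 - keep the search alive
            warnings.warn(f"{family} failed for {params}: {exc}", stacklevel=2)
            score = float("inf")
        rows.append({**params, "cv_mae": score})
        if best is None or score < best[0]:
            best = (score, i, eff)
    assert best is not None
    return best[2], best[0], pd.DataFrame(rows)


def train_final(
    family: str,
    hyperparams: Mapping,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
    feature_names: Sequence[str] | None = None,
    k: int = 5,
) -> ModelBundle:
    """Fit the final model and package it with its provenance.

    The bundle records the selected feature indices (into the fixed
    15-feature map), the hyperparameters, the training-split CV MAE (used
    as the prediction error band), per-feature training ranges (for
    extrapolation warnings) and, for random forests, the impurity-based
    importances.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if not np.all(np.isfinite(X_train)):
        raise ModelError("non-finite feature values in training matrix")
    if feature_indices is None:
        feature_indices = tuple(range(X_train.shape[1]))
    feature_indices = tuple(int(i) for i in feature_indices)
    if len(feature_indices) != X_train.shape[1]:
        raise ModelError("feature_indices length must match the matrix width")
    if feature_names is None:
        feature_names = tuple(
            _feat.FEATURE_NAMES[i] if i < len(_feat.FEATURE_NAMES) else f"x{i}"
            for i in feature_indices
        )
    folds = _make_folds(len(y_train), k, seed)
    cv = _cv_mae_estimator(
        lambda: make_estimator(family, hyperparams, seed, X_train.shape[1], feature_indices),
        X_train,
        y_train,
        folds,
    )
    est = make_estimator(family, hyperparams, seed, X_train.shape[1], feature_indices)
    est.fit(X_train, y_train)
    importances = None
    if family == "rf":
        imp = np.asarray(est.feature_importances_, dtype=float)
        importances = imp / imp.sum() if imp.sum() > 0 else imp
    return ModelBundle(
        family=family,
        estimator=est,
        feature_indices=feature_indices,
        feature_names=tuple(feature_names),
        hyperparams=dict(hyperparams),
        train_cv_mae=cv,
        seed=seed,
        feature_ranges=np.vstack([X_train.min(axis=0), X_train.max(axis=0)]),
        importances=importances,
    )


def feature_importance_rank(bundle: ModelBundle) -> list[tuple[str, float]]:
    """Impurity-based importances of a random-forest bundle, descending;
    weights are normalised to sum to 1."""
    if bundle.family != "rf" or bundle.importances is None:
        raise ModelError(
            "feature importances are only defined for random-forest bundles"
        )
    order = np.argsort(-bundle.importances, kind="stable")
    return [(bundle.feature_names[i], float(bundle.importances[i])) for i in order]


def compare_models(
    X: np.ndarray,
    y: np.ndarray,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    spec: SplitSpec | None = None,
    seed: int = 0,
    families: Sequence[str] = ("rf", "svm", "ann"),
    feature_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tune and evaluate each model family on a common split.

    For every family: grid search on the training split, final fit, then a
    row of training CV MAE and held-out test MAE. Per-family failures are
    isolated into their row rather than aborting the comparison.
    """
    grids = grids or DEFAULT_GRIDS
    spec = spec or SplitSpec(seed=seed)
    (Xtr, ytr), (Xte, yte) = split_cohort(X, y, spec)
    rows = []
    for family in families:
        try:
            params, _, _ = grid_search(
                family, grids[family], Xtr, ytr, seed=seed, feature_indices=feature_indices
            )
            bundle = train_final(
                family, params, Xtr, ytr, seed=seed, feature_indices=feature_indices
            )
            rows.append(
                {
                    "model": family,
                    "train_cv_mae": bundle.train_cv_mae,
                    "test_mae": mae(yte, bundle.estimator.predict(Xte)),
                }
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-family failures
            warnings.warn(f"model family {family} failed: {exc}", stacklevel=2)
            rows.append({"model": family, "train_cv_mae": np.nan, "test_mae": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation and prediction
# ---------------------------------------------------------------------------


def evaluate(
    bundle: ModelBundle, X: np.ndarray, y: np.ndarray, bin_width: float = 2.0
) -> EvaluationReport:
    """Held-out evaluation: residuals (predicted - actual), MAE and a
    residual histogram with ``bin_width``-degree bins."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(bundle.feature_indices):
        raise ModelError("evaluation matrix width does not match the bundle")
    res = np.asarray(bundle.estimator.predict(X), dtype=float) - y
    lo = bin_width * np.floor(res.min() / bin_width)
    hi = bin_width * np.ceil(res.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(res, bins=edges)
    return EvaluationReport(
        residuals=res, mae=float(np.mean(np.abs(res))), hist_edges=edges, hist_counts=counts
    )


def predict_final_cobb(
    bundle: ModelBundle, record: "_feat.PatientRecord | np.ndarray"
) -> PredictionResult:
    """Predict one patient's final major Cobb angle in degrees.

    Accepts a raw :class:`~scoliopred.features.PatientRecord` (encoded via
    the fixed feature map, then restricted to the bundle's selected
    indices) or an already-encoded vector matching the bundle's features.
    The +/- band is the bundle's training CV MAE. Features outside the
    training range trigger a warning: a forest cannot extrapolate beyond
    the targets it was trained on.
    """
    if isinstance(record, _feat.PatientRecord):
        full, _ = _feat.build_feature_vector(record)
        if max(bundle.feature_indices) >= full.size:
            raise ModelError("bundle feature indices exceed the encoded vector")
        x = full[list(bundle.feature_indices)]
    else:
        x = np.asarray(record, dtype=float)
        if x.shape != (len(bundle.feature_indices),):
            raise ModelError(
                f"expected a vector of {len(bundle.feature_indices)} selected features"
            )
    notes = []
    lo, hi = bundle.feature_ranges
    for name, v, a, b in zip(bundle.feature_names, x, lo, hi):
        if v < a or v > b:
            notes.append(
                f"{name}={v:g} outside training range [{a:g}, {b:g}]; "
                "prediction is an extrapolation"
            )
    pred = float(bundle.estimator.predict(x[None, :])[0])
    return PredictionResult(pred, bundle.train_cv_mae, tuple(notes))


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialise a bundle (versioned pickle with an index-map header)."""
    payload = {
        "format": "scoliopred-bundle",
        "version": bundle.version,
        "feature_indices": list(bundle.feature_indices),
        "feature_names": list(bundle.feature_names),
        "seed": bundle.seed,
        "bundle": bundle,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_bundle(path, expect_feature_names: Sequence[str] | None = None) -> ModelBundle:
    """Load a bundle; refuses version or feature-index-map mismatches."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except Exception as exc:
        raise ModelError(f"{path}: not a scoliopred model bundle ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != "scoliopred-bundle":
        raise ModelError(f"{path}: not a scoliopred model bundle")
    if payload.get("version") != _BUNDLE_VERSION:
        raise ModelError(
            f"{path}: bundle version {payload.get('version')} unsupported "
            f"(expected {_BUNDLE_VERSION})"
        )
    bundle: ModelBundle = payload["bundle"]
    names = [
        _feat.FEATURE_NAMES[i] if i < len(_feat.FEATURE_NAMES) else f"x{i}"
        for i in bundle.feature_indices
    ]
    expected = list(expect_feature_names) if expect_feature_names else names
    if list(bundle.feature_names) != expected:
        raise ModelError(
            f"{path}: bundle feature map {list(bundle.feature_names)} does not "
            f"match the expected map {expected}"
        )
    return bundle
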