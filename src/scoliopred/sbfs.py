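"""Sequential Backward Floating Selection under cross-validated MAE.

Native implementation of SBFS for regression feature selection: starting
from the full feature set, the feature whose removal minimises the 5-fold
cross-validated mean absolute error is excluded at each step; after every
exclusion, previously removed features are conditionally re-included while
doing so strictly improves the best recorded subset of that size. The
subset with the overall minimum CV MAE is selected.

All subsets of one selection run are scored on the same seeded fold
partition (paired comparisons) and subset scores are memoized.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold

__all__ = [
    "DEFAULT_CI_MULTIPLIER",
    "CVResult",
    "SubsetTrace",
    "SBFSError",
    "cv_mae",
    "sbfs_select",
    "trace_report",
    "parse_trace_report",
]

#: Multiplier turning the fold-score SD into the reported confidence bound.
#: The conventional tables this mirrors show a CI/SD ratio of ~1.28
#: (the one-sided 90% normal quantile); configurable everywhere it is used.
DEFAULT_CI_MULTIPLIER = 1.2816


class SBFSError(ValueError):
    """Invalid feature-selection input."""


@dataclass(frozen=True)
class CVResult:
    """Per-fold MAE scores of one subset on one fold partition."""

    fold_maes: tuple[float, ...]
    mean: float
    sd: float  # population SD over the fold scores


@dataclass(frozen=True)
class SubsetTrace:
    """One recorded subset: indices, size and its cross-validated MAE."""

    features: tuple[int, ...]  # sorted ascending
    size: int
    mean_mae: float
    sd_mae: float
    ci_bound: float


def _make_folds(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    if not 2 <= k <= n:
        raise SBFSError(f"need n >= k >= 2 (got n={n}, k={k})")
    return list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))


def _score_subset(X, y, subset, model_factory, folds) -> CVResult:
    cols = list(subset)
    maes = []
    for tr, te in folds:
        model = model_factory()
        model = clone(model) if hasattr(model, "get_params") else model
        model.fit(X[np.ix_(tr, cols)], y[tr])
        pred = np.asarray(model.predict(X[np.ix_(te, cols)]), dtype=float)
        maes.append(float(np.mean(np.abs(y[te] - pred))))
    arr = np.array(maes)
    return CVResult(tuple(maes), float(arr.mean()), float(arr.std(ddof=0)))


def cv_mae(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: Sequence[int],
    model_factory: Callable,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Seeded k-fold cross-validated MAE of a model on a feature subset.

    A fresh model from ``model_factory`` is fitted per fold on the training
    folds restricted to ``feature_subset`` and scored on the held-out fold;
    returns the fold MAEs with their mean and population SD. Deterministic
    given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    subset = sorted(set(int(i) for i in feature_subset))
    if not subset:
        raise SBFSError("feature subset must be non-empty")
    if subset[0] < 0 or subset[-1] >= X.shape[1]:
        raise SBFSError(
            f"subset {subset} references an index outside 0..{X.shape[1] - 1}"
        )
    folds = _make_folds(len(y), k, seed)
    return _score_subset(X, y, subset, model_factory, folds)


def _trace(subset, res: CVResult, ci_multiplier: float) -> SubsetTrace:
    return SubsetTrace(
        features=tuple(sorted(subset)),
        size=len(subset),
        mean_mae=res.mean,
        sd_mae=res.sd,
        ci_bound=ci_multiplier * res.sd,
    )


def _better(a: SubsetTrace, b: SubsetTrace) -> bool:
    """Ordering for best-subset selection: lower MAE, then smaller size,
    then lexicographically smallest index set."""
    return (a.mean_mae, a.size, a.features) < (b.mean_mae, b.size, b.features)


def sbfs_select(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable,
    k: int = 5,
    seed: int = 0,
    min_size: int = 1,
    ci_multiplier: float = DEFAULT_CI_MULTIPLIER,
) -> tuple[SubsetTrace, list[SubsetTrace]]:
    """Run SBFS; returns (best trace, all recorded traces sorted by MAE).

    One trace is recorded per subset size (the best subset found at that
    size). The best overall subset is the recorded trace of minimum mean
    MAE; ties go to the smaller subset, then the lexicographically smallest
    index set. All cross-validation reuses one seeded fold partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise SBFSError("X must have at least one feature")
    if not 1 <= min_size <= p:
        raise SBFSError(f"min_size must be in 1..{p}")
    folds = _make_folds(len(y), k, seed)
    cache: dict[frozenset, CVResult] = {}

    def score(subset: frozenset) -> CVResult:
        if subset not in cache:
            try:
                cache[subset] = _score_subset(X, y, subset, model_factory, folds)
            except Exception as exc:  # noqa: BLE001 - annotate offending subset
                raise SBFSError(
                    f"model failure on subset {tuple(sorted(subset))}: {exc}"
                ) from exc
        return cache[subset]

    best_by_size: dict[int, SubsetTrace] = {}

    def record(subset: frozenset) -> SubsetTrace:
        t = _trace(subset, score(subset), ci_multiplier)
        cur = best_by_size.get(t.size)
        if cur is None or _better(t, cur):
            best_by_size[t.size] = t
        return t

    current = frozenset(range(p))
    record(current)
    while len(current) > min_size:
        # exclusion: drop the feature whose removal minimises CV MAE
        candidates = sorted(current)
        removal = min(
            candidates, key=lambda f: (score(current - {f}).mean, f)
        )
        current = current - {removal}
        record(current)
        # floating inclusion: re-add excluded features while that strictly
        # improves the best recorded subset of the next size up
        while len(current) < p:
            excluded = sorted(set(range(p)) - current)
            g = min(excluded, key=lambda f: (score(current | {f}).mean, f))
            incumbent = best_by_size.get(len(current) + 1)
            if incumbent is not None and score(current | {g}).mean >= incumbent.mean_mae:
                break
            current = current | {g}
            record(current)

    traces = sorted(
        best_by_size.values(), key=lambda t: (t.mean_mae, t.size, t.features)
    )
    return traces[0], traces


def trace_report(
    traces: Sequence[SubsetTrace], ndigits_mae: int = 3, ndigits_sd: int = 2
) -> pd.DataFrame:
    """Ranked subset table, ascending by mean MAE (ties: smaller size first).

    Carries full-precision numeric columns (``mean_mae``, ``sd_mae``,
    ``ci_bound``) alongside a display string formatted to 3 decimals for
    MAE and 2 for SD/CI, so reports round-trip losslessly through CSV.
    """
    if not traces:
        raise SBFSError("no traces to report")
    rows = sorted(traces, key=lambda t: (t.mean_mae, t.size, t.features))
    return pd.DataFrame(
        {
            "n_features": [t.size for t in rows],
            "feature_indices": [",".join(map(str, t.features)) for t in rows],
            "mean_mae": [t.mean_mae for t in rows],
            "sd_mae": [t.sd_mae for t in rows],
            "ci_bound": [t.ci_bound for t in rows],
            "display": [
                f"{t.mean_mae:.{ndigits_mae}f} ({t.sd_mae:.{ndigits_sd}f}) "
                f"CI {t.ci_bound:.{ndigits_sd}f}"
                for t in rows
            ],
        }
    )


def parse_trace_report(report: pd.DataFrame | str) -> list[SubsetTrace]:
    """Inverse of :func:`trace_report` (accepts the DataFrame or its CSV)."""
    df = pd.read_csv(StringIO(report)) if isinstance(report, str) else report
    out = []
    for _, r in df.iterrows():
        feats = tuple(int(t) for t in str(r["feature_indices"]).split(",") if t != "")
        out.append(
            SubsetTrace(
                features=feats,
                size=int(r["n_features"]),
                mean_mae=float(r["mean_mae"]),
                sd_mae=float(r["sd_mae"]),
                ci_bound=float(r["ci_bound"]),
            )
        )
    return out
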