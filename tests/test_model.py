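"""Splitting, grid search, final training, importances and prediction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoliopred.model import (
    DEFAULT_GRIDS,
    RF_REFERENCE_PARAMS,
    ModelError,
    SplitSpec,
    evaluate,
    feature_importance_rank,
    grid_search,
    load_bundle,
    mae,
    make_estimator,
    predict_final_cobb,
    save_bundle,
    split_cohort,
    train_final,
)
from scoliopred.sbfs import _make_folds


def _linear_data(n=120, p=4, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.arange(1, p + 1, dtype=float)
    y = X @ beta + rng.normal(0, sd, n)
    return X, y


# ---------------------------------------------------------------------------
# split_cohort / mae
# ---------------------------------------------------------------------------


def test_split_sizes_disjoint_and_exhaustive():
    X = np.arange(16.0).reshape(8, 2)
    y = np.arange(8.0)
    (Xtr, ytr), (Xte, yte) = split_cohort(X, y, SplitSpec(0.25, seed=1))
    assert len(ytr) == 6 and len(yte) == 2
    assert sorted(np.concatenate([ytr, yte])) == list(map(float, range(8)))


def test_split_is_seed_deterministic():
    X, y = _linear_data(40)
    a = split_cohort(X, y, SplitSpec(0.25, seed=5))
    b = split_cohort(X, y, SplitSpec(0.25, seed=5))
    assert np.array_equal(a[0][1], b[0][1]) and np.array_equal(a[1][1], b[1][1])
    c = split_cohort(X, y, SplitSpec(0.25, seed=6))
    assert not np.array_equal(a[1][1], c[1][1])


def test_split_rejects_bad_fraction():
    with pytest.raises(ModelError):
        SplitSpec(1.5)


@pytest.mark.parametrize(
    "y,yhat,expect",
    [([10, 20], [12, 18], 2.0), ([1, 2, 3], [1, 2, 3], 0.0), ([0, 0, 0], [1, 2, 3], 2.0)],
)
def test_mae_examples(y, yhat, expect):
    assert mae(np.array(y, float), np.array(yhat, float)) == pytest.approx(expect)


def test_mae_rejects_length_mismatch():
    with pytest.raises(ModelError):
        mae(np.zeros(3), np.zeros(4))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(c=st.floats(-100.0, 100.0), seed=st.integers(0, 1000))
def test_mae_paired_translation_invariance(c, seed):
    rng = np.random.default_rng(seed)
    y, yhat = rng.normal(size=10), rng.normal(size=10)
    assert mae(y + c, yhat + c) == pytest.approx(mae(y, yhat), abs=1e-9)


# ---------------------------------------------------------------------------
# grid_search
# ---------------------------------------------------------------------------


def test_one_point_grid_returns_that_point():
    X, y = _linear_data()
    params, score, table = grid_search(
        "rf", {"n_estimators": [20], "max_depth": [5]}, X, y, seed=0
    )
    assert params == {"n_estimators": 20, "max_depth": 5}
    assert np.isfinite(score)
    assert len(table) == 1


def test_grid_search_matches_independent_exhaustive_loop():
    """Oracle: score each combination with an explicit CV loop and take the
    argmin; the search must agree."""
    X, y = _linear_data(n=100, sd=0.5, seed=3)
    grid = {"n_estimators": [1, 60]}
    params, score, _ = grid_search("rf", grid, X, y, k=3, seed=2)
    folds = _make_folds(len(y), 3, 2)
    oracle = {}
    for (n_est,) in itertools.product(grid["n_estimators"]):
        maes = []
        for tr, te in folds:
            est = make_estimator("rf", {"n_estimators": n_est}, 2, X.shape[1])
            est.fit(X[tr], y[tr])
            maes.append(mae(y[te], est.predict(X[te])))
        oracle[n_est] = float(np.mean(maes))
    best = min(oracle, key=oracle.get)
    assert params["n_estimators"] == best == 60  # the bigger forest wins here
    assert score == pytest.approx(oracle[best])


def test_grid_search_is_seed_deterministic():
    X, y = _linear_data(n=60)
    g = {"n_estimators": [10, 30], "min_samples_leaf": [1, 3]}
    assert grid_search("rf", g, X, y, seed=4)[0] == grid_search("rf", g, X, y, seed=4)[0]


def test_grid_search_survives_estimator_failure():
    X, y = _linear_data(n=60)
    with pytest.warns(UserWarning):
        params, score, table = grid_search(
            "rf", {"n_estimators": [20], "max_depth": [-3, 5]}, X, y, seed=0
        )
    assert params["max_depth"] == 5
    assert np.isinf(table["cv_mae"].max())


# ---------------------------------------------------------------------------
# train_final / importances / families
# ---------------------------------------------------------------------------


def test_reference_forest_fits_noise_free_linear_signal():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 7))
    y = X @ np.array([3.0, 2.0, 1.5, 1.0, 0.5, 0.25, 0.1])
    bundle = train_final("rf", RF_REFERENCE_PARAMS, X, y, seed=0)
    assert bundle.train_cv_mae < np.std(y)


def test_constant_target_predicted_exactly():
    X = np.arange(40.0).reshape(20, 2)
    y = np.full(20, 55.0)
    for family in ("rf", "svm"):
        bundle = train_final(family, {} if family == "svm" else {"n_estimators": 10},
                             X, y, seed=0)
        assert mae(y, bundle.estimator.predict(X)) < 0.11  # SVR tube is 1e-3
    rf = train_final("rf", {"n_estimators": 10}, X, y, seed=0)
    assert mae(y, rf.estimator.predict(X)) == pytest.approx(0.0, abs=1e-9)


def test_training_is_seed_deterministic():
    X, y = _linear_data()
    a = train_final("rf", {"n_estimators": 30}, X, y, seed=7)
    b = train_final("rf", {"n_estimators": 30}, X, y, seed=7)
    assert np.array_equal(a.estimator.predict(X), b.estimator.predict(X))
    assert a.train_cv_mae == b.train_cv_mae


def test_importances_normalised_and_ranked():
    X, y = _linear_data(n=300, p=3, sd=0.1, seed=2)  # beta = (1, 2, 3)
    bundle = train_final("rf", {"n_estimators": 100}, X, y, seed=0)
    ranked = feature_importance_rank(bundle)
    weights = np.array([w for _, w in ranked])
    assert weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert all(a >= b for a, b in zip(weights, weights[1:]))
    assert ranked[0][0] == "age_first_visit"  # column 2 carries the largest effect


def test_single_feature_importance_is_one():
    X, y = _linear_data(p=1)
    bundle = train_final("rf", {"n_estimators": 20}, X, y, seed=0)
    assert feature_importance_rank(bundle)[0][1] == pytest.approx(1.0)


def test_importance_requires_random_forest():
    X, y = _linear_data()
    bundle = train_final("svm", {}, X, y, seed=0)
    with pytest.raises(ModelError):
        feature_importance_rank(bundle)


def test_ann_and_gbr_families_fit():
    X, y = _linear_data(n=80)
    for family, hp in (("ann", {"epochs": 50, "optimizer": "adam"}),
                       ("gbr", {"n_estimators": 50})):
        bundle = train_final(family, hp, X, y, seed=0)
        assert np.isfinite(mae(y, bundle.estimator.predict(X)))


def test_non_finite_features_rejected():
    X, y = _linear_data()
    X[0, 0] = np.nan
    with pytest.raises(ModelError):
        train_final("rf", {"n_estimators": 10}, X, y, seed=0)


# ---------------------------------------------------------------------------
# evaluate / predict / bundle IO
# ---------------------------------------------------------------------------


def test_evaluate_consistent_with_batch_prediction():
    X, y = _linear_data(n=100, sd=0.5)
    (Xtr, ytr), (Xte, yte) = split_cohort(X, y, SplitSpec(0.25, seed=0))
    bundle = train_final("rf", {"n_estimators": 50}, Xtr, ytr, seed=0)
    rep = evaluate(bundle, Xte, yte)
    assert rep.mae == pytest.approx(mae(yte, bundle.estimator.predict(Xte)))
    assert rep.hist_counts.sum() == len(yte)
    assert np.all(np.diff(rep.hist_edges) == pytest.approx(2.0))
    preds = [predict_final_cobb(bundle, x).prediction for x in Xte]
    assert mae(yte, np.array(preds)) == pytest.approx(rep.mae)


def test_memorised_training_row_predicted_closely():
    X, y = _linear_data(n=60, sd=0.0, seed=4)
    bundle = train_final(
        "rf", {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1},
        X, y, seed=0,
    )
    res = predict_final_cobb(bundle, X[0])
    assert res.prediction == pytest.approx(y[0], abs=3.0)
    assert res.band == bundle.train_cv_mae


def test_out_of_range_feature_warns_extrapolation():
    X, y = _linear_data(n=60)
    bundle = train_final("rf", {"n_estimators": 10}, X, y, seed=0)
    far = X[0].copy()
    far[1] = X[:, 1].max() + 100.0
    res = predict_final_cobb(bundle, far)
    assert any("outside training range" in w for w in res.warnings)
    assert not predict_final_cobb(bundle, X[0]).warnings


def test_bundle_round_trip_and_mismatch_refusal(tmp_path):
    X, y = _linear_data(p=3)
    bundle = train_final("rf", {"n_estimators": 10}, X, y, seed=0,
                         feature_indices=(0, 7, 9))
    path = tmp_path / "m.bundle"
    save_bundle(bundle, path)
    loaded = load_bundle(path)
    assert loaded.feature_indices == (0, 7, 9)
    assert np.array_equal(loaded.estimator.predict(X), bundle.estimator.predict(X))
    with pytest.raises(ModelError):
        load_bundle(path, expect_feature_names=["a", "b", "c"])
    with pytest.raises(ModelError):
        load_bundle(__file__.replace("test_model.py", "conftest.py"))
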