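import json

import numpy as np
import pytest

import taarip as T
from taarip.classifier import encode_labels, default_lambda_grid
from taarip.synthetic import NORMAL, ABNORMAL


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Unpenalized logistic MLE by iteratively reweighted least squares."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        z = eta + (y - p) / w
        beta_new = np.linalg.solve(Xd.T @ (w[:, None] * Xd), Xd.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


@pytest.fixture(scope="module")
def overlapping_2d():
    """Two overlapping Gaussian classes so the unpenalized MLE is finite."""
    rng = np.random.default_rng(12)
    n = 60
    X0 = rng.normal([0.0, 0.0], 1.0, size=(n, 2))
    X1 = rng.normal([1.5, 1.0], 1.0, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return X, y


def test_unpenalized_fit_matches_irls_oracle(overlapping_2d):
    """At lambda=0 the elastic-net path endpoint is the plain logistic MLE."""
    X, y = overlapping_2d
    model = T.fit_elastic_net(
        X, y, feature_grid_deg=np.array([0.0, 1.0]),
        lambda_grid=np.array([0.0]), n_folds=4, seed=0,
    )
    oracle = irls_logistic(X, y.astype(float))
    assert model.beta0 == pytest.approx(oracle[0], abs=1e-4)
    np.testing.assert_allclose(model.betas, oracle[1:], atol=1e-4)


def test_shrinkage_path_monotone(small_cohort_features):
    """L1 norm and nonzero count both shrink as the penalty grows."""
    X, y, _ = small_cohort_features
    lambdas, coefs = T.coefficient_path(X, y)  # descending lambda
    l1 = np.abs(coefs).sum(axis=1)
    nnz = (np.abs(coefs) > 1e-8).sum(axis=1)
    # ascending lambda order for the monotonicity statement
    l1_up, nnz_up = l1[::-1], nnz[::-1]
    assert np.all(np.diff(l1_up) <= 1e-6 * max(1.0, l1_up.max()))
    assert np.all(np.diff(nnz_up) <= 0)


def test_huge_lambda_shrinks_all_coefficients_to_majority_vote():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 5))
    y = np.r_[np.zeros(20, dtype=int), np.ones(10, dtype=int)]
    model = T.fit_elastic_net(
        X, y, feature_grid_deg=np.arange(5, dtype=float),
        lambda_grid=np.array([1e4]), n_folds=5, seed=0,
    )
    assert np.all(model.betas == 0.0)
    # majority class is normal (code 0)
    _, label = T.predict(model, np.zeros(5))
    assert label == NORMAL


def test_fit_is_deterministic_given_seed(small_cohort_features):
    X, y, _ = small_cohort_features
    a = T.fit_elastic_net(X, y, T.DEFAULT_FEATURE_GRID_DEG, n_folds=4, seed=5)
    b = T.fit_elastic_net(X, y, T.DEFAULT_FEATURE_GRID_DEG, n_folds=4, seed=5)
    assert a.lambda_selected == b.lambda_selected
    np.testing.assert_array_equal(a.betas, b.betas)


def test_one_se_rule_picks_largest_qualifying_lambda(small_cohort_features):
    X, y, _ = small_cohort_features
    m_1se = T.fit_elastic_net(X, y, T.DEFAULT_FEATURE_GRID_DEG, n_folds=4, seed=5, rule="1se")
    m_min = T.fit_elastic_net(X, y, T.DEFAULT_FEATURE_GRID_DEG, n_folds=4, seed=5, rule="min")
    assert m_1se.lambda_selected >= m_min.lambda_selected
    lams = np.array([l for l, _, _ in m_1se.cv_curve])
    means = np.array([m for _, m, _ in m_1se.cv_curve])
    ses = np.array([s for _, _, s in m_1se.cv_curve])
    cutoff = means.min() + ses[np.argmin(means)]
    qualifying = lams[means <= cutoff]
    assert m_1se.lambda_selected == qualifying.max()


def test_fit_input_validation():
    X = np.ones((4, 2))
    with pytest.raises(ValueError):
        T.fit_elastic_net(X, [NORMAL] * 4, np.arange(2.0))
    with pytest.raises(ValueError):
        T.fit_elastic_net(X, [NORMAL, NORMAL, NORMAL, ABNORMAL], np.arange(2.0))
    Xn = X.copy()
    Xn[0, 0] = np.nan
    with pytest.raises(ValueError):
        T.fit_elastic_net(Xn, [NORMAL, NORMAL, ABNORMAL, ABNORMAL], np.arange(2.0))
    with pytest.raises(ValueError):
        T.fit_elastic_net(X, [NORMAL, NORMAL, ABNORMAL, ABNORMAL], np.arange(2.0),
                          n_folds=10)
    with pytest.raises(ValueError):
        encode_labels(["bogus"])


def test_predict_null_model_and_length_mismatch():
    model = T.ClassifierModel(
        beta0=0.0, betas=np.zeros(3), alpha=0.5, lambda_selected=1.0,
        feature_grid_deg=np.array([0.0, 5.0, 10.0]),
        cv_curve=[(1.0, 0.5, 0.1)],
    )
    prob, _ = T.predict(model, np.array([50.0, 20.0, 5.0]))
    assert prob == 0.5
    with pytest.raises(ValueError):
        T.predict(model, np.zeros(4))


def test_evaluate_counts_and_structure():
    model = T.ClassifierModel(
        beta0=-1.0, betas=np.array([2.0]), alpha=0.5, lambda_selected=0.1,
        feature_grid_deg=np.array([0.0]), cv_curve=[(0.1, 0.0, 0.0)],
    )
    # 13 clearly-normal and 4 clearly-abnormal one-feature subjects
    X = np.r_[np.full((13, 1), -2.0), np.full((4, 1), 2.0)]
    y = [NORMAL] * 13 + [ABNORMAL] * 4
    res = T.evaluate(model, X, y)
    assert res["accuracy"] == 1.0
    assert res["n_predicted_normal"] == 13
    assert res["n_predicted_abnormal"] == 4
    assert res["n"] == 17

    flipped = T.evaluate(model, -X, y)
    assert flipped["accuracy"] == 0.0
    with pytest.raises(ValueError):
        T.evaluate(model, np.empty((0, 1)), [])


def test_model_json_round_trip_bit_equal(tmp_path, small_cohort_features):
    X, y, _ = small_cohort_features
    model = T.fit_elastic_net(X, y, T.DEFAULT_FEATURE_GRID_DEG, n_folds=4, seed=2)
    path = tmp_path / "model.json"
    T.save_model(model, path)
    back = T.load_model(path)
    assert back.beta0 == model.beta0
    np.testing.assert_array_equal(back.betas, model.betas)
    assert back.lambda_selected == model.lambda_selected
    assert back.cv_curve == [tuple(r) for r in model.cv_curve]


def test_load_model_corrupt_and_missing_field(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ValueError):
        T.load_model(bad)
    incomplete = tmp_path / "incomplete.json"
    incomplete.write_text(json.dumps({"beta0": 0.0}))
    with pytest.raises(ValueError, match="missing"):
        T.load_model(incomplete)


def test_lambda_grid_starts_at_full_shrinkage(small_cohort_features):
    X, y, _ = small_cohort_features
    y_codes = encode_labels(y)
    Xs = (X - X.mean(0)) / np.where(X.std(0) == 0, 1.0, X.std(0))
    grid = default_lambda_grid(Xs, y_codes, alpha=0.5)
    assert np.all(np.diff(grid) < 0)
    _, coefs = T.coefficient_path(X, y, lambda_grid=grid)
    assert np.count_nonzero(np.abs(coefs[0]) > 1e-8) == 0  # largest lambda first
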