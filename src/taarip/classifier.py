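"""Elastic-net-regularized logistic classification of breathing patterns.

The classifier scores a subject's ICP feature vector x with a linear
predictor ``beta0 + x.beta`` mapped through the logistic function;
labels are normal (0) / abnormal (1) at a 0.5 probability cut.  With
~37 ICP predictors against cohorts of a few dozen subjects the fit must
be penalized: the elastic net mixes an L1 (sparsity) and L2 (grouping)
penalty, with mixing weight alpha (default 0.5) and overall strength
lambda.

lambda is chosen by stratified k-fold cross-validation (default 10
folds) on misclassification error — not deviance, since the CV curve is
read in error units.  The default selection is the one-standard-error
rule: the largest lambda whose mean CV error is within one standard
error of the minimum, i.e. the most parsimonious model statistically
indistinguishable from the best.  A plain min-error rule is available.

Features are standardized internally before penalization (the ICP
predictors share a 0–100 scale but not a variance); coefficients are
reported back on the original feature scale.  The penalized objective
follows the conventional scaling ``(1/n) sum(loss) + lambda * penalty``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .synthetic import NORMAL, ABNORMAL

logger = logging.getLogger("taarip")

MODEL_SCHEMA_VERSION = 1

LABEL_CODE = {NORMAL: 0, ABNORMAL: 1}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}


@dataclass
class ClassifierModel:
    """Fitted intercept + coefficients with the CV curve that chose lambda.

    ``betas`` are on the original feature scale, one per feature-grid
    angle.  ``cv_curve`` rows are (lambda, mean misclassification error,
    error standard error) along the descending lambda path.
    """

    beta0: float
    betas: np.ndarray
    alpha: float
    lambda_selected: float
    feature_grid_deg: np.ndarray
    cv_curve: list[tuple[float, float, float]]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.feature_grid_deg = np.asarray(self.feature_grid_deg, dtype=float)
        if len(self.betas) != len(self.feature_grid_deg):
            raise ValueError("one coefficient per feature-grid angle required")
        lambdas = {lam for lam, _, _ in self.cv_curve}
        if self.cv_curve and self.lambda_selected not in lambdas:
            raise ValueError("lambda_selected must come from the CV curve")


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map normal/abnormal strings to 0/1 codes."""
    try:
        return np.array([LABEL_CODE[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label: {exc.args[0]!r}") from exc


def default_lambda_grid(
    X_std: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 40, ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced lambda path from the smallest all-zero lambda.

    lambda_max = max |X'(y - ybar)| / (n * max(alpha, 0.05)) is the
    smallest penalty at which every coefficient is zero for the L1 part.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X_std.T @ resid)) / (n * max(alpha, 0.05)))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_at_lambda(
    X_std: np.ndarray, y: np.ndarray, alpha: float, lam: float, tol: float = 1e-6
) -> LogisticRegression:
    """One penalized logistic fit on standardized features.

    Maps the (1/n)·loss + lambda·penalty objective onto scikit-learn's
    C-scaled formulation via C = 1 / (n * lambda).
    """
    n = len(y)
    if lam <= 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=10000, tol=min(tol, 1e-7))
    else:
        clf = LogisticRegression(
            penalty="elasticnet",
            l1_ratio=alpha,
            C=1.0 / (n * lam),
            solver="saga",
            max_iter=50000,
            tol=tol,
            random_state=0,  # saga shuffles per epoch; pin it for determinism
        )
    clf.fit(X_std, y)
    return clf


def fit_elastic_net(
    X: np.ndarray,
    y: Sequence[str] | np.ndarray,
    feature_grid_deg: np.ndarray,
    alpha: float = 0.5,
    lambda_grid: Optional[np.ndarray] = None,
    n_folds: int = 10,
    seed: int = 0,
    rule: Literal["1se", "min"] = "1se",
    threshold: float = 0.5,
) -> ClassifierModel:
    """Cross-validated elastic-net logistic fit over a lambda path.

    For each lambda the stratified k-fold misclassification error is
    computed; lambda is selected by the one-standard-error rule (or the
    min-error rule), and the model is refit on all data at that lambda.
    Fold assignment is seeded, so the whole procedure is deterministic
    given (X, y, seed).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    y_codes = np.asarray(y) if np.issubdtype(np.asarray(y).dtype, np.integer) else encode_labels(y)
    classes, counts = np.unique(y_codes, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if n_folds > counts.min():
        raise ValueError(
            f"{n_folds}-fold stratified CV impossible with minority class of {counts.min()}"
        )

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X_std = (X - mu) / sd

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X_std, y_codes, alpha)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X_std, y_codes))

    cv_curve: list[tuple[float, float, float]] = []
    for lam in lambda_grid:
        fold_err = []
        for tr, te in folds:
            clf = _fit_at_lambda(X_std[tr], y_codes[tr], alpha, lam)
            pred = clf.predict(X_std[te])
            fold_err.append(float(np.mean(pred != y_codes[te])))
        fold_err = np.asarray(fold_err)
        # standard error of the mean CV error across folds
        se = float(fold_err.std(ddof=1) / np.sqrt(n_folds)) if n_folds > 1 else 0.0
        cv_curve.append((float(lam), float(fold_err.mean()), se))

    means = np.array([m for _, m, _ in cv_curve])
    ses = np.array([s for _, _, s in cv_curve])
    i_min = int(np.argmin(means))
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        cutoff = means[i_min] + ses[i_min]
        # path is descending in lambda: the first index meeting the cutoff
        # is the largest qualifying lambda
        i_sel = int(np.flatnonzero(means <= cutoff)[0])
    else:
        raise ValueError(f"unknown selection rule: {rule!r}")
    lam_sel = cv_curve[i_sel][0]

    final = _fit_at_lambda(X_std, y_codes, alpha, lam_sel)
    betas_std = final.coef_.ravel()
    betas = betas_std / sd
    beta0 = float(final.intercept_[0] - np.dot(betas_std, mu / sd))

    logger.info(
        "elastic net: lambda=%.5g (%s rule), %d/%d nonzero coefficients",
        lam_sel, rule, int(np.count_nonzero(betas)), len(betas),
    )
    return ClassifierModel(
        beta0=beta0,
        betas=betas,
        alpha=alpha,
        lambda_selected=float(lam_sel),
        feature_grid_deg=feature_grid_deg,
        cv_curve=cv_curve,
        threshold=threshold,
    )


def coefficient_path(
    X: np.ndarray,
    y: Sequence[str] | np.ndarray,
    alpha: float = 0.5,
    lambda_grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-data coefficients along a descending lambda path.

    Returns ``(lambdas, coefs)`` with one row of standardized-scale
    coefficients per lambda — the shrinkage path whose nonzero count
    drops as lambda grows.
    """
    X = np.asarray(X, dtype=float)
    y_codes = np.asarray(y) if np.issubdtype(np.asarray(y).dtype, np.integer) else encode_labels(y)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X_std = (X - mu) / sd
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X_std, y_codes, alpha)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    coefs = np.array(
        [_fit_at_lambda(X_std, y_codes, alpha, lam).coef_.ravel() for lam in lambda_grid]
    )
    return lambda_grid, coefs


def predict(model: ClassifierModel, x: np.ndarray) -> tuple[float, str]:
    """Probability of abnormal breathing and the thresholded label."""
    x = np.asarray(x, dtype=float)
    if x.shape != model.betas.shape:
        raise ValueError(
            f"feature vector length {x.shape} does not match model {model.betas.shape}"
        )
    score = model.beta0 + float(np.dot(x, model.betas))
    prob = 1.0 / (1.0 + np.exp(-score))
    label = ABNORMAL if prob >= model.threshold else NORMAL
    return prob, label


def evaluate(
    model: ClassifierModel, X_test: np.ndarray, y_test: Sequence[str]
) -> dict:
    """Confusion counts and accuracy on a labelled test set."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    y_codes = encode_labels(y_test)
    preds = np.array([LABEL_CODE[predict(model, x)[1]] for x in X_test])
    tp = int(np.sum((preds == 1) & (y_codes == 1)))
    tn = int(np.sum((preds == 0) & (y_codes == 0)))
    fp = int(np.sum((preds == 1) & (y_codes == 0)))
    fn = int(np.sum((preds == 0) & (y_codes == 1)))
    n = len(y_codes)
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "n": n,
        "n_predicted_normal": tn + fn,
        "n_predicted_abnormal": tp + fp,
        "accuracy": (tp + tn) / n,
    }


def save_model(model: ClassifierModel, path) -> None:
    """Persist a model as JSON with full-precision coefficients."""
    obj = {
        "version": MODEL_SCHEMA_VERSION,
        "beta0": model.beta0,
        "betas": model.betas.tolist(),
        "alpha": model.alpha,
        "lambda_selected": model.lambda_selected,
        "feature_grid_deg": model.feature_grid_deg.tolist(),
        "cv_curve": [list(row) for row in model.cv_curve],
        "threshold": model.threshold,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def load_model(path) -> ClassifierModel:
    """Load a model saved by :func:`save_model`; validates the schema."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt model file {path}: {exc}") from exc
    required = {"version", "beta0", "betas", "alpha", "lambda_selected",
                "feature_grid_deg", "cv_curve", "threshold"}
    missing = required - set(obj)
    if missing:
        raise ValueError(f"model file missing field(s): {sorted(missing)}")
    return ClassifierModel(
        beta0=float(obj["beta0"]),
        betas=np.asarray(obj["betas"], dtype=float),
        alpha=float(obj["alpha"]),
        lambda_selected=float(obj["lambda_selected"]),
        feature_grid_deg=np.asarray(obj["feature_grid_deg"], dtype=float),
        cv_curve=[tuple(row) for row in obj["cv_curve"]],
        threshold=float(obj["threshold"]),
    )
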