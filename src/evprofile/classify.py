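"""Linear discriminant analysis with cross-validated reporting.

The classifier is classical multiclass LDA: class means with a pooled
within-class covariance, regularized by Ledoit-Wolf-style shrinkage
toward a scaled identity (necessary because the size-partitioned
feature count can approach or exceed the sample count).  Class priors
are equal by default — class sizes here are experimental-design
artifacts, not prevalences.  Evaluation aggregates out-of-fold
predictions into an overall accuracy, a probability matrix
(row-normalized prediction frequencies per true class) and per-class
one-vs-rest ROC AUCs computed as Mann-Whitney concordance of the
discriminant scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg, stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold


def _ledoit_wolf_shrinkage(resid: np.ndarray) -> float:
    """Shrinkage intensity toward (trace/F)*I from centered residuals."""
    n, f = resid.shape
    s = resid.T @ resid / n
    mu = np.trace(s) / f
    d2 = float(((s - mu * np.eye(f)) ** 2).sum())
    if d2 == 0:
        return 0.0
    sq = (resid**2).sum(axis=1)
    b2 = float((sq**2).sum() / n**2 - (s**2).sum() / n)
    return float(np.clip(b2 / d2, 0.0, 1.0))


@dataclass
class LDAModel:
    """Fitted discriminant: scores are linear in the features."""

    classes: np.ndarray
    means: np.ndarray  # (C, F)
    covariance: np.ndarray  # (F, F), shrunk pooled within-class
    coef: np.ndarray  # (C, F)
    intercept: np.ndarray  # (C,)
    priors: np.ndarray
    shrinkage: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax breaks exact ties toward the lowest class index
        return self.classes[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)


def fit_lda(
    X: np.ndarray,
    y,
    shrinkage: float | str | None = "ledoit-wolf",
    priors: np.ndarray | None = None,
) -> LDAModel:
    """Fit multiclass LDA with a shrunk pooled within-class covariance.

    ``shrinkage`` is a fixed intensity in [0, 1], ``"ledoit-wolf"`` for the
    data-driven intensity, or ``None`` (forced on anyway when the feature
    count reaches the sample count, where the scatter is singular).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, f = X.shape
    c = len(classes)
    if c < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    means = np.vstack([X[y_idx == i].mean(axis=0) for i in range(c)])
    resid = X - means[y_idx]
    cov = resid.T @ resid / (n - c)
    if shrinkage is None and f >= n:
        shrinkage = "ledoit-wolf"
    if shrinkage == "ledoit-wolf":
        alpha = _ledoit_wolf_shrinkage(resid)
    elif shrinkage is None:
        alpha = 0.0
    else:
        alpha = float(shrinkage)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    mu = np.trace(cov) / f
    cov_reg = (1.0 - alpha) * cov + alpha * mu * np.eye(f)
    cov_reg += 1e-12 * max(mu, 1.0) * np.eye(f)  # numerical floor
    if priors is None:
        priors = np.full(c, 1.0 / c)
    cho = linalg.cho_factor(cov_reg)
    coef = linalg.cho_solve(cho, means.T).T
    intercept = -0.5 * np.einsum("ij,ij->i", means, coef) + np.log(priors)
    return LDAModel(
        classes=classes,
        means=means,
        covariance=cov_reg,
        coef=coef,
        intercept=intercept,
        priors=priors,
        shrinkage=alpha,
    )


def roc_auc_ovr(scores: np.ndarray, labels) -> dict:
    """Per-class one-vs-rest AUC as Mann-Whitney concordance (ties 0.5).

    ``scores`` is (n_samples, n_classes) with column order matching the
    sorted unique labels.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for ROC analysis")
    scores = np.asarray(scores, dtype=float)
    out = {}
    for j, cls in enumerate(classes):
        pos = labels == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        ranks = stats.rankdata(scores[:, j])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        out[cls] = float(auc)
    return out


@dataclass
class ClassificationReport:
    """Aggregated out-of-fold evaluation of an LDA run."""

    accuracy: float
    classes: list
    per_class_recall: dict
    probability_matrix: np.ndarray  # true class x predicted class
    per_class_auc: dict
    scheme: str
    seed: int | None
    n_samples: int

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "accuracy": self.accuracy,
            "classes": [str(c) for c in self.classes],
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "probability_matrix": self.probability_matrix.tolist(),
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "scheme": self.scheme,
            "seed": self.seed,
            "n_samples": self.n_samples,
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def _splits(y, scheme: str, n_folds: int, seed: int | None):
    y = np.asarray(y)
    dummy = np.zeros((len(y), 1))
    if scheme in ("loo", "leave-one-out"):
        return list(LeaveOneOut().split(dummy)), "leave-one-out"
    if scheme in ("kfold", "stratified-kfold"):
        counts = np.bincount(np.unique(y, return_inverse=True)[1])
        if n_folds > counts.min():
            raise ValueError(
                f"{n_folds}-fold CV infeasible: smallest class has {counts.min()}"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(skf.split(dummy, y)), f"stratified-{n_folds}-fold"
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cv_accuracy(X, y, splits, shrinkage="ledoit-wolf") -> float:
    """Out-of-fold accuracy over precomputed splits (fast path for search)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    correct = 0
    for train, test in splits:
        model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        correct += int((model.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def cross_validate(
    X,
    y,
    scheme: str = "loo",
    n_folds: int = 5,
    seed: int | None = 0,
    shrinkage="ledoit-wolf",
) -> ClassificationReport:
    """Cross-validated LDA evaluation with out-of-fold aggregation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    splits, scheme_name = _splits(y, scheme, n_folds, seed)
    preds = np.empty(len(y), dtype=y.dtype)
    scores = np.zeros((len(y), len(classes)))
    for train, test in splits:
        model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        if not np.array_equal(model.classes, classes):
            raise RuntimeError("a fold lost a class; use stratified folds")
        preds[test] = model.predict(X[test])
        # posterior probabilities as per-class scores for the ROC analysis
        scores[test] = model.predict_proba(X[test])
    accuracy = float((preds == y).mean())
    c = len(classes)
    prob = np.zeros((c, c))
    recall = {}
    for i, true_cls in enumerate(classes):
        mask = y == true_cls
        for j, pred_cls in enumerate(classes):
            prob[i, j] = (preds[mask] == pred_cls).mean()
        recall[true_cls] = float(prob[i, i])
    return ClassificationReport(
        accuracy=accuracy,
        classes=list(classes),
        per_class_recall=recall,
        probability_matrix=prob,
        per_class_auc=roc_auc_ovr(scores, y),
        scheme=scheme_name,
        seed=seed,
        n_samples=len(y),
    )
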