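"""Matthews correlation coefficient, cross-validated SVM scoring, and
accuracy-evaluation harnesses.

The MCC of a pooled cross-validated confusion table is the objective the
whole selection procedure optimises.  Folds are stratified by seeded
within-class permutation, and predictions are pooled into a single confusion
table per cross-validation (not averaged per fold).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .datamodel import ExpressionDataset, GeneSubset

# Hyperparameter grid for tuned SVM evaluations: C over powers of 4 spanning
# 2^-5..2^15, gamma over powers of 4 spanning 2^-15..2^3.
DEFAULT_SVM_GRID = {
    "C": [2.0**e for e in range(-5, 16, 4)],
    "gamma": [2.0**e for e in range(-15, 4, 4)],
}

_CLASSIFIERS = ("svm", "lda", "qda", "nb")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion table for a two-class prediction task."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion table.

    Returns (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)); by
    convention exactly 0 whenever any of the four marginal sums is zero
    (the numerator is then zero as well).
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sums = ((tp + fn), (tn + fp), (tp + fp), (tn + fn))
    if any(s == 0 for s in sums):
        return 0.0
    num = tp * tn - fp * fn
    return num / math.sqrt(float(sums[0]) * sums[1] * sums[2] * sums[3])


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for subset scoring.

    ``svm_params`` configures the untuned RBF SVM used inside filtering
    (one cross-validated training per scored subset, no grid search).
    Unless ``svm_params`` fixes gamma explicitly, the kernel width is
    gamma = kernel_width_factor / |subset|.  The factor defaults to 4: at
    the plain 1/|subset| the kernel is nearly linear for the subset sizes
    filtering visits, and purely interacting gene pairs are invisible to
    it; a moderately narrower kernel resolves them while leaving marginal
    effects and noise behaviour unchanged.
    """

    n_folds: int = 5
    seed: int = 0
    stratified: bool = True
    svm_params: dict = field(default_factory=lambda: {"kernel": "rbf", "C": 1.0})
    kernel_width_factor: float = 4.0

    def with_seed(self, seed: int) -> "CVConfig":
        return replace(self, seed=int(seed))

    def resolved_svm_params(self, n_features: int) -> dict:
        params = dict(self.svm_params)
        if "gamma" not in params:
            params["gamma"] = self.kernel_width_factor / max(n_features, 1)
        return params


def subset_seed(master_seed: int, indices: Sequence[int]) -> int:
    """Deterministic sub-seed derived from a master seed and a gene subset.

    Hashing the sorted subset means identical subsets always get identical
    fold partitions within one run, so greedy comparisons are not perturbed
    by CV noise; the result is kept below 2**31.
    """
    key = f"{int(master_seed)}:" + ",".join(str(i) for i in sorted(int(i) for i in indices))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stratified_fold_ids(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified fold assignment; fold sizes differ by at most one."""
    fold_ids = np.empty(len(labels), dtype=int)
    offset = 0
    for cls in (1, -1):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        for j, idx in enumerate(perm):
            fold_ids[idx] = (offset + j) % n_folds
        offset += len(members)
    return fold_ids


def _random_fold_ids(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for j, idx in enumerate(perm):
        fold_ids[idx] = j % n_folds
    return fold_ids


def _make_folds(labels: np.ndarray, cfg: CVConfig, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment; redraws once if a training split lacks a class."""
    for attempt in range(2):
        if cfg.stratified:
            fold_ids = _stratified_fold_ids(labels, cfg.n_folds, rng)
        else:
            fold_ids = _random_fold_ids(len(labels), cfg.n_folds, rng)
        ok = all(
            len(np.unique(labels[fold_ids != f])) == 2 for f in range(cfg.n_folds)
        )
        if ok:
            return fold_ids
    raise RuntimeError(
        "could not form folds whose training splits contain both classes "
        f"(n_folds={cfg.n_folds}); reduce n_folds or use stratified folds"
    )


def _check_cfg(dataset: ExpressionDataset, cfg: CVConfig) -> None:
    if cfg.n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    smaller = min(int(np.sum(dataset.labels == 1)), int(np.sum(dataset.labels == -1)))
    if cfg.stratified and cfg.n_folds > smaller:
        raise ValueError(
            f"n_folds={cfg.n_folds} exceeds the smaller class size {smaller}"
        )


def cv_mcc(dataset: ExpressionDataset, subset: GeneSubset, cfg: CVConfig) -> float:
    """MCC of pooled k-fold cross-validated SVM predictions on a gene subset.

    An empty subset scores 0 by the random-prediction convention (it denotes
    the empty model, which arises legitimately in the significance design).
    """
    _check_cfg(dataset, cfg)
    subset.validate_against(dataset)
    if len(subset) == 0:
        return 0.0
    X = dataset.submatrix(subset.indices)
    y = dataset.labels
    rng = np.random.default_rng(cfg.seed)
    fold_ids = _make_folds(y, cfg, rng)
    y_pred = np.empty_like(y)
    params = cfg.resolved_svm_params(len(subset))
    for f in range(cfg.n_folds):
        test = fold_ids == f
        clf = SVC(**params)
        clf.fit(X[~test], y[~test])
        y_pred[test] = clf.predict(X[test])
    return mcc(ConfusionCounts.from_predictions(y, y_pred))


def _build_classifier(classifier: str, X_train, y_train, tuning_seed: int):
    """Instantiate (and for SVM, tune) a classifier on a training split."""
    if classifier == "svm":
        smaller = min(int(np.sum(y_train == 1)), int(np.sum(y_train == -1)))
        inner = min(5, smaller)
        if inner < 2:
            raise ValueError("inner hyperparameter tuning needs >= 2 samples per class")
        cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=tuning_seed)
        search = GridSearchCV(
            SVC(kernel="rbf"), DEFAULT_SVM_GRID, cv=cv, scoring="accuracy", n_jobs=1
        )
        search.fit(X_train, y_train)
        return search.best_estimator_
    if classifier == "lda":
        if X_train.shape[0] <= X_train.shape[1]:
            raise ValueError(
                f"lda needs more training samples than features "
                f"(subset size {X_train.shape[1]})"
            )
        model = LinearDiscriminantAnalysis()
    elif classifier == "qda":
        smaller = min(int(np.sum(y_train == 1)), int(np.sum(y_train == -1)))
        if smaller <= X_train.shape[1]:
            raise ValueError(
                f"qda needs more samples per class than features "
                f"(subset size {X_train.shape[1]})"
            )
        model = QuadraticDiscriminantAnalysis()
    elif classifier == "nb":
        model = GaussianNB()
    else:
        raise ValueError(f"classifier must be one of {_CLASSIFIERS}")
    model.fit(X_train, y_train)
    return model


def loocv_accuracy(
    dataset: ExpressionDataset,
    subset: GeneSubset,
    classifier: str = "svm",
    seed: int = 0,
) -> float:
    """Leave-one-out accuracy = (TP + TN) / N.

    For the SVM, hyperparameters are re-tuned for every left-out sample by
    an inner stratified 5-fold grid search over the training N-1.
    """
    subset.validate_against(dataset)
    if len(subset) == 0:
        raise ValueError("LOOCV requires a non-empty gene subset")
    y = dataset.labels
    for cls in (1, -1):
        if int(np.sum(y == cls)) < 2:
            raise ValueError("LOOCV needs at least 2 samples in each class")
    X = dataset.submatrix(subset.indices)
    n = len(y)
    correct = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        model = _build_classifier(classifier, X[train], y[train], tuning_seed=seed)
        correct += int(model.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def repeated_kfold_accuracy(
    dataset: ExpressionDataset,
    subset: GeneSubset,
    classifier: str = "svm",
    k: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of pooled k-fold accuracy over repeated random partitions."""
    subset.validate_against(dataset)
    if len(subset) == 0:
        raise ValueError("k-fold evaluation requires a non-empty gene subset")
    X = dataset.submatrix(subset.indices)
    y = dataset.labels
    cfg = CVConfig(n_folds=k, stratified=True)
    _check_cfg(dataset, cfg)
    rng = np.random.default_rng(seed)
    accuracies = []
    for _ in range(n_repeats):
        fold_ids = _make_folds(y, cfg, rng)
        y_pred = np.empty_like(y)
        for f in range(k):
            test = fold_ids == f
            model = _build_classifier(classifier, X[~test], y[~test], tuning_seed=seed)
            y_pred[test] = model.predict(X[test])
        accuracies.append(float(np.mean(y_pred == y)))
    mean = float(np.mean(accuracies))
    sd = float(np.std(accuracies, ddof=1)) if n_repeats > 1 else 0.0
    return mean, sd


def prescreen_ttest(
    dataset: ExpressionDataset, alpha: float = 0.05, equal_var: bool = False
) -> GeneSubset:
    """Univariate two-sample t-test filter: keep genes with p < alpha.

    Welch's unequal-variance test by default (``equal_var=True`` gives the
    pooled version).  Genes with zero variance in both classes get p = 1 and
    are dropped with a warning.  Column order is preserved.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    pos = dataset.matrix[dataset.labels == 1]
    neg = dataset.matrix[dataset.labels == -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both classes; "
            "their p-values are set to 1"
        )
        p[degenerate] = 1.0
    keep = np.flatnonzero(p < alpha)
    return GeneSubset(keep)


def aac(dataset: ExpressionDataset, subset: GeneSubset) -> float:
    """Average absolute pairwise Pearson correlation within a gene subset.

    A redundancy diagnostic: high values mean the retained genes carry
    overlapping information.  Pairs involving zero-variance genes are
    excluded with a warning.
    """
    if len(subset) < 2:
        raise ValueError("AAC needs at least 2 genes")
    X = dataset.submatrix(subset.indices)
    variances = X.var(axis=0)
    valid = variances > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} zero-variance gene(s) excluded from AAC"
        )
    X = X[:, valid]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 genes with positive variance")
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(X.shape[1], k=1)
    return float(np.mean(np.abs(corr[iu])))
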