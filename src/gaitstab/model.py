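"""Severity staging model: standardise, PCA to 4 components, linear SVM,
repeated stratified 5-fold cross-validation with one-vs-rest ROC/AUC.

The four classes are healthy controls and the mild/moderate/severe
dizziness-handicap stages.  To avoid information leaking from validation
subjects into the trained model, standardisation and PCA are by default fit
on the training folds only and applied to the held-out fold; a
``leak_mode`` flag fits them on the full dataset first, for comparison with
analyses that reduce before cross-validating.

ROC/AUC is computed here from first principles (AUC = probability that a
positive outscores a negative, ties counted one half, which equals the
trapezoidal area under the empirical ROC); scikit-learn's implementation
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "pca_reduce",
    "PCAResult",
    "train_linear_svm",
    "roc_curve_points",
    "roc_auc",
    "repeated_stratified_cv",
    "CVReport",
    "CLASS_ORDER",
]

CLASS_ORDER = ("healthy", "mild", "moderate", "severe")


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k) component scores
    loadings: np.ndarray  # (k, p) rows are components
    explained_variance: np.ndarray  # (k,)
    explained_variance_ratio: np.ndarray
    n_components: int
    rank_deficient: bool = False


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: each component's largest-magnitude
    loading is positive."""
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def pca_reduce(matrix: np.ndarray, k: int = 4) -> PCAResult:
    """Project standardised data onto its top-k principal components.

    The caller is responsible for z-scoring the columns (inside
    cross-validation the standardisation must be fit on the training portion
    only).  When the data rank is below ``k``, fewer components are returned
    and the result is flagged.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] <= k:
        raise ValueError(f"need more than {k} rows for a rank-{k} reduction")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k_eff = min(k, rank)
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    _fix_signs(loadings, scores)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_components=k_eff,
        rank_deficient=k_eff < k,
    )


def train_linear_svm(X: np.ndarray, y, C: float = 1.0) -> OneVsRestClassifier:
    """Fit a one-vs-rest linear-kernel SVM exposing per-class decision
    scores via ``decision_function``."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    model = OneVsRestClassifier(SVC(kernel="linear", C=C))
    model.fit(np.asarray(X, dtype=float), y)
    return model


def roc_auc(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties 1/2).

    Computed from midranks (the Mann-Whitney statistic), which equals the
    trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as an (m, 2) array of (FPR, TPR) points, from
    (0, 0) to (1, 1), thresholding at every distinct score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.diff(np.append(-s[order], np.inf)))
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    return np.column_stack([fpr, tpr])


@dataclass
class FoldResult:
    repeat: int
    fold: int
    class_label: str
    auc: float
    roc: np.ndarray  # (m, 2) FPR, TPR


@dataclass
class CVReport:
    """Per-fold one-vs-rest ROC/AUC results of the repeated CV."""

    folds: int
    repeats: int
    seed: int
    results: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def aucs(self, class_label: str) -> np.ndarray:
        return np.array(
            [r.auc for r in self.results if r.class_label == class_label and np.isfinite(r.auc)]
        )

    def summary(self) -> dict:
        """Per-class mean and SD of the per-fold AUCs."""
        out = {}
        for c in sorted({r.class_label for r in self.results}, key=_class_sort_key):
            a = self.aucs(c)
            out[c] = {
                "mean_auc": float(a.mean()) if a.size else float("nan"),
                "sd_auc": float(a.std(ddof=1)) if a.size > 1 else float("nan"),
                "n_folds": int(a.size),
            }
        return out


def _class_sort_key(c):
    return CLASS_ORDER.index(c) if c in CLASS_ORDER else len(CLASS_ORDER)


def _median_impute(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Replace NaNs with training-fold column medians."""
    if not (np.isnan(train).any() or np.isnan(test).any()):
        return train, test, False
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    train = np.where(np.isnan(train), med, train)
    test = np.where(np.isnan(test), med, test)
    return train, test, True


def repeated_stratified_cv(
    X: np.ndarray,
    y,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    k_components: int = 4,
    C: float = 1.0,
    leak_mode: bool = False,
) -> CVReport:
    """Evaluate the PCA + linear-SVM model with repeated stratified k-fold CV.

    Per repeat the cohort is partitioned into ``folds`` stratified folds;
    standardisation and PCA are fit on the training folds (unless
    ``leak_mode``), the one-vs-rest SVM is trained on the reduced training
    data, and per-class ROC/AUC is computed on the held-out fold from the
    continuous decision scores.  Fully reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 members")
    report = CVReport(folds=folds, repeats=repeats, seed=seed)
    if np.any(counts < folds):
        report.warnings.append(
            f"smallest class has {counts.min()} members < {folds} folds; "
            "stratification degrades to fewer distinct folds"
        )

    if leak_mode:
        scaler_all = StandardScaler().fit(X)
        X_leak = scaler_all.transform(X)
        pca_all = PCA(n_components=min(k_components, X.shape[1]), svd_solver="full").fit(X_leak)

    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    for split_idx, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        repeat, fold = divmod(split_idx, folds)
        X_tr, X_te = X[train_idx], X[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        X_tr, X_te, imputed = _median_impute(X_tr, X_te)
        if imputed and "median imputation applied" not in report.warnings:
            report.warnings.append("median imputation applied")
        if leak_mode:
            Z_tr = pca_all.transform(scaler_all.transform(X_tr))
            Z_te = pca_all.transform(scaler_all.transform(X_te))
        else:
            scaler = StandardScaler().fit(X_tr)
            red = pca_reduce(scaler.transform(X_tr), k=k_components)
            Z_tr = red.scores
            Z_te = (scaler.transform(X_te) - scaler.transform(X_tr).mean(axis=0)) @ red.loadings.T
        model = train_linear_svm(Z_tr, y_tr, C=C)
        dec = model.decision_function(Z_te)
        if dec.ndim == 1:  # two-class case
            dec = np.column_stack([-dec, dec])
        for ci, c in enumerate(model.classes_):
            binary = (y_te == c).astype(int)
            if binary.sum() == 0 or binary.sum() == binary.size:
                continue  # fold without both classes: AUC undefined
            scores = dec[:, ci]
            report.results.append(
                FoldResult(
                    repeat=repeat,
                    fold=fold,
                    class_label=str(c),
                    auc=roc_auc(scores, binary),
                    roc=roc_curve_points(scores, binary),
                )
            )
    return report
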