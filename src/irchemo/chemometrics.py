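"""Multivariate classification of preprocessed spectra.

Implements the study-style workflow: a stratified 70/30 train/test split,
PCA, linear discriminant analysis in a truncated PC space (PCA-LDA), and an
RBF-kernel support vector machine whose cost/gamma pair is selected by
venetian-blinds cross-validation, plus per-class quality parameters
(one-vs-rest accuracy, sensitivity and specificity in percent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .spectra_io import SpectrumSet

__all__ = [
    "SplitConfig",
    "SVMConfig",
    "PCAResult",
    "PCALDAModel",
    "SVMModel",
    "ClassMetrics",
    "split_train_test",
    "venetian_blinds_folds",
    "fit_pca",
    "fit_pca_lda",
    "tune_train_svm",
    "evaluate_classifier",
    "metrics_from_confusion",
]

DEFAULT_GRID = tuple(10.0 ** k for k in range(-3, 4))


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.absorbance
    return np.atleast_2d(np.asarray(data, dtype=float))


@dataclass
class SplitConfig:
    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    cost_grid: Sequence[float] = DEFAULT_GRID
    gamma_grid: Sequence[float] = DEFAULT_GRID
    cv_splits: int = 10
    cv_scheme: str = "venetian_blinds"

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("cost/gamma grids must be non-empty")
        if any(v <= 0 for v in list(self.cost_grid) + list(self.gamma_grid)):
            raise ValueError("cost and gamma values must be positive")
        if self.cv_splits < 2:
            raise ValueError("cv_splits must be >= 2")
        if self.cv_scheme != "venetian_blinds":
            raise ValueError(f"unknown cv scheme {self.cv_scheme!r}")


def split_train_test(sset: SpectrumSet, cfg: SplitConfig,
                     label_field: str = "plant_type"):
    """Split into train/test with ``|train| = floor(train_fraction * n)``.

    Stratification uses the given metadata field; the per-class rounding is
    reconciled so the global training count is exact.  Deterministic for a
    fixed seed.
    """
    n = sset.n_spectra
    if n < 2:
        raise ValueError("need at least 2 spectra to split")
    # floor of the exact product; guard against binary-float droop
    # (0.7 * 1580 evaluates below 1106 in double precision).
    n_train = math.floor(cfg.train_fraction * n + 1e-9)
    n_train = min(max(n_train, 1), n - 1)
    if cfg.stratified:
        labels = sset.labels(label_field)
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(
                f"classes {small} have fewer than 2 members; use "
                "stratified=False"
            )
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=n_train, test_size=n - n_train,
            random_state=cfg.seed,
        )
        train_idx, test_idx = next(splitter.split(np.zeros(n), labels))
    else:
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    return sset.subset(np.sort(train_idx)), sset.subset(np.sort(test_idx))


def venetian_blinds_folds(n: int, k: int) -> np.ndarray:
    """Fold index per sample: position ``i`` (acquisition order) -> ``i % k``."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    return np.arange(n) % k


@dataclass
class PCAResult:
    """Principal components of a data matrix (centring handled internally)."""

    loadings: np.ndarray                 # n_points x n_components
    scores: np.ndarray                   # n_samples x n_components
    explained_variance_fraction: np.ndarray
    column_means: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (_as_matrix(matrix) - self.column_means) @ self.loadings


def fit_pca(data, n_components: int) -> PCAResult:
    """PCA by full SVD of the column-centred matrix.

    Requests beyond the available rank are truncated with a warning rather
    than raised, so pipelines keep working on degenerate inputs.
    """
    X = _as_matrix(data)
    limit = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    if n_components > limit:
        warnings.warn(
            f"requested {n_components} components but only {limit} are "
            "available; truncating", stacklevel=2,
        )
        n_components = limit
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        loadings=model.components_.T,
        scores=scores,
        explained_variance_fraction=model.explained_variance_ratio_,
        column_means=model.mean_,
    )


@dataclass
class PCALDAModel:
    """LDA fitted on the leading PC scores of the training matrix."""

    n_pcs: int
    pca: PCAResult
    lda: LinearDiscriminantAnalysis
    classes: np.ndarray

    @property
    def discriminant_axes(self) -> np.ndarray:
        return self.lda.scalings_

    @property
    def class_centroids(self) -> np.ndarray:
        """Class means projected into the discriminant space."""
        return self.lda.transform(self.lda.means_)

    def transform(self, data) -> np.ndarray:
        return self.lda.transform(self.pca.transform(_as_matrix(data)))

    def predict(self, data) -> np.ndarray:
        return self.lda.predict(self.pca.transform(_as_matrix(data)))


def fit_pca_lda(train, labels, n_pcs: int = 10) -> PCALDAModel:
    """Fit PCA (``n_pcs`` components) followed by LDA on the scores."""
    X = _as_matrix(train)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training spectra")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    pca = fit_pca(X, n_pcs)
    lda = LinearDiscriminantAnalysis()
    lda.fit(pca.scores, labels)
    return PCALDAModel(n_pcs=pca.scores.shape[1], pca=pca, lda=lda, classes=classes)


@dataclass
class SVMModel:
    cost: float
    gamma: float
    support_vector_count: int
    estimator: SVC
    classes: np.ndarray
    cv_accuracy: float
    cv_table: pd.DataFrame = field(repr=False, default=None)

    def predict(self, data) -> np.ndarray:
        return self.estimator.predict(_as_matrix(data))


def _cv_accuracy(X, y, folds, cost, gamma) -> float:
    hits = 0
    for f in np.unique(folds):
        mask = folds == f
        clf = SVC(C=cost, gamma=gamma, kernel="rbf")
        clf.fit(X[~mask], y[~mask])
        hits += int((clf.predict(X[mask]) == y[mask]).sum())
    return hits / len(y)


def tune_train_svm(train, labels, cfg: SVMConfig | None = None) -> SVMModel:
    """Grid-search cost x gamma by venetian-blinds CV, refit on all data.

    Ties in CV accuracy are broken toward the smaller cost, then the smaller
    gamma.  Multi-class decisions use one-vs-one voting (the SVC default).
    """
    cfg = cfg or SVMConfig()
    X = _as_matrix(train)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    folds = venetian_blinds_folds(len(y), cfg.cv_splits)
    rows = []
    best = None  # (accuracy, cost, gamma)
    for cost, gamma in product(sorted(cfg.cost_grid), sorted(cfg.gamma_grid)):
        acc = _cv_accuracy(X, y, folds, cost, gamma)
        rows.append({"cost": cost, "gamma": gamma, "cv_accuracy": acc})
        if best is None or acc > best[0] + 1e-12:
            best = (acc, cost, gamma)
    _, cost, gamma = best
    final = SVC(C=cost, gamma=gamma, kernel="rbf")
    final.fit(X, y)
    return SVMModel(
        cost=cost,
        gamma=gamma,
        support_vector_count=int(final.n_support_.sum()),
        estimator=final,
        classes=final.classes_,
        cv_accuracy=best[0],
        cv_table=pd.DataFrame(rows),
    )


@dataclass
class ClassMetrics:
    """Per-class quality parameters and their unweighted macro averages.

    Every per-class record is a one-vs-rest reading of the attached
    confusion matrix, so the numbers can always be recomputed from it.
    Classes absent from the test set carry NaN sensitivity and are excluded
    from the macro averages.
    """

    classes: list
    confusion: np.ndarray
    per_class: pd.DataFrame
    macro_accuracy: float
    macro_sensitivity: float
    macro_specificity: float

    def to_frame(self) -> pd.DataFrame:
        """Quality-parameter table with a trailing Average row."""
        avg = pd.DataFrame([
            {
                "class": "Average",
                "accuracy": self.macro_accuracy,
                "sensitivity": self.macro_sensitivity,
                "specificity": self.macro_specificity,
            }
        ])
        return pd.concat([self.per_class, avg], ignore_index=True)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


def metrics_from_confusion(confusion: np.ndarray, classes: Sequence) -> ClassMetrics:
    """One-vs-rest accuracy/sensitivity/specificity (%) from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    records = []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        acc = (tp + tn) / n * 100.0
        sens = np.nan if tp + fn == 0 else tp / (tp + fn) * 100.0
        spec = np.nan if tn + fp == 0 else tn / (tn + fp) * 100.0
        records.append({"class": cls, "accuracy": acc,
                        "sensitivity": sens, "specificity": spec})
    table = pd.DataFrame(records)
    present = table["sensitivity"].notna()
    if not present.all():
        missing = table.loc[~present, "class"].tolist()
        warnings.warn(
            f"classes {missing} have no test members; excluded from macro "
            "averages", stacklevel=2,
        )
    sub = table[present]
    return ClassMetrics(
        classes=list(classes),
        confusion=np.asarray(confusion),
        per_class=table,
        macro_accuracy=float(sub["accuracy"].mean()),
        macro_sensitivity=float(sub["sensitivity"].mean()),
        macro_specificity=float(sub["specificity"].mean()),
    )


def evaluate_classifier(model, test, labels) -> ClassMetrics:
    """Score a fitted model on an external test set."""
    X = _as_matrix(test)
    y_true = np.asarray(labels)
    if len(y_true) == 0:
        raise ValueError("test set is empty")
    y_pred = model.predict(X)
    classes = list(model.classes)
    extra = sorted(set(y_true) - set(classes))
    if extra:
        raise ValueError(f"test labels {extra} were absent from training")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return metrics_from_confusion(cm, classes)
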