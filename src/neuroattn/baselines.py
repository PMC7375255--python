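"""Comparison classifiers: ROI-feature SVM and voxel-feature SVM.

Region features are gray-matter volumes (mean density x region volume in
mm^3) on any parcellation (coarse or fine); voxel features are in-mask
densities reduced by a two-sample t test computed on the training split
only.  Both feed a Gaussian-RBF support vector machine whose signed
decision value doubles as the baseline's per-subject class score.  The
attention-free ResNet baseline lives in :mod:`neuroattn.estimators`
(``with_attention=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import Cohort, Parcellation

__all__ = ["FeatureTable", "roi_features", "voxel_features",
           "ttest_feature_select", "median_heuristic_gamma", "svm_rbf",
           "ROISVMClassifier", "VoxelSVMClassifier"]


@dataclass
class FeatureTable:
    matrix: np.ndarray          # (n_subjects, n_features)
    feature_names: list
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features must be finite")
        if self.matrix.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature table dimensions are inconsistent")


def roi_features(cohort: Cohort, parcellation: Parcellation) -> FeatureTable:
    """Per-region gray-matter volume: sum of density times voxel volume."""
    for rid in parcellation.region_ids:
        if not np.any(parcellation.labels == rid):
            raise ValueError(f"region {rid} is empty")
    rows = []
    for sid in cohort.ids:
        vol = cohort.volumes[sid]
        voxel_mm3 = float(vol.voxel_size_mm) ** 3
        sums = ndimage.sum_labels(vol.values, labels=parcellation.labels,
                                  index=parcellation.region_ids)
        rows.append(np.asarray(sums) * voxel_mm3)
    return FeatureTable(matrix=np.asarray(rows),
                        feature_names=list(parcellation.region_ids),
                        subject_ids=list(cohort.ids))


def voxel_features(cohort: Cohort, mask: np.ndarray | None = None) -> FeatureTable:
    """Flattened in-mask voxel densities (mask defaults to all voxels)."""
    shape = cohort.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    rows = [cohort.volumes[sid].values.ravel()[idx] for sid in cohort.ids]
    return FeatureTable(matrix=np.asarray(rows), feature_names=idx.tolist(),
                        subject_ids=list(cohort.ids))


def ttest_feature_select(X_train: np.ndarray, y_train: np.ndarray,
                         n_keep: int) -> np.ndarray:
    """Indices of the n_keep features with the largest |t| between classes.

    Computed on the training split only; ties break by ascending index.
    """
    X_train = np.asarray(X_train, dtype=float)
    classes = np.unique(y_train)
    if len(classes) != 2:
        raise ValueError("feature selection needs exactly two classes")
    if n_keep > X_train.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds {X_train.shape[1]} features")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(X_train[y_train == classes[0]],
                            X_train[y_train == classes[1]],
                            axis=0, equal_var=True).statistic
    score = np.abs(np.nan_to_num(t, nan=0.0))
    order = np.lexsort((np.arange(len(score)), -score))
    return np.sort(order[:n_keep])


def median_heuristic_gamma(X: np.ndarray, max_points: int = 500,
                           seed: int = 0) -> float:
    """RBF gamma = 1 / median squared pairwise distance (subsampled)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_points, replace=False)]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def svm_rbf(X_train, y_train, X_test, C: float = 1.0, gamma=None):
    """Train a Gaussian-RBF SVM; return (decision values, predictions).

    Features are standardized with training statistics; the decision value
    is the signed distance analogue from the separating surface and is
    positive toward the alphabetically larger class.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) != 2:
        raise ValueError("SVM training needs two classes")
    scaler = StandardScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Xte = scaler.transform(X_test)
    if gamma is None:
        gamma = median_heuristic_gamma(Xtr)
    svc = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xtr, y_train)
    return svc.decision_function(Xte), svc.predict(Xte)


class _BaseSVM(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the volume-input SVM baselines."""

    def _features(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _fit_features(self, F: np.ndarray, y: np.ndarray):
        return F

    def _transform_features(self, F: np.ndarray) -> np.ndarray:
        return F

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        F = self._fit_features(self._features(np.asarray(X)), y)
        self.scaler_ = StandardScaler().fit(F)
        Fs = self.scaler_.transform(F)
        gamma = self.gamma
        if gamma in (None, "median"):
            gamma = median_heuristic_gamma(Fs)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=gamma).fit(Fs, y)
        return self

    def _prep(self, X):
        check_is_fitted(self, "svc_")
        return self.scaler_.transform(self._transform_features(
            self._features(np.asarray(X))))

    def decision_function(self, X):
        return self.svc_.decision_function(self._prep(X))

    def predict(self, X):
        return self.svc_.predict(self._prep(X))


class ROISVMClassifier(_BaseSVM):
    """RBF-SVM on per-region gray-matter volumes.

    ``X`` is a (n, H, W, D) stack of density volumes; features are region
    volumes under the supplied parcellation.
    """

    def __init__(self, parcellation: Parcellation = None, C: float = 1.0,
                 gamma="median", voxel_size_mm: float = 2.0):
        self.parcellation = parcellation
        self.C = C
        self.gamma = gamma
        self.voxel_size_mm = voxel_size_mm

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.parcellation is None:
            raise ValueError("a parcellation is required")
        labels = self.parcellation.labels
        voxel_mm3 = float(self.voxel_size_mm) ** 3
        rows = [np.asarray(ndimage.sum_labels(v, labels=labels,
                                              index=self.parcellation.region_ids))
                * voxel_mm3 for v in X]
        return np.asarray(rows)


class VoxelSVMClassifier(_BaseSVM):
    """RBF-SVM on voxel densities after t-test dimensionality reduction.

    The t test ranks voxels on the training split only; the top ``n_keep``
    (default 2000, capped at the voxel count) are kept.
    """

    def __init__(self, n_keep: int = 2000, C: float = 1.0, gamma="median",
                 mask: np.ndarray = None):
        self.n_keep = n_keep
        self.C = C
        self.gamma = gamma
        self.mask = mask

    def _features(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        flat = X.reshape(n, -1)
        if self.mask is not None:
            flat = flat[:, np.flatnonzero(np.asarray(self.mask).ravel())]
        return flat

    def _fit_features(self, F: np.ndarray, y: np.ndarray):
        keep = min(self.n_keep, F.shape[1])
        self.selected_ = ttest_feature_select(F, y, keep)
        return F[:, self.selected_]

    def _transform_features(self, F: np.ndarray) -> np.ndarray:
        return F[:, self.selected_]
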