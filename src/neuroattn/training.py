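"""Model training, classification metrics, and cross-validation strategies.

Four evaluation strategies are supported: train on one database and test on
another (both directions), leave-center-out across acquisition sites, and
stratified k-fold within one database.  Metrics are accuracy, sensitivity,
specificity and trapezoidal AUC, all at the argmax operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from ._nn import softmax
from .estimators import AttentionNetClassifier
from .io import Cohort, EvalMetrics

__all__ = ["TrainConfig", "CVPlan", "CVResult", "train", "evaluate",
           "evaluate_estimator", "run_cv"]


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the published protocol.

    The 1e-6 learning rate is tuned to full-size 2 mm MNI volumes; toy-grid
    experiments typically raise it (around 1e-3) to converge in few epochs.
    """

    learning_rate: float = 1e-6
    batch_size: int = 8
    max_epochs: int = 30
    early_stop_patience: int | None = None
    seed: int = 0
    positive_class: str = "AD"
    block_channels: tuple = (8, 16, 32, 64)
    with_attention: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class CVPlan:
    strategy: str = "k_fold"  # {"cross_database", "leave_center_out", "k_fold"}
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("cross_database", "leave_center_out", "k_fold"):
            raise ValueError(f"unknown CV strategy {self.strategy!r}")


@dataclass
class CVResult:
    fold_metrics: list[EvalMetrics]
    fold_names: list[str]
    skipped: list[str] = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(np.mean([m.acc for m in self.fold_metrics]))

    def summary(self) -> dict:
        def _mean(attr):
            vals = [getattr(m, attr) for m in self.fold_metrics]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return float(np.nanmean(vals))
        return {"acc": _mean("acc"), "sen": _mean("sen"),
                "spe": _mean("spe"), "auc": _mean("auc"),
                "n_folds": len(self.fold_metrics), "skipped": self.skipped}


def _default_positive(classes) -> object:
    """Disease class by convention: AD, else pMCI, else the last label."""
    for preferred in ("AD", "pMCI"):
        if preferred in classes:
            return preferred
    return classes[1]


def _cohort_labels(cohort: Cohort, label_attr: str) -> np.ndarray:
    labels = cohort.labels(label_attr)
    if any(l is None for l in labels):
        raise ValueError(f"some subjects lack a {label_attr!r} label")
    return labels.astype(str)


def train(cohort: Cohort, config: TrainConfig,
          labels: np.ndarray | None = None,
          label_attr: str = "diagnosis") -> AttentionNetClassifier:
    """Fit a 3DAN (or ResNet baseline) on a two-class cohort."""
    y = labels if labels is not None else _cohort_labels(cohort, label_attr)
    if len(np.unique(y)) != 2:
        raise ValueError(f"training requires exactly two classes; got {np.unique(y)}")
    clf = AttentionNetClassifier(
        block_channels=config.block_channels,
        with_attention=config.with_attention,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        seed=config.seed,
    )
    clf.fit(cohort.stack(), y)
    return clf


def evaluate(scores: np.ndarray, labels: np.ndarray,
             positive_label=None) -> EvalMetrics:
    """Metrics from unnormalized two-class scores.

    Predictions are the argmax over the two score columns (column order
    follows the sorted class labels); AUC is the trapezoidal area under the
    ROC of the positive-class softmax probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must have shape (n, 2)")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"both classes must be present; got {classes}")
    if positive_label is None:
        positive_label = _default_positive(classes)
    pos_col = int(np.where(classes == positive_label)[0][0])
    preds = classes[np.argmax(scores, axis=1)]
    return _metrics_from(preds, softmax(scores)[:, pos_col], labels, positive_label)


def _metrics_from(preds, rank_scores, labels, positive_label) -> EvalMetrics:
    pos = labels == positive_label
    tp = int(np.sum((preds == positive_label) & pos))
    fn = int(np.sum((preds != positive_label) & pos))
    tn = int(np.sum((preds != positive_label) & ~pos))
    fp = int(np.sum((preds == positive_label) & ~pos))
    n_pos, n_neg = tp + fn, tn + fp
    acc = (tp + tn) / (n_pos + n_neg)
    # one-class test sets (e.g. leave-one-out folds) leave SEN/SPE/AUC undefined
    sen = tp / n_pos if n_pos else float("nan")
    spe = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(pos.astype(int), rank_scores)
        auc = float(np.trapezoid(tpr, fpr))
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        auc, roc = float("nan"), []
    return EvalMetrics(acc=acc, sen=sen, spe=spe, auc=auc, roc=roc,
                       n_pos=n_pos, n_neg=n_neg)


def evaluate_estimator(est, X, y, positive_label=None) -> EvalMetrics:
    """Metrics for any fitted classifier exposing predict + a ranking score."""
    y = np.asarray(y)
    if positive_label is None:
        positive_label = _default_positive(list(est.classes_))
    preds = est.predict(X)
    if hasattr(est, "predict_proba"):
        pos_col = int(np.where(est.classes_ == positive_label)[0][0])
        rank = est.predict_proba(X)[:, pos_col]
    else:
        rank = est.decision_function(X)
        if est.classes_[1] != positive_label:
            rank = -rank
    return _metrics_from(preds, rank, y, positive_label)


def run_cv(plan: CVPlan, cohort: Cohort, make_estimator,
           label_attr: str = "diagnosis", labels: np.ndarray | None = None,
           test_cohort: Cohort | None = None,
           positive_label=None) -> CVResult:
    """Run one cross-validation strategy.

    ``make_estimator(fold_index)`` must return a fresh unfitted classifier.
    ``labels`` overrides the cohort labels (e.g. for permutation tests).
    For ``cross_database``, ``cohort`` is the training and ``test_cohort``
    the testing database.
    """
    y = np.asarray(labels) if labels is not None else _cohort_labels(cohort, label_attr)
    X = cohort.stack()
    fold_metrics, fold_names, skipped = [], [], []

    if plan.strategy == "cross_database":
        if test_cohort is None:
            raise ValueError("cross_database needs a test_cohort")
        y_test = _cohort_labels(test_cohort, label_attr)
        est = make_estimator(0).fit(X, y)
        fold_metrics.append(evaluate_estimator(est, test_cohort.stack(), y_test,
                                               positive_label))
        fold_names.append("cross_database")

    elif plan.strategy == "leave_center_out":
        sites = cohort.labels("site")
        for i, site in enumerate(sorted(set(sites))):
            test_idx = np.where(sites == site)[0]
            train_idx = np.where(sites != site)[0]
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                warnings.warn(f"center {site!r} skipped: a split contains one class")
                skipped.append(site)
                continue
            est = make_estimator(i).fit(X[train_idx], y[train_idx])
            fold_metrics.append(evaluate_estimator(est, X[test_idx], y[test_idx],
                                                   positive_label))
            fold_names.append(f"center:{site}")

    else:  # k_fold, stratified and seeded (plain KFold when k exceeds class counts)
        _, counts = np.unique(y, return_counts=True)
        if plan.k <= counts.min():
            splitter = StratifiedKFold(n_splits=plan.k, shuffle=True,
                                       random_state=plan.seed)
        else:
            splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        for i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            est = make_estimator(i).fit(X[train_idx], y[train_idx])
            fold_metrics.append(evaluate_estimator(est, X[test_idx], y[test_idx],
                                                   positive_label))
            fold_names.append(f"fold:{i}")

    if not fold_metrics:
        raise ValueError("no usable folds")
    return CVResult(fold_metrics=fold_metrics, fold_names=fold_names, skipped=skipped)
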