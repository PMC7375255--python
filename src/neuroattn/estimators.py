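"""Scikit-learn style classifiers over 3D gray-matter volumes.

``AttentionNetClassifier`` trains the 3D attention network (or the
attention-free ResNet baseline) with Adam on softmax cross-entropy.  Input
``X`` is an array of shape ``(n_subjects, H, W, D)``; ``y`` holds two class
labels.  Following the convention used for association analyses, the
*unnormalized* class score of the positive class (``classes_[1]``) is exposed
through :meth:`decision_function`, not the softmax posterior.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, softmax
from ._nn.layers import DTYPE
from .network import AttentionNet3D, NetworkSpec

__all__ = ["AttentionNetClassifier"]


class AttentionNetClassifier(BaseEstimator, ClassifierMixin):
    """3D residual CNN with a spatial attention module.

    Parameters
    ----------
    block_channels : tuple of 4 ints
        Channel widths of the four residual stages (two blocks each).
    with_attention : bool
        If False, skip the attention module (plain ResNet baseline).
    learning_rate : float
        Adam step size.  The published default of 1e-6 suits full-size
        2 mm MNI volumes; toy grids train in reasonable time at ~1e-3.
    batch_size : int
        Mini-batch size (default 8).
    max_epochs : int
        Number of passes over the training set.
    early_stop_patience : int or None
        Stop when the training loss has not improved for this many epochs.
    seed : int
        Seed for weight initialisation and batch shuffling; fixed seed plus
        fixed data give a bit-identical fit.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is treated as the positive
        (disease) class.
    net_ : AttentionNet3D
        The fitted network.
    loss_history_ : list of float
        Mean training cross-entropy per epoch.
    """

    def __init__(self, block_channels=(8, 16, 32, 64), stem_channels=None,
                 with_attention=True, learning_rate=1e-6, batch_size=8,
                 max_epochs=30, early_stop_patience=None, seed=0):
        self.block_channels = block_channels
        self.stem_channels = stem_channels
        self.with_attention = with_attention
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed

    # ------------------------------------------------------------------

    def _validate_volumes(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_subjects, H, W, D); got ndim={X.ndim}")
        if not np.all(np.isfinite(X)):
            raise ValueError("volumes contain non-finite values")
        return X

    def fit(self, X, y):
        X = self._validate_volumes(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly two classes required; got {list(self.classes_)}")
        y_enc = np.searchsorted(self.classes_, y)

        spec = NetworkSpec(in_shape=tuple(X.shape[1:]),
                           stem_channels=self.stem_channels,
                           block_channels=tuple(self.block_channels),
                           with_attention=self.with_attention)
        self.net_ = AttentionNet3D(spec, seed=self.seed)
        opt = Adam(self.net_.layers(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)

        from ._nn.loss import softmax_cross_entropy

        n = X.shape[0]
        self.loss_history_ = []
        best = np.inf
        stale = 0
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx][:, None]  # add channel axis
                logits, _ = self.net_.forward(xb, train=True)
                loss, dlogits = softmax_cross_entropy(logits, y_enc[idx])
                self.net_.backward(dlogits)
                opt.step()
                losses.append(loss * len(idx))
            epoch_loss = float(np.sum(losses) / n)
            self.loss_history_.append(epoch_loss)
            if self.early_stop_patience is not None:
                if epoch_loss < best - 1e-6:
                    best, stale = epoch_loss, 0
                else:
                    stale += 1
                    if stale >= self.early_stop_patience:
                        break
        self._finalize_batchnorm(X)
        return self

    def _finalize_batchnorm(self, X: np.ndarray) -> None:
        """Recompute batch-norm running statistics under the final weights.

        The exponentially averaged statistics collected during training lag
        the weights; one equal-weight pass over the training set aligns the
        inference-time normalisation with the fitted parameters.
        """
        from ._nn.layers import BatchNorm3d

        bns = [ly for ly in self.net_.layers() if isinstance(ly, BatchNorm3d)]
        if not bns:
            return
        for bn in bns:
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 0.0
        momenta = [bn.momentum for bn in bns]
        n = X.shape[0]
        for k, start in enumerate(range(0, n, self.batch_size), start=1):
            for bn in bns:
                bn.momentum = 1.0 / k  # cumulative equal-weight average
            self.net_.forward(X[start:start + self.batch_size][:, None], train=True)
        for bn, mom in zip(bns, momenta):
            bn.momentum = mom
        for ly in self.net_.layers():  # drop the last batch's caches
            for attr in ("_cache", "_mask", "_out", "_x", "_shape"):
                if hasattr(ly, attr):
                    setattr(ly, attr, None)

    # ------------------------------------------------------------------

    def _forward_batches(self, X, batch: int = 8):
        X = self._validate_volumes(X)
        logits, maps = [], []
        for start in range(0, X.shape[0], batch):
            lg, att = self.net_.forward(X[start:start + batch][:, None], train=False)
            logits.append(lg)
            if att is not None:
                maps.append(att)
        logits = np.concatenate(logits, axis=0)
        maps = np.concatenate(maps, axis=0) if maps else None
        return logits, maps

    def class_scores(self, X) -> np.ndarray:
        """Unnormalized class scores (pre-softmax), shape (n, 2)."""
        check_is_fitted(self, "net_")
        return self._forward_batches(X)[0]

    def decision_function(self, X) -> np.ndarray:
        """Unnormalized score of the positive class (``classes_[1]``)."""
        return self.class_scores(X)[:, 1]

    def score_for_class(self, X, label) -> np.ndarray:
        """Unnormalized score column for an explicit class label.

        Association analyses use the *disease*-class score (e.g. "AD"),
        which with alphabetically sorted labels is not always
        ``classes_[1]``.
        """
        where = np.where(self.classes_ == label)[0]
        if len(where) == 0:
            raise ValueError(f"{label!r} is not one of the fitted classes "
                             f"{list(self.classes_)}")
        return self.class_scores(X)[:, int(where[0])]

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.class_scores(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.class_scores(X), axis=1)]

    def attention_maps(self, X) -> np.ndarray:
        """Per-subject attention maps on the post-pooling grid, shape (n, h, w, d)."""
        check_is_fitted(self, "net_")
        if not self.with_attention:
            raise ValueError("model was built without an attention module")
        return self._forward_batches(X)[1]

    # ------------------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint the fitted network together with the class labels."""
        check_is_fitted(self, "net_")
        from .network import save_model
        save_model(self.net_, path, classes=self.classes_)

    @classmethod
    def from_checkpoint(cls, path) -> "AttentionNetClassifier":
        from .network import load_model, load_classes
        net = load_model(path)
        clf = cls(block_channels=tuple(net.spec.block_channels),
                  stem_channels=net.spec.stem_channels,
                  with_attention=net.spec.with_attention)
        clf.net_ = net
        clf.classes_ = load_classes(path)
        clf.loss_history_ = []
        return clf
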