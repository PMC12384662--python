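"""Scikit-learn estimator interface to the micro-capsule network.

``CapsNetClassifier`` takes flat segments (n_samples, window_pts) — or
already expanded (n_samples, h, w) matrices — and handles the 2-D expansion
internally, so it drops into sklearn pipelines and model selection
unchanged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autograd import Adam
from .capsnet import MarginLossParams, MicroCapsNet, ModelConfig
from .preprocess import factorize_length

__all__ = ["CapsNetClassifier"]


class CapsNetClassifier(ClassifierMixin, BaseEstimator):
    """Capsule-network classifier for windowed single-channel EEG.

    Parameters
    ----------
    input_hw : (int, int) or None
        Matrix shape for the 2-D expansion. None derives the most-square
        shape (with tail zero-padding) from the number of input features.
    routing_iters : int
        Rounds of routing-by-agreement between primary and label capsules.
    m_plus, m_minus, lam : float
        Margin-loss hyperparameters (true-class upper margin, absent-class
        lower margin, absent-class weight).
    loss_threshold : float or None
        Stop training early once the epoch mean margin loss falls below
        this value; disabled when None.
    learning_rate, batch_size, epochs
        Adam optimisation schedule. Training runs for `epochs` passes
        (no other stopping rule by default).
    class_weight : dict, array-like or None
        Optional per-class multipliers on the sample loss.
    random_state : int or None
        Seeds weight initialisation and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in fit.
    model_ : MicroCapsNet
        The trained network.
    input_hw_ : (int, int)
        The matrix shape actually used.
    history_ : dict of lists
        Per-epoch train loss/accuracy and, when validation data is given,
        validation loss/accuracy.
    """

    def __init__(
        self,
        input_hw=None,
        conv1_filters: int = 8,
        conv2_filters: int = 8,
        primary_caps_dim: int = 4,
        label_caps_dim: int = 16,
        routing_iters: int = 3,
        m_plus: float = 0.9,
        m_minus: float = 0.1,
        lam: float = 0.5,
        loss_threshold: float | None = None,
        learning_rate: float = 5e-4,
        batch_size: int = 32,
        epochs: int = 400,
        class_weight=None,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.input_hw = input_hw
        self.conv1_filters = conv1_filters
        self.conv2_filters = conv2_filters
        self.primary_caps_dim = primary_caps_dim
        self.label_caps_dim = label_caps_dim
        self.routing_iters = routing_iters
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lam = lam
        self.loss_threshold = loss_threshold
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers --------------------------------------------------------------

    def _expand(self, X: np.ndarray) -> np.ndarray:
        """(n, L) -> (n, h, w, 1) row-major with tail zero padding."""
        h, w = self.input_hw_
        n, L = X.shape
        grid = np.zeros((n, h * w))
        grid[:, :L] = X
        return grid.reshape(n, h, w, 1)

    def _as_matrices(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[1]} features, expected {self.n_features_in_}"
                )
            return self._expand(X)
        if X.ndim in (3, 4):
            if tuple(X.shape[1:3]) != tuple(self.input_hw_):
                raise ValueError(
                    f"X matrices are {X.shape[1:3]}, expected {self.input_hw_}"
                )
            return X.reshape(X.shape[0], *self.input_hw_, 1)
        raise ValueError("X must be 2-D (flat segments) or 3-D/4-D (matrices)")

    def _class_weight_vector(self, n_classes: int) -> np.ndarray | None:
        if self.class_weight is None:
            return None
        if isinstance(self.class_weight, dict):
            return np.array([self.class_weight.get(k, 1.0) for k in range(n_classes)])
        w = np.asarray(self.class_weight, dtype=float)
        if w.size != n_classes:
            raise ValueError("class_weight length must equal the number of classes")
        return w

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim == 2:
            self.n_features_in_ = X.shape[1]
            self.input_hw_ = (
                tuple(self.input_hw)
                if self.input_hw is not None
                else factorize_length(X.shape[1])
            )
        elif X.ndim in (3, 4):
            self.input_hw_ = tuple(X.shape[1:3])
            self.n_features_in_ = int(np.prod(self.input_hw_))
        else:
            raise ValueError("X must be 2-D or 3-D/4-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")

        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes in y")

        config = ModelConfig(
            input_hw=self.input_hw_,
            n_classes=int(self.classes_.size),
            conv1_filters=self.conv1_filters,
            conv2_filters=self.conv2_filters,
            primary_caps_dim=self.primary_caps_dim,
            label_caps_dim=self.label_caps_dim,
            routing_iters=self.routing_iters,
            loss=MarginLossParams(
                self.m_plus, self.m_minus, self.lam, self.loss_threshold
            ),
        )
        rng = np.random.default_rng(self.random_state)
        init_seed = int(rng.integers(0, 2**31 - 1))
        self.model_ = MicroCapsNet(config, seed=init_seed)
        optimizer = Adam(self.model_.params, lr=self.learning_rate)
        weights = self._class_weight_vector(config.n_classes)

        Xm = self._as_matrices(X)
        if validation_data is not None:
            Xv, yv = validation_data
            Xv = self._as_matrices(np.asarray(Xv, dtype=float))
            yv_idx = np.searchsorted(self.classes_, np.asarray(yv))
        history: dict[str, list[float]] = {"train_loss": [], "train_acc": []}
        if validation_data is not None:
            history["val_loss"] = []
            history["val_acc"] = []

        n = Xm.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                lengths, loss = self.model_.forward(Xm[batch], y_idx[batch], weights)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data) * batch.size
                epoch_correct += int(
                    (np.argmax(lengths.data, axis=1) == y_idx[batch]).sum()
                )
            history["train_loss"].append(epoch_loss / n)
            history["train_acc"].append(epoch_correct / n)
            if validation_data is not None:
                vl, va = self._evaluate(Xv, yv_idx, weights)
                history["val_loss"].append(vl)
                history["val_acc"].append(va)
            if self.verbose:
                msg = (
                    f"epoch {epoch + 1}/{self.epochs} "
                    f"loss {history['train_loss'][-1]:.4f} "
                    f"acc {history['train_acc'][-1]:.4f}"
                )
                if validation_data is not None:
                    msg += f" val_loss {vl:.4f} val_acc {va:.4f}"
                print(msg)
            if (
                self.loss_threshold is not None
                and history["train_loss"][-1] < self.loss_threshold
            ):
                break
        self.history_ = history
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _evaluate(self, Xm, y_idx, weights) -> tuple[float, float]:
        from .capsnet import margin_loss

        lengths = self.model_.predict_lengths(Xm)
        _, loss = margin_loss(
            np.clip(lengths, 0.0, 1.0), y_idx, self.model_.config.loss, weights
        )
        acc = float((np.argmax(lengths, axis=1) == y_idx).mean())
        return loss, acc

    def decision_function(self, X):
        """Label-capsule lengths, shape (n_samples, n_classes)."""
        check_is_fitted(self, "model_")
        return self.model_.predict_lengths(self._as_matrices(np.asarray(X, float)))

    def predict_proba(self, X):
        """Capsule lengths normalised to sum to one per sample."""
        lengths = self.decision_function(X)
        total = lengths.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return lengths / total

    def predict(self, X):
        lengths = self.decision_function(X)
        return self.classes_[np.argmax(lengths, axis=1)]

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        self.model_.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "CapsNetClassifier":
        model = MicroCapsNet.load(path)
        cfg = model.config
        est = cls(
            input_hw=cfg.input_hw,
            conv1_filters=cfg.conv1_filters,
            conv2_filters=cfg.conv2_filters,
            primary_caps_dim=cfg.primary_caps_dim,
            label_caps_dim=cfg.label_caps_dim,
            routing_iters=cfg.routing_iters,
            m_plus=cfg.loss.m_plus,
            m_minus=cfg.loss.m_minus,
            lam=cfg.loss.lam,
            loss_threshold=cfg.loss.loss_threshold,
        )
        est.model_ = model
        est.input_hw_ = tuple(cfg.input_hw)
        est.n_features_in_ = int(np.prod(cfg.input_hw))
        est.classes_ = np.arange(cfg.n_classes)
        est.history_ = {}
        return est
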