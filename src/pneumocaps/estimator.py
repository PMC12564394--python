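"""scikit-learn style classifier wrapping the capsule network.

``CapsNetClassifier`` follows the estimator contract (get_params /
set_params, ``fit`` -> fitted attributes with trailing underscores,
``predict`` / ``predict_proba`` / ``decision_function``) so it composes
with sklearn pipelines and model selection.  Training minimizes the
margin loss with Adam and stops early when validation accuracy stalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .capsnet import CapsNet, CapsNetConfig


@dataclass
class TrainLog:
    """Per-epoch training history and the stopping outcome."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def record(self, train_loss: float, train_acc: float, val_loss: float, val_acc: float) -> None:
        self.epochs.append(
            {
                "epoch": len(self.epochs) + 1,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )

    @property
    def val_accuracies(self) -> list[float]:
        return [e["val_acc"] for e in self.epochs]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CapsNetClassifier(BaseEstimator, ClassifierMixin):
    """Capsule-network binary image classifier.

    Parameters mirror :class:`~pneumocaps.capsnet.CapsNetConfig` plus the
    training loop (Adam learning rate 1e-4, batch size 16, early stopping
    on validation accuracy with a 5-epoch patience by default).

    ``fit(X, y)`` expects X of shape (n, S, S, C) with values in [0, 1]
    and y as class labels.  A validation set is either passed explicitly
    via ``eval_set=(X_val, y_val)`` or carved from X with
    ``validation_fraction``.
    """

    def __init__(
        self,
        input_size: int = 224,
        in_channels: int = 3,
        n_filters: int = 64,
        primary_caps_types: int = 32,
        primary_caps_dim: int = 8,
        digit_caps_dim: int = 16,
        routing_iterations: int = 3,
        m_plus: float = 0.9,
        m_minus: float = 0.1,
        lambda_down: float = 0.5,
        drop_rate: float = 0.0,
        learning_rate: float = 1e-4,
        batch_size: int = 16,
        max_epochs: int = 30,
        early_stop_patience: int = 5,
        validation_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.primary_caps_types = primary_caps_types
        self.primary_caps_dim = primary_caps_dim
        self.digit_caps_dim = digit_caps_dim
        self.routing_iterations = routing_iterations
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lambda_down = lambda_down
        self.drop_rate = drop_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _config(self) -> CapsNetConfig:
        return CapsNetConfig(
            input_size=self.input_size,
            in_channels=self.in_channels,
            n_filters=self.n_filters,
            primary_caps_types=self.primary_caps_types,
            primary_caps_dim=self.primary_caps_dim,
            digit_caps_dim=self.digit_caps_dim,
            routing_iterations=self.routing_iterations,
            m_plus=self.m_plus,
            m_minus=self.m_minus,
            lambda_down=self.lambda_down,
            drop_rate=self.drop_rate,
        )

    def fit(self, X, y, eval_set: tuple | None = None):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("max_epochs and early_stop_patience must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {list(self.classes_)}")
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(self.random_state)
        if eval_set is not None:
            Xtr, ytr = X, y_idx
            Xval = np.asarray(eval_set[0], dtype=float)
            yval = np.searchsorted(self.classes_, np.asarray(eval_set[1]))
        else:
            n_val = max(1, int(round(len(X) * self.validation_fraction)))
            order = rng.permutation(len(X))
            val_ids, tr_ids = order[:n_val], order[n_val:]
            Xtr, ytr = X[tr_ids], y_idx[tr_ids]
            Xval, yval = X[val_ids], y_idx[val_ids]
        if len(Xtr) == 0 or len(Xval) == 0:
            raise ValueError("train and validation sets must be nonempty")

        cfg = self._config()
        model = CapsNet(cfg, seed=self.random_state)
        opt = _Adam(model.params, lr=self.learning_rate)
        eye = np.eye(cfg.n_classes)
        log = TrainLog()
        best_val, best_epoch, best_params = -np.inf, -1, None

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(Xtr))
            losses, correct = [], 0
            for start in range(0, len(Xtr), self.batch_size):
                ids = order[start : start + self.batch_size]
                cache = model.forward(Xtr[ids], training=True, dropout_rng=rng)
                loss, grads = model.backward(cache, eye[ytr[ids]])
                opt.step(model.params, grads)
                losses.append(loss)
                correct += int((cache["lengths"].argmax(-1) == ytr[ids]).sum())
            val_loss, val_acc = self._evaluate(model, Xval, yval, eye)
            log.record(float(np.mean(losses)), correct / len(Xtr), val_loss, val_acc)
            if val_acc > best_val:
                best_val, best_epoch = val_acc, epoch
                best_params = {k: v.copy() for k, v in model.params.items()}
            if epoch - best_epoch >= self.early_stop_patience:
                log.stop_reason = f"early stop: no val-accuracy gain for {self.early_stop_patience} epochs"
                break
        else:
            log.stop_reason = "max_epochs reached"

        model.params = best_params
        log.best_epoch = best_epoch
        self.model_ = model
        self.log_ = log
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    @staticmethod
    def _evaluate(model: CapsNet, X, y_idx, eye, batch: int = 64) -> tuple[float, float]:
        from .capsnet import margin_loss

        chunks = [model.forward(X[s : s + batch])["lengths"] for s in range(0, len(X), batch)]
        lengths = np.concatenate(chunks)
        loss = margin_loss(lengths, eye[y_idx], model.cfg.m_plus, model.cfg.m_minus, model.cfg.lambda_down)
        acc = float((lengths.argmax(-1) == y_idx).mean())
        return loss, acc

    # ------------------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Positive-class capsule length per sample (the ROC/PR score)."""
        check_is_fitted(self, "model_")
        return self._lengths(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        idx = self._lengths(X).argmax(axis=-1)
        return self.classes_[idx]

    def predict_proba(self, X) -> np.ndarray:
        """Capsule lengths normalized to sum to one (lengths themselves
        are not a simplex)."""
        check_is_fitted(self, "model_")
        lengths = self._lengths(X)
        return lengths / (lengths.sum(axis=-1, keepdims=True) + 1e-12)

    def capsule_lengths(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self._lengths(X)

    def _lengths(self, X, batch: int = 64) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.concatenate(
            [self.model_.lengths(X[s : s + batch]) for s in range(0, len(X), batch)]
        )
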