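"""Capsule network with dynamic routing-by-agreement and margin loss.

Architecture: a 3x3 convolutional stem with ReLU, 2x2 max-pooling,
optional dropout, a PrimaryCaps convolution (3x3, stride 2) whose output
channels are reshaped into pose vectors and squashed, and a DigitCaps
layer that routes every primary capsule's linear prediction to one output
capsule per class over a fixed number of agreement iterations.  Class
scores are the output capsule lengths; training minimizes the two-sided
margin loss.

Everything runs in NumPy: the forward pass follows the routing algorithm
literally, and the backward pass is hand-derived, treating the converged
coupling coefficients as constants (the usual CapsNet training
simplification; see docs/methods.md).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._ops import (
    conv2d_backward,
    conv2d_forward,
    maxpool2x2_backward,
    maxpool2x2_forward,
    relu_backward,
    relu_forward,
)

_EPS = 1e-12


@dataclass
class CapsNetConfig:
    """Architecture and loss hyperparameters.

    Defaults reproduce the reference model: 224x224x3 input, 64 stem
    filters, 32 primary capsule types of dimension 8, two 16-dimensional
    class capsules, three routing iterations, margin loss with m+=0.9,
    m-=0.1 and down-weight 0.5.
    """

    input_size: int = 224
    in_channels: int = 3
    n_filters: int = 64
    conv_kernel: int = 3
    primary_caps_types: int = 32
    primary_caps_dim: int = 8
    primary_kernel: int = 3
    primary_stride: int = 2
    digit_caps_dim: int = 16
    n_classes: int = 2
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    drop_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if not 0.0 < self.m_minus < self.m_plus < 1.0:
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if not 0.0 < self.lambda_down <= 1.0:
            raise ValueError("lambda_down must be in (0, 1]")
        if self.primary_caps_dim < 1 or self.digit_caps_dim < 1:
            raise ValueError("capsule dimensions must be >= 1")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must be in [0, 1)")
        if self.input_size % 2:
            raise ValueError(
                f"input_size must be even (2x2 max-pool halves it); got {self.input_size}"
            )

    @property
    def pooled_size(self) -> int:
        return self.input_size // 2

    @property
    def primary_grid(self) -> int:
        # 'same' padding, stride s -> ceil division
        return -(-self.pooled_size // self.primary_stride)

    @property
    def n_primary_capsules(self) -> int:
        return self.primary_grid**2 * self.primary_caps_types


def parameter_counts(cfg: CapsNetConfig) -> dict[str, int]:
    """Closed-form trainable parameter counts per layer.

    stem conv: k^2*c_in*F + F; PrimaryCaps conv: k^2*F*(types*d_p) +
    types*d_p; DigitCaps: N_primary*n_classes*d_p*d_o (transform matrices
    only, no bias).
    """
    k = cfg.conv_kernel
    pk = cfg.primary_kernel
    primary_channels = cfg.primary_caps_types * cfg.primary_caps_dim
    stem = k * k * cfg.in_channels * cfg.n_filters + cfg.n_filters
    primary = pk * pk * cfg.n_filters * primary_channels + primary_channels
    digit = cfg.n_primary_capsules * cfg.n_classes * cfg.primary_caps_dim * cfg.digit_caps_dim
    return {
        "conv_stem": stem,
        "primary_caps": primary,
        "digit_caps": digit,
        "total": stem + primary + digit,
    }


# ---------------------------------------------------------------------------
# squash nonlinearity
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """v = (|s|^2 / (1 + |s|^2)) * s/|s| along ``axis``; squash(0) = 0."""
    s = np.asarray(s, dtype=float)
    sq = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq + _EPS)
    return (sq / (1.0 + sq)) * (s / norm)


def _squash_backward(dv: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector-Jacobian product of squash at s.

    With n = |s|, v = a(n) * s and a(n) = n / (1 + n^2):
    ds = a*dv + a'(n) * (s.dv / n) * s, a'(n) = (1 - n^2) / (1 + n^2)^2.
    """
    sq = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(sq + _EPS)
    a = n / (1.0 + sq)
    aprime = (1.0 - sq) / (1.0 + sq) ** 2
    sdotdv = np.sum(s * dv, axis=axis, keepdims=True)
    return a * dv + aprime * (sdotdv / n) * s


# ---------------------------------------------------------------------------
# dynamic routing
# ---------------------------------------------------------------------------

def dynamic_routing(u_hat: np.ndarray, r: int):
    """Routing-by-agreement over prediction vectors.

    u_hat: (..., N_in, N_out, d_o).  Logits b start at zero; each of the
    ``r`` iterations softmax-normalizes b over output capsules, forms the
    weighted sum s_j = sum_i c_ij u_hat_ij, squashes it, and adds the
    agreement u_hat . v to b (skipped after the final iteration).

    Returns (v, state) with v: (..., N_out, d_o) and state a dict holding
    the final logits ``b``, couplings ``c`` and outputs ``v``.
    """
    if r < 1:
        raise ValueError("routing needs at least one iteration")
    b = np.zeros(u_hat.shape[:-1], dtype=float)  # (..., N_in, N_out)
    c = v = None
    for it in range(r):
        bmax = b.max(axis=-1, keepdims=True)
        e = np.exp(b - bmax)
        c = e / e.sum(axis=-1, keepdims=True)
        s = np.einsum("...ij,...ijd->...jd", c, u_hat)
        v = squash(s, axis=-1)
        if it < r - 1:
            b = b + np.einsum("...ijd,...jd->...ij", u_hat, v)
    return v, {"b": b, "c": c, "v": v}


def routing_forward(u: np.ndarray, W: np.ndarray, r: int):
    """Full DigitCaps forward: u (..., N_in, d_p), W (N_in, N_out, d_p, d_o).

    Returns (lengths, v, state): class capsule lengths ||v_j||, the output
    capsules, and the final routing state.
    """
    u_hat = np.einsum("...id,ijde->...ije", u, W)
    v, state = dynamic_routing(u_hat, r)
    lengths = np.linalg.norm(v, axis=-1)
    return lengths, v, state


# ---------------------------------------------------------------------------
# margin loss
# ---------------------------------------------------------------------------

def _check_onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[None, :]
    ok = (
        labels.shape[-1] == n_classes
        and np.all((labels == 0) | (labels == 1))
        and np.all(labels.sum(axis=-1) == 1)
    )
    if not ok:
        raise ValueError("labels must be one-hot rows over the class capsules")
    return labels


def margin_loss(
    lengths: np.ndarray,
    labels_onehot: np.ndarray,
    m_plus: float = 0.9,
    m_minus: float = 0.1,
    lambda_down: float = 0.5,
) -> float:
    """Mean over the batch of sum_k T_k max(0, m+ - |v_k|)^2
    + lambda (1 - T_k) max(0, |v_k| - m-)^2."""
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    T = _check_onehot(labels_onehot, lengths.shape[-1])
    pos = np.maximum(0.0, m_plus - lengths) ** 2
    neg = np.maximum(0.0, lengths - m_minus) ** 2
    per_sample = (T * pos + lambda_down * (1.0 - T) * neg).sum(axis=-1)
    return float(per_sample.mean())


def margin_loss_grad(
    lengths: np.ndarray,
    labels_onehot: np.ndarray,
    m_plus: float = 0.9,
    m_minus: float = 0.1,
    lambda_down: float = 0.5,
) -> np.ndarray:
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    T = _check_onehot(labels_onehot, lengths.shape[-1])
    g = -2.0 * T * np.maximum(0.0, m_plus - lengths) + 2.0 * lambda_down * (
        1.0 - T
    ) * np.maximum(0.0, lengths - m_minus)
    return g / lengths.shape[0]


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CapsNet:
    """NumPy capsule network: forward, hand-derived backward, Adam-ready.

    Parameters live in ``self.params`` (dict of float64 arrays).  The
    object is deterministic given its init seed and input.
    """

    def __init__(self, cfg: CapsNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg
        pc = c.primary_caps_types * c.primary_caps_dim
        # He-style init for the conv stacks, small normal for the routing
        # transforms so initial capsule sums do not saturate the squash
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / (c.conv_kernel**2 * c.in_channels)),
                             (c.conv_kernel, c.conv_kernel, c.in_channels, c.n_filters)),
            "b1": np.zeros(c.n_filters),
            "W2": rng.normal(0.0, np.sqrt(2.0 / (c.primary_kernel**2 * c.n_filters)),
                             (c.primary_kernel, c.primary_kernel, c.n_filters, pc)),
            "b2": np.zeros(pc),
            "Wd": rng.normal(0.0, 0.01,
                             (c.n_primary_capsules, c.n_classes, c.primary_caps_dim, c.digit_caps_dim)),
        }

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict:
        """Run the network; returns a cache of intermediates.

        x: (B, S, S, C) float in [0, 1].  cache["lengths"] holds the class
        scores, cache["v"] the output capsules.
        """
        c = self.cfg
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1:] != (c.input_size, c.input_size, c.in_channels):
            raise ValueError(
                f"expected batch of shape (B, {c.input_size}, {c.input_size}, "
                f"{c.in_channels}), got {x.shape}"
            )
        cache: dict = {"x": x}
        z1, cache["conv1"] = conv2d_forward(x, self.params["W1"], self.params["b1"], stride=1)
        a1, cache["relu"] = relu_forward(z1)
        p, cache["pool"] = maxpool2x2_forward(a1)
        if training and c.drop_rate > 0.0:
            rng = dropout_rng or np.random.default_rng(0)
            mask = (rng.random(p.shape) >= c.drop_rate) / (1.0 - c.drop_rate)
        else:
            mask = None
        d = p * mask if mask is not None else p
        cache["drop_mask"] = mask
        z2, cache["conv2"] = conv2d_forward(d, self.params["W2"], self.params["b2"],
                                            stride=c.primary_stride)
        cache["z2"] = z2
        bsz = x.shape[0]
        u_raw = z2.reshape(bsz, c.n_primary_capsules, c.primary_caps_dim)
        u = squash(u_raw, axis=-1)
        cache["u_raw"], cache["u"] = u_raw, u
        u_hat = np.einsum("bid,ijde->bije", u, self.params["Wd"])
        v, state = dynamic_routing(u_hat, c.routing_iterations)
        cache["u_hat"], cache["v"], cache["routing"] = u_hat, v, state
        cache["lengths"] = np.linalg.norm(v, axis=-1)
        return cache

    def lengths(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)["lengths"]

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Class scores and hard labels (argmax; ties -> lower index)."""
        lengths = self.lengths(x)
        return lengths, lengths.argmax(axis=-1)

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, labels_onehot: np.ndarray) -> tuple[float, dict]:
        """Margin loss and its gradients w.r.t. every parameter.

        The coupling coefficients from the routing loop are treated as
        constants; gradients flow through the final weighted sum and both
        squash applications.
        """
        c = self.cfg
        lengths = cache["lengths"]
        loss = margin_loss(lengths, labels_onehot, c.m_plus, c.m_minus, c.lambda_down)
        dlen = margin_loss_grad(lengths, labels_onehot, c.m_plus, c.m_minus, c.lambda_down)

        v = cache["v"]
        dv = dlen[..., None] * (v / (lengths[..., None] + _EPS))
        dz2, dWd = self._backward_caps(cache, dv)
        grads = {"Wd": dWd}
        dd, grads["W2"], grads["b2"] = conv2d_backward(dz2, cache["conv2"])
        if cache["drop_mask"] is not None:
            dd = dd * cache["drop_mask"]
        da1 = maxpool2x2_backward(dd, cache["pool"])
        dz1 = relu_backward(da1, cache["relu"])
        _, grads["W1"], grads["b1"] = conv2d_backward(dz1, cache["conv1"])
        return loss, grads

    def _backward_caps(self, cache: dict, dv: np.ndarray):
        """Gradient from d(loss)/d(v) back to the PrimaryCaps conv output."""
        c = self.cfg
        coupling = cache["routing"]["c"]  # (B, N_in, N_out)
        # v = squash(s), s_j = sum_i c_ij u_hat_ij  (c fixed)
        s = np.einsum("bij,bijd->bjd", coupling, cache["u_hat"])
        ds = _squash_backward(dv, s, axis=-1)
        du_hat = coupling[..., None] * ds[:, None, :, :]
        du = np.einsum("bije,ijde->bid", du_hat, self.params["Wd"])
        dWd = np.einsum("bid,bije->ijde", cache["u"], du_hat)
        du_raw = _squash_backward(du, cache["u_raw"], axis=-1)
        bsz = dv.shape[0]
        grid = c.primary_grid
        dz2 = du_raw.reshape(bsz, grid, grid, c.primary_caps_types * c.primary_caps_dim)
        return dz2, dWd

    # -- Grad-CAM hook -----------------------------------------------------

    def primary_feature_gradients(self, x: np.ndarray, target_class: int):
        """Feature maps of the PrimaryCaps convolution (pre-reshape) and
        the gradient of the target class's capsule length w.r.t. them.

        Both are (B, h, w, types*d_p); this is the hook Grad-CAM consumes.
        """
        c = self.cfg
        if not 0 <= target_class < c.n_classes:
            raise ValueError(f"target_class must be in [0, {c.n_classes}), got {target_class}")
        cache = self.forward(x)
        v = cache["v"]
        lengths = cache["lengths"]
        dv = np.zeros_like(v)
        dv[:, target_class, :] = v[:, target_class, :] / (lengths[:, target_class, None] + _EPS)
        dz2, _ = self._backward_caps(cache, dv)
        return cache["z2"], dz2

    # -- bookkeeping -------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def parameter_table(self) -> pd.DataFrame:
        """Per-layer trainable parameter counts, counted from the actual
        weight arrays (one row per layer plus a total row)."""
        c = self.cfg
        grid = c.primary_grid
        rows = [
            ("input", f"({c.input_size}, {c.input_size}, {c.in_channels})", 0),
            ("conv_stem", f"({c.input_size}, {c.input_size}, {c.n_filters})",
             self.params["W1"].size + self.params["b1"].size),
            ("max_pool", f"({c.pooled_size}, {c.pooled_size}, {c.n_filters})", 0),
            ("primary_caps", f"({c.n_primary_capsules}, {c.primary_caps_dim})",
             self.params["W2"].size + self.params["b2"].size),
            ("digit_caps", f"({c.n_classes}, {c.digit_caps_dim})", self.params["Wd"].size),
            ("length", f"({c.n_classes},)", 0),
        ]
        df = pd.DataFrame(rows, columns=["layer", "output_shape", "params"])
        df.loc[len(df)] = ("total", "", df["params"].sum())
        return df

    # -- persistence -------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Write weights (.npz) plus a JSON config sidecar (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg), indent=2))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CapsNet":
        path = Path(path)
        cfg = CapsNetConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k].copy() for k in data.files}
        return model


def build_model(cfg: CapsNetConfig, seed: int = 0) -> tuple[CapsNet, pd.DataFrame]:
    """Construct a CapsNet and return it with its parameter table."""
    model = CapsNet(cfg, seed=seed)
    return model, model.parameter_table()
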