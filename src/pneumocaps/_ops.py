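"""Low-level NHWC conv / pool primitives with explicit backward passes.

im2col-based 2-D convolution with TensorFlow-style "same" padding (pad
total = max((out-1)*stride + k - in, 0), split before/after with the extra
pixel after), 2x2 max-pooling, and ReLU.  Forward functions return a cache
consumed by the matching backward function.
"""

from __future__ import annotations

import numpy as np


def same_pad(in_size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Return (out_size, pad_before, pad_after) for 'same' convolution."""
    out = -(-in_size // stride)  # ceil
    total = max((out - 1) * stride + kernel - in_size, 0)
    before = total // 2
    return out, before, total - before


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    b, _, _, c = xp.shape
    cols = np.empty((b, ho, wo, kh, kw, c), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :]
    return cols.reshape(b, ho, wo, kh * kw * c)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1):
    """x: (B,H,W,Cin), w: (kh,kw,Cin,Cout), b: (Cout,). 'Same' padding."""
    kh, kw, cin, cout = w.shape
    if x.shape[-1] != cin:
        raise ValueError(f"channel mismatch: input has {x.shape[-1]}, kernel expects {cin}")
    bsz, h, wid, _ = x.shape
    ho, pt, pb = same_pad(h, kh, stride)
    wo, pl, pr = same_pad(wid, kw, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    cols = _im2col(xp, kh, kw, stride, ho, wo)
    out = cols @ w.reshape(-1, cout) + b
    cache = (cols, w, x.shape, (pt, pb, pl, pr), stride)
    return out, cache


def conv2d_backward(dout: np.ndarray, cache):
    cols, w, x_shape, (pt, pb, pl, pr), stride = cache
    kh, kw, cin, cout = w.shape
    bsz, h, wid, _ = x_shape
    _, ho, wo, _ = dout.shape
    dflat = dout.reshape(-1, cout)
    dw = (cols.reshape(-1, kh * kw * cin).T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(-1, cout).T).reshape(bsz, ho, wo, kh, kw, cin)
    dxp = np.zeros((bsz, h + pt + pb, wid + pl + pr, cin), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += dcols[:, :, :, i, j, :]
    dx = dxp[:, pt : pt + h, pl : pl + wid, :]
    return dx, dw, db


def maxpool2x2_forward(x: np.ndarray):
    """2x2 max pool, stride 2; input H, W must be even."""
    b, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool 2x2 needs even spatial dims, got {h}x{w}")
    win = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2x2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    b, h, w, c = x_shape
    dwin = np.zeros((b, h // 2, w // 2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    # invert the forward transpose (0,1,3,5,2,4): target axis order (b,h2,2,w2,2,c)
    return dwin.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(b, h, w, c)


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask
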