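"""Grad-CAM for the capsule network and lung-localization statistics.

The class score is the target class's capsule length; gradients are taken
with respect to the PrimaryCaps convolution's pre-reshape feature maps
(the network's last convolutional computation).  Channel weights are the
spatial means of those gradients; the heatmap is the ReLU of the weighted
channel sum, min-max normalized to [0, 1] and bilinearly upsampled to the
input size.  ``localization_stat`` quantifies how much supra-threshold
heatmap energy falls inside a ground-truth lung mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .preprocess import resize_bilinear


@dataclass
class Heatmap:
    map: np.ndarray            # H x W floats in [0, 1]
    layer: str
    target_class: int
    all_zero: bool = False     # flagged when the raw map was identically 0


@dataclass
class LocalizationStat:
    threshold: float
    in_lung_fraction: float
    non_lung_fraction: float
    n_active: int
    empty: bool = False        # no pixel exceeded the threshold


def grad_cam(model, image: np.ndarray, target_class: int) -> Heatmap:
    """Gradient-weighted class activation map for one image.

    ``model`` must expose ``primary_feature_gradients(x, target_class)``
    returning (feature maps, gradients), both (B, h, w, K) — the hook
    :class:`~pneumocaps.capsnet.CapsNet` provides.  ``image`` is a single
    (S, S, C) preprocessed array.
    """
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError(f"grad_cam expects one (S, S, C) image, got shape {image.shape}")
    maps, grads = model.primary_feature_gradients(x, target_class)
    maps, grads = maps[0], grads[0]
    weights = grads.mean(axis=(0, 1))
    cam = np.maximum(maps @ weights, 0.0)
    all_zero = cam.max() <= 0.0
    if not all_zero:
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    up = np.clip(resize_bilinear(cam, x.shape[1]), 0.0, 1.0)
    if not all_zero and up.max() > 0:
        up = up / up.max()  # keep the peak at 1 after interpolation
    return Heatmap(map=up, layer="primary_caps_conv",
                   target_class=int(target_class), all_zero=all_zero)


def localization_stat(hm: Heatmap, mask: np.ndarray, tau: float = 0.5) -> LocalizationStat:
    """Share of supra-threshold heatmap pixels inside vs outside the lungs."""
    if not 0.0 < tau < 1.0:
        raise ValueError("threshold tau must be in (0, 1)")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != hm.map.shape:
        raise ValueError(f"mask shape {mask.shape} does not match heatmap {hm.map.shape}")
    active = hm.map > tau
    n = int(active.sum())
    if n == 0:
        return LocalizationStat(threshold=tau, in_lung_fraction=float("nan"),
                                non_lung_fraction=float("nan"), n_active=0, empty=True)
    in_frac = float((active & mask).sum() / n)
    return LocalizationStat(threshold=tau, in_lung_fraction=in_frac,
                            non_lung_fraction=1.0 - in_frac, n_active=n)


def overlay(
    image: np.ndarray,
    hm: Heatmap,
    alpha: float = 0.4,
    out_path: str | os.PathLike | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend the colormapped heatmap onto the grayscale image.

    ``image`` may be uint8 [0, 255] or float [0, 1]; returns (and
    optionally writes) an RGB uint8 array of the same spatial size.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 0]
    if img.shape != hm.map.shape:
        raise ValueError(f"image shape {img.shape} does not match heatmap {hm.map.shape}")
    gray = img.astype(float) / 255.0 if img.dtype == np.uint8 else np.clip(img.astype(float), 0, 1)
    base = np.repeat(gray[..., None], 3, axis=2)
    colored = colormaps[cmap](hm.map)[..., :3]
    blended = (1.0 - alpha) * base + alpha * colored
    out = np.clip(np.rint(blended * 255.0), 0, 255).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(out, mode="RGB").save(out_path)
    return out


def save_heatmap(hm: Heatmap, out_path: str | os.PathLike) -> None:
    """Write the raw activation map as an 8-bit grayscale PNG."""
    Image.fromarray(np.clip(np.rint(hm.map * 255.0), 0, 255).astype(np.uint8), mode="L").save(out_path)
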