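"""Radiograph preprocessing: resize, normalize, denoise, CLAHE, gamma.

The chain runs in a fixed order — bilinear resize to the model's input
size, rescaling of 8-bit intensities to [0, 1], Gaussian denoising,
contrast-limited adaptive histogram equalization (CLAHE) and gamma
correction — followed by replication of the single gray channel to the
channel count the network expects.

The intensity range is tagged by dtype: ``uint8`` arrays are 8-bit
[0, 255] images, floating arrays are real [0, 1] images.  ``normalize01``
refuses float input so the 0-1 rescaling cannot be applied twice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class PreprocessConfig:
    target_size: int = 224
    gaussian_kernel: int = 3          # odd window size, pixels
    gaussian_sigma: float = 1.0
    clahe_clip_limit: float = 2.0     # in 256-bin histogram units (>=256 disables clipping)
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    replicate_channels: int = 3
    clahe_enabled: bool = True

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError(f"target_size must be >= 32, got {self.target_size}")
        if self.gaussian_kernel % 2 == 0 or self.gaussian_kernel < 1:
            raise ValueError(f"gaussian_kernel must be odd and positive, got {self.gaussian_kernel}")
        for name in ("gaussian_sigma", "clahe_clip_limit", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.replicate_channels < 1:
            raise ValueError("replicate_channels must be >= 1")


def resize_bilinear(img: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to target_size x target_size.

    Uses half-pixel-centred sampling: output pixel (r, c) samples the input
    at ((r + 0.5) * H_in / H_out - 0.5, (c + 0.5) * W_in / W_out - 0.5),
    with edge coordinates clamped.  Values never leave the input's range.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    h, w = img.shape[:2]
    if (h, w) == (target_size, target_size):
        return img.copy()
    rows = (np.arange(target_size) + 0.5) * (h / target_size) - 0.5
    cols = (np.arange(target_size) + 0.5) * (w / target_size) - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        img.astype(float), np.stack(grid), order=1, mode="nearest"
    )
    if img.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def normalize01(img: np.ndarray) -> np.ndarray:
    """Rescale an 8-bit image to [0, 1] by dividing by 255."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise TypeError(
            "normalize01 expects an 8-bit (uint8) image; input is already "
            f"{img.dtype} — refusing to normalize twice"
        )
    return img.astype(np.float64) / 255.0


def gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian window, exp(-(x^2+y^2)/(2 sigma^2))."""
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_denoise(img: np.ndarray, kernel: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Convolve with a normalized Gaussian window; reflected borders."""
    k = gaussian_kernel2d(kernel, sigma)
    return ndimage.convolve(np.asarray(img, dtype=float), k, mode="reflect")


def clahe(
    img: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    The image is quantized to 8 bits (the algorithm is histogram-based),
    equalized per tile with the contrast-limited clip and bilinear blending
    of the tile mappings, and rescaled to [0, 1].  ``clip_limit`` is
    expressed in 256-bin histogram units (2.0 clips each bin at twice the
    uniform tile count).
    """
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("clahe expects intensities in [0, 1]")
    h, w = img.shape
    ty, tx = tile_grid
    if ty > h or tx > w:
        raise ValueError(f"tile grid {tile_grid} larger than image {img.shape}")
    if img.max() == img.min():
        return img.copy()  # degenerate histogram: nothing to equalize
    quant = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    out = exposure.equalize_adapthist(
        quant,
        kernel_size=(max(1, h // ty), max(1, w // tx)),
        clip_limit=min(1.0, clip_limit / 256.0),
        nbins=256,
    )
    return np.clip(out, 0.0, 1.0)


def gamma_correct(img: np.ndarray, gamma: float = 1.2) -> np.ndarray:
    """Power-law intensity mapping out = in**gamma on a [0, 1] image."""
    img = np.asarray(img, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if img.min() < 0:
        raise ValueError("gamma correction requires nonnegative intensities")
    return np.power(img, gamma)


def read_grayscale(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array (color → luminance)."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc


def preprocess_array(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Run the full chain on an 8-bit array; returns H×W×C float in [0, 1]."""
    cfg = cfg or PreprocessConfig()
    x = resize_bilinear(np.asarray(img), cfg.target_size)
    x = normalize01(x)
    x = gaussian_denoise(x, cfg.gaussian_kernel, cfg.gaussian_sigma)
    x = np.clip(x, 0.0, 1.0)
    if cfg.clahe_enabled:
        x = clahe(x, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    x = gamma_correct(x, cfg.gamma)
    return np.repeat(x[:, :, None], cfg.replicate_channels, axis=2)


def preprocess_pipeline(path: str | os.PathLike, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Read an image file and run the preprocessing chain on it."""
    return preprocess_array(read_grayscale(path), cfg)


class RadiographPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer wrapping the preprocessing chain.

    ``transform`` accepts a list of file paths or a stack of 8-bit arrays
    and returns an (n, target_size, target_size, channels) float array.
    """

    def __init__(
        self,
        target_size: int = 224,
        gaussian_kernel: int = 3,
        gaussian_sigma: float = 1.0,
        clahe_clip_limit: float = 2.0,
        clahe_tile_grid: tuple[int, int] = (8, 8),
        gamma: float = 1.2,
        replicate_channels: int = 3,
        clahe_enabled: bool = True,
    ):
        self.target_size = target_size
        self.gaussian_kernel = gaussian_kernel
        self.gaussian_sigma = gaussian_sigma
        self.clahe_clip_limit = clahe_clip_limit
        self.clahe_tile_grid = clahe_tile_grid
        self.gamma = gamma
        self.replicate_channels = replicate_channels
        self.clahe_enabled = clahe_enabled

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            target_size=self.target_size,
            gaussian_kernel=self.gaussian_kernel,
            gaussian_sigma=self.gaussian_sigma,
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tile_grid=tuple(self.clahe_tile_grid),
            gamma=self.gamma,
            replicate_channels=self.replicate_channels,
            clahe_enabled=self.clahe_enabled,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        out = []
        for item in X:
            if isinstance(item, (str, os.PathLike)):
                out.append(preprocess_pipeline(item, cfg))
            else:
                out.append(preprocess_array(item, cfg))
        return np.stack(out)
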