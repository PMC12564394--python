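"""Synthetic chest-radiograph generator with ground-truth lung masks.

Real pediatric chest X-rays cannot be bundled with the package, so every
downstream stage (preprocessing, the capsule classifier, Grad-CAM
localization) is exercised on a controllable stand-in: an 8-bit grayscale
thorax-like image with two elliptical lung fields, rib-like periodic
banding, additive Gaussian noise and — for the pneumonia class — one or
more blurred bright opacities whose centres lie inside the lung fields.
The generator also emits the exact binary lung mask of each image, which
is what makes quantitative heatmap-localization tests possible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CLASSES = ("normal", "pneumonia")
POSITIVE_CLASS = "pneumonia"

#: gray levels (0-255) of the scene components
_BACKGROUND = 30.0
_THORAX = 150.0
_LUNG = 80.0
_RIB_AMPLITUDE = 10.0
#: peak added intensity of a pneumonia opacity, in gray levels
_OPACITY_PEAK = 70.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    noise_sd is the standard deviation of the additive Gaussian noise on
    the [0, 1] intensity scale (e.g. 0.02 = ~5 gray levels).
    """

    n_images: int = 100
    class_balance: float = 0.5
    image_size: int = 256
    n_opacities: tuple[int, int] = (1, 4)
    opacity_radius: tuple[float, float] | None = None
    noise_sd: float = 0.02
    seed: int = 0
    image_format: str = "png"  # "png" (lossless) or "jpeg"

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError(f"n_images must be >= 2, got {self.n_images}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(
                f"class_balance must be in (0, 1), got {self.class_balance}"
            )
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_format not in ("png", "jpeg"):
            raise ValueError(f"image_format must be png or jpeg, got {self.image_format!r}")
        if self.opacity_radius is None:
            # scale blob size with the frame so geometry is resolution-invariant
            self.opacity_radius = (self.image_size / 16.0, self.image_size / 8.0)

    @property
    def n_positive(self) -> int:
        return int(round(self.n_images * self.class_balance))


@dataclass
class DatasetManifest:
    """Table of generated files: path, class label, mask path, split."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("path", "label", "mask_path", "split")

    def __post_init__(self) -> None:
        if len(self.records):
            missing = set(self.COLUMNS) - set(self.records.columns)
            if missing:
                raise ValueError(f"manifest missing columns: {sorted(missing)}")
            bad = set(self.records["label"]) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown class labels in manifest: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.records[self.records["split"] == split].reset_index(drop=True))

    def save(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DatasetManifest":
        return cls(pd.read_csv(path))


def _lung_mask(size: int) -> np.ndarray:
    """Two elliptical lung fields inside the thorax; boolean H×W."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = 0.52 * size
    mask = np.zeros((size, size), dtype=bool)
    for cx in (0.33 * size, 0.67 * size):
        e = ((xx - cx) / (0.13 * size)) ** 2 + ((yy - cy) / (0.30 * size)) ** 2
        mask |= e <= 1.0
    return mask


def _thorax_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    e = ((xx - 0.5 * size) / (0.38 * size)) ** 2 + ((yy - 0.52 * size) / (0.42 * size)) ** 2
    return e <= 1.0


def generate_image(
    spec: SyntheticSpec, label: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic radiograph.

    Returns (image uint8 H×W, lung mask bool H×W).  For ``label ==
    "pneumonia"`` between ``spec.n_opacities[0]`` and ``spec.n_opacities[1]``
    blurred bright blobs are added, each centred strictly inside a lung
    field; the normal class gets none.
    """
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}, got {label!r}")
    size = spec.image_size
    thorax = _thorax_mask(size)
    lungs = _lung_mask(size)

    img = np.full((size, size), _BACKGROUND, dtype=float)
    img[thorax] = _THORAX
    img[lungs] = _LUNG

    # rib-like horizontal banding over the thorax wall (kept out of the
    # lung fields so the lung interior carries only noise and opacities)
    yy = np.arange(size, dtype=float)[:, None]
    ribs = _RIB_AMPLITUDE * np.sin(2.0 * np.pi * yy / (size / 9.0))
    img += np.where(thorax & ~lungs, ribs, 0.0)

    if label == POSITIVE_CLASS:
        lo, hi = spec.n_opacities
        n_blobs = int(rng.integers(lo, hi + 1))
        for _ in range(n_blobs):
            r = rng.uniform(*spec.opacity_radius)
            # keep the whole blob inside the lung parenchyma: sample the
            # centre from the mask eroded by roughly the blob radius
            core = ndimage.binary_erosion(lungs, iterations=max(1, int(round(r * 0.75))))
            lung_idx = np.argwhere(core if core.any() else lungs)
            cy, cx = lung_idx[rng.integers(len(lung_idx))]
            yg, xg = np.mgrid[0:size, 0:size].astype(float)
            blob = np.exp(-(((yg - cy) ** 2 + (xg - cx) ** 2) / (2.0 * (r / 2.0) ** 2)))
            img += _OPACITY_PEAK * ndimage.gaussian_filter(blob, sigma=r / 4.0)

    img += rng.normal(0.0, spec.noise_sd * 255.0, size=(size, size))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, lungs


def generate_dataset(spec: SyntheticSpec, out_dir: str | os.PathLike) -> DatasetManifest:
    """Write a labeled dataset of synthetic radiographs to ``out_dir``.

    Layout: ``<out_dir>/<class>/<name>.png`` with lung masks in a parallel
    ``<out_dir>_masks`` tree and a ``manifest.csv`` at the root.  Class
    counts follow ``round(n_images * class_balance)``.  The same spec
    (including seed) reproduces byte-identical images.
    """
    out_dir = Path(out_dir)
    mask_dir = Path(str(out_dir) + "_masks")
    try:
        for cls in CLASSES:
            (out_dir / cls).mkdir(parents=True, exist_ok=True)
            (mask_dir / cls).mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory under {out_dir}: {exc}") from exc

    n_pos = spec.n_positive
    labels = [POSITIVE_CLASS] * n_pos + ["normal"] * (spec.n_images - n_pos)
    rng = np.random.default_rng(spec.seed)
    ext = "png" if spec.image_format == "png" else "jpg"

    rows = []
    for i, label in enumerate(labels):
        img, mask = generate_image(spec, label, rng)
        img_path = out_dir / label / f"{label}_{i:05d}.{ext}"
        mask_path = mask_dir / label / f"{label}_{i:05d}.png"
        Image.fromarray(img, mode="L").save(img_path)
        # masks are always PNG so they stay lossless
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(mask_path)
        rows.append(
            {"path": str(img_path), "label": label, "mask_path": str(mask_path), "split": "unassigned"}
        )

    manifest = DatasetManifest(pd.DataFrame(rows, columns=list(DatasetManifest.COLUMNS)))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a stored lung mask back as a boolean array."""
    return np.asarray(Image.open(path).convert("L")) > 127
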