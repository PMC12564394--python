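"""Dataset splitting and supervised training of the capsule classifier.

Stratified train/validation/test splitting over a dataset manifest
(largest-remainder rounding keeps per-class fractions within one sample),
a thin ``train_model`` wrapper that loads and preprocesses the manifest's
images and fits a :class:`~pneumocaps.estimator.CapsNetClassifier`, and
``evaluate_split`` producing scored predictions plus a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import CapsNetClassifier, TrainLog
from .metrics import ConfusionMatrix, confusion_from_predictions
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synthetic import CLASSES, POSITIVE_CLASS, DatasetManifest


@dataclass
class SplitSpec:
    """Stratified split fractions; must sum to 1."""

    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.val + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split fractions must be nonnegative")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # biggest deficit first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_split(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign train/val/test splits per class, reproducibly under seed."""
    df = manifest.records.copy()
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train, spec.val, spec.test)
    names = ("train", "val", "test")
    split = pd.Series("unassigned", index=df.index)
    for label in df["label"].unique():
        idx = df.index[df["label"] == label].to_numpy()
        if len(idx) < 1:
            raise ValueError(f"class {label!r} has no samples")
        idx = rng.permutation(idx)
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for name, cnt in zip(names, counts):
            split.loc[idx[start : start + cnt]] = name
            start += cnt
    df["split"] = split
    return DatasetManifest(df)


def load_split_arrays(
    manifest: DatasetManifest,
    split: str | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load and preprocess the images of one split (or all).

    Returns (X, y, rows) with X (n, S, S, C) in [0, 1] and y string labels.
    """
    df = manifest.records if split is None else manifest.subset(split).records
    if len(df) == 0:
        raise ValueError(f"split {split!r} is empty")
    missing = [p for p in df["path"] if not __import__("os").path.exists(p)]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")
    X = np.stack([preprocess_pipeline(p, preprocess_cfg) for p in df["path"]])
    return X, df["label"].to_numpy(), df.reset_index(drop=True)


def train_model(
    clf: CapsNetClassifier,
    manifest: DatasetManifest,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[CapsNetClassifier, TrainLog]:
    """Fit the classifier on the manifest's train split, early-stopping on
    the val split; returns the fitted estimator (best-epoch weights) and
    its training log."""
    Xtr, ytr, _ = load_split_arrays(manifest, "train", preprocess_cfg)
    Xval, yval, _ = load_split_arrays(manifest, "val", preprocess_cfg)
    clf.fit(Xtr, ytr, eval_set=(Xval, yval))
    return clf, clf.log_


def evaluate_split(
    clf: CapsNetClassifier,
    manifest: DatasetManifest,
    split: str = "test",
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Score one split: per-image positive-class score and hard label.

    Returns (scored predictions, confusion matrix); positive class =
    pneumonia.
    """
    X, y, rows = load_split_arrays(manifest, split, preprocess_cfg)
    lengths = clf.capsule_lengths(X)
    pos_idx = int(np.where(clf.classes_ == POSITIVE_CLASS)[0][0]) if POSITIVE_CLASS in clf.classes_ else 1
    preds = pd.DataFrame(
        {
            "id": rows["path"],
            "true_label": y,
            "score": lengths[:, pos_idx],
            "pred_label": clf.classes_[lengths.argmax(-1)],
        }
    )
    y_true = (preds["true_label"] == POSITIVE_CLASS).to_numpy().astype(int)
    y_pred = (preds["pred_label"] == POSITIVE_CLASS).to_numpy().astype(int)
    return preds, confusion_from_predictions(y_true, y_pred)


__all__ = [
    "SplitSpec",
    "stratified_split",
    "load_split_arrays",
    "train_model",
    "evaluate_split",
    "CLASSES",
]
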