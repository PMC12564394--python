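"""Run configuration: YAML/JSON loading with strict validation, seed
fan-out, and the end-to-end pipeline (simulate -> preprocess -> train ->
evaluate -> explain).

A single global seed derives per-stage seeds by fixed offsets so any
stage can be rerun in isolation and reproduce its part of a full run.
Every run writes the fully resolved configuration and package version
next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .estimator import CapsNetClassifier
from .explain import grad_cam, localization_stat, overlay, save_heatmap
from .metrics import metrics_report
from .preprocess import PreprocessConfig
from .synthetic import POSITIVE_CLASS, SyntheticSpec, generate_dataset, load_mask
from .training import SplitSpec, evaluate_split, load_split_arrays, stratified_split, train_model

logger = logging.getLogger("pneumocaps")

#: fixed per-stage seed offsets (all derived seeds stay below 2**31)
SEED_OFFSETS = {"simulate": 11, "split": 23, "train": 37, "tune": 53, "explain": 71}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class SimulateSection:
    n_images: int = 120
    class_balance: float = 0.5
    image_size: int = 96
    noise_sd: float = 0.02


@dataclass
class ModelSection:
    input_size: int = 64
    n_filters: int = 8
    primary_caps_types: int = 4
    primary_caps_dim: int = 4
    digit_caps_dim: int = 8
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    drop_rate: float = 0.0


@dataclass
class TrainSection:
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 30
    early_stop_patience: int = 5


@dataclass
class TuneSection:
    n_trials: int = 5
    wall_budget_s: float = 600.0
    trial_epochs_max: int = 2
    data_fraction: float = 0.4


@dataclass
class ExplainSection:
    tau: float = 0.5
    alpha: float = 0.4
    n_images: int = 8


@dataclass
class PreprocessSection:
    target_size: int = 64
    gaussian_kernel: int = 3
    gaussian_sigma: float = 1.0
    clahe_clip_limit: float = 2.0
    gamma: float = 1.2
    replicate_channels: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "runs/run0"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    tune: TuneSection = field(default_factory=TuneSection)
    explain: ExplainSection = field(default_factory=ExplainSection)


class ConfigError(ValueError):
    pass


_RANGES = {
    "train.learning_rate": lambda v: v > 0,
    "train.batch_size": lambda v: v >= 1,
    "train.max_epochs": lambda v: v >= 1,
    "train.early_stop_patience": lambda v: v >= 1,
    "model.routing_iterations": lambda v: v >= 1,
    "model.m_plus": lambda v: 0 < v < 1,
    "model.m_minus": lambda v: 0 < v < 1,
    "model.lambda_down": lambda v: 0 < v <= 1,
    "model.drop_rate": lambda v: 0 <= v < 1,
    "simulate.n_images": lambda v: v >= 2,
    "simulate.class_balance": lambda v: 0 < v < 1,
    "simulate.image_size": lambda v: v >= 32,
    "preprocess.target_size": lambda v: v >= 32,
    "preprocess.gamma": lambda v: v > 0,
    "tune.n_trials": lambda v: v >= 1,
    "tune.data_fraction": lambda v: 0 < v <= 1,
    "explain.tau": lambda v: 0 < v < 1,
    "explain.alpha": lambda v: 0 <= v <= 1,
}


def _build_section(cls, data: dict, prefix: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    kwargs = {}
    for key, value in data.items():
        dotted = prefix + key
        check = _RANGES.get(dotted)
        if check is not None and not check(value):
            raise ConfigError(f"value out of range for {dotted}: {value!r}")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML or JSON run configuration; missing keys get defaults,
    unknown keys and out-of-range values raise ConfigError naming the key."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if overrides:
        data.update(overrides)

    sections = {
        "simulate": SimulateSection,
        "preprocess": PreprocessSection,
        "model": ModelSection,
        "train": TrainSection,
        "tune": TuneSection,
        "explain": ExplainSection,
    }
    top_known = {"seed", "log_level", "out_dir", *sections}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {k: data[k] for k in ("seed", "log_level", "out_dir") if k in data}
    for name, cls in sections.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, sub, name + ".")
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def run_end_to_end(cfg: RunConfig) -> dict:
    """Simulate, preprocess, train, evaluate and explain in one run.

    Returns a dict of artifact paths; raises RuntimeError naming the stage
    that failed.  Idempotent under a fixed seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")
    (out / "VERSION").write_text(__version__ + "\n")
    artifacts = {"config": str(out / "resolved_config.yaml")}

    stage = "simulate"
    try:
        spec = SyntheticSpec(
            n_images=cfg.simulate.n_images,
            class_balance=cfg.simulate.class_balance,
            image_size=cfg.simulate.image_size,
            noise_sd=cfg.simulate.noise_sd,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        manifest = generate_dataset(spec, out / "data")
        manifest = stratified_split(manifest, SplitSpec(seed=stage_seed(cfg.seed, "split")))
        manifest.save(out / "manifest.csv")
        artifacts["manifest"] = str(out / "manifest.csv")

        stage = "train"
        pp = PreprocessConfig(
            target_size=cfg.preprocess.target_size,
            gaussian_kernel=cfg.preprocess.gaussian_kernel,
            gaussian_sigma=cfg.preprocess.gaussian_sigma,
            clahe_clip_limit=cfg.preprocess.clahe_clip_limit,
            gamma=cfg.preprocess.gamma,
            replicate_channels=cfg.preprocess.replicate_channels,
        )
        clf = CapsNetClassifier(
            input_size=cfg.preprocess.target_size,
            n_filters=cfg.model.n_filters,
            primary_caps_types=cfg.model.primary_caps_types,
            primary_caps_dim=cfg.model.primary_caps_dim,
            digit_caps_dim=cfg.model.digit_caps_dim,
            routing_iterations=cfg.model.routing_iterations,
            m_plus=cfg.model.m_plus,
            m_minus=cfg.model.m_minus,
            lambda_down=cfg.model.lambda_down,
            drop_rate=cfg.model.drop_rate,
            learning_rate=cfg.train.learning_rate,
            batch_size=cfg.train.batch_size,
            max_epochs=cfg.train.max_epochs,
            early_stop_patience=cfg.train.early_stop_patience,
            random_state=stage_seed(cfg.seed, "train"),
        )
        clf, log = train_model(clf, manifest, pp)
        log.to_frame().to_csv(out / "train_log.csv", index=False)
        clf.model_.save(out / "checkpoint")
        artifacts["checkpoint"] = str(out / "checkpoint.npz")
        artifacts["train_log"] = str(out / "train_log.csv")

        stage = "evaluate"
        preds, cm = evaluate_split(clf, manifest, "test", pp)
        preds.to_csv(out / "test_scores.csv", index=False)
        y_true = (preds["true_label"] == POSITIVE_CLASS).astype(int)
        y_pred = (preds["pred_label"] == POSITIVE_CLASS).astype(int)
        report = metrics_report(y_true, preds["score"], y_pred)
        report_dict = report.to_dict()
        report_dict["confusion"] = {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}
        (out / "metrics.json").write_text(json.dumps(report_dict, indent=2))
        artifacts["metrics"] = str(out / "metrics.json")

        stage = "explain"
        heat_dir = out / "heatmaps"
        heat_dir.mkdir(exist_ok=True)
        test_rows = manifest.subset("test").records
        pos_rows = test_rows[test_rows["label"] == POSITIVE_CLASS].head(cfg.explain.n_images)
        Xpos, _, rows = load_split_arrays(
            type(manifest)(pos_rows.reset_index(drop=True)), None, pp
        )
        pos_class = int(np.where(clf.classes_ == POSITIVE_CLASS)[0][0])
        stats = []
        for i in range(len(Xpos)):
            hm = grad_cam(clf.model_, Xpos[i], pos_class)
            mask_small = load_mask(rows["mask_path"].iloc[i])
            from .preprocess import resize_bilinear

            mask_rs = resize_bilinear(mask_small.astype(float), cfg.preprocess.target_size) > 0.5
            stat = localization_stat(hm, mask_rs, cfg.explain.tau)
            stats.append(stat.in_lung_fraction)
            stem = Path(rows["path"].iloc[i]).stem
            save_heatmap(hm, heat_dir / f"{stem}_cam.png")
            overlay(Xpos[i], hm, cfg.explain.alpha, heat_dir / f"{stem}_overlay.png")
        (out / "localization.json").write_text(
            json.dumps({"tau": cfg.explain.tau, "in_lung_fractions": stats}, indent=2)
        )
        artifacts["localization"] = str(out / "localization.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return artifacts
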