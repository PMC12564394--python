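"""Sequential model-based hyperparameter search with median pruning.

The search protocol: sample configurations from the declared space
(learning rate log-uniform over [1e-5, 1e-3]; categorical stem-filter
count, primary-capsule dimension and batch size; continuous dropout
rate), train each trial at reduced fidelity (smaller input resolution, a
fixed stratified fraction of the training data, a small epoch cap),
report per-epoch validation accuracies, prune a trial whose intermediate
falls below the running median of its peers at the same epoch, and stop
at a trial-count or wall-clock budget, whichever binds first.

The suggestion engine is a Tree-structured-Parzen-Estimator-style sampler:
after a random warm-up it splits the history at the top objective
quantile, models good and bad configurations with kernel density
estimates (counts for categoricals) and proposes the candidate maximizing
the good/bad density ratio.  A uniform random sampler is available behind
``sampler="random"``.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class SearchSpace:
    """Supports of the tunable hyperparameters."""

    lr: tuple[float, float] = (1e-5, 1e-3)  # log-uniform
    n_filters: tuple[int, ...] = (32, 64, 128)
    drop_rate: tuple[float, float] = (0.0, 0.5)  # uniform
    cap_dim: tuple[int, ...] = (8, 16, 32)
    batch_size: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self) -> None:
        if not (0 < self.lr[0] < self.lr[1]):
            raise ValueError("lr support must satisfy 0 < lo < hi")
        if not self.n_filters or not self.cap_dim or not self.batch_size:
            raise ValueError("categorical supports must be nonempty")
        if not self.drop_rate[0] <= self.drop_rate[1]:
            raise ValueError("drop_rate support must be ordered")

    def contains(self, config: dict) -> bool:
        return (
            self.lr[0] <= config["lr"] <= self.lr[1]
            and config["n_filters"] in self.n_filters
            and self.drop_rate[0] <= config["drop_rate"] <= self.drop_rate[1]
            and config["cap_dim"] in self.cap_dim
            and config["batch_size"] in self.batch_size
        )


@dataclass
class StudyConfig:
    """Budgets and reduced-fidelity settings of one study."""

    n_trials: int = 100
    wall_budget_s: float = 8 * 3600.0
    trial_epochs_max: int = 8
    trial_image_size: int = 112
    data_fraction: float = 0.40
    pruning: bool = True
    warmup_epochs: int = 2
    seed: int = 0
    sampler: str = "tpe"  # "tpe" | "random"

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.wall_budget_s <= 0 or self.trial_epochs_max < 1:
            raise ValueError("budgets must be positive")
        if not 0.0 < self.data_fraction <= 1.0:
            raise ValueError("data_fraction must be in (0, 1]")
        if self.sampler not in ("tpe", "random"):
            raise ValueError(f"sampler must be 'tpe' or 'random', got {self.sampler!r}")


@dataclass
class TrialRecord:
    trial_id: int
    config: dict
    intermediates: list[float] = field(default_factory=list)
    status: str = "running"  # completed | pruned | failed
    objective: float = math.nan

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class StudyResult:
    best_config: dict
    best_objective: float
    trials: list[TrialRecord]

    @property
    def n_pruned(self) -> int:
        return sum(t.status == "pruned" for t in self.trials)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _random_config(space: SearchSpace, rng: np.random.Generator) -> dict:
    return {
        "lr": float(10 ** rng.uniform(math.log10(space.lr[0]), math.log10(space.lr[1]))),
        "n_filters": int(rng.choice(space.n_filters)),
        "drop_rate": float(rng.uniform(*space.drop_rate)),
        "cap_dim": int(rng.choice(space.cap_dim)),
        "batch_size": int(rng.choice(space.batch_size)),
    }


def _kde(values: np.ndarray, lo: float, hi: float):
    """Gaussian KDE with a fixed-bandwidth fallback for degenerate samples."""
    if len(values) < 2 or np.ptp(values) < 1e-12:
        center = values[0] if len(values) else (lo + hi) / 2.0
        bw = max((hi - lo) / 5.0, 1e-9)
        return lambda x: np.exp(-0.5 * ((np.asarray(x) - center) / bw) ** 2) / (
            bw * math.sqrt(2 * math.pi)
        )
    k = gaussian_kde(values)
    return lambda x: k(np.atleast_1d(x))


def _tpe_continuous(good: np.ndarray, bad: np.ndarray, lo: float, hi: float,
                    rng: np.random.Generator, n_candidates: int = 24) -> float:
    gpdf = _kde(good, lo, hi)
    bpdf = _kde(bad, lo, hi)
    # candidates from the good model (jittered around good points) + prior draws
    bw = max((hi - lo) / 5.0, 1e-9)
    cand = []
    for _ in range(n_candidates):
        if len(good) and rng.random() < 0.75:
            cand.append(float(np.clip(rng.choice(good) + rng.normal(0, bw), lo, hi)))
        else:
            cand.append(float(rng.uniform(lo, hi)))
    cand = np.array(cand)
    ratio = np.asarray(gpdf(cand)) / (np.asarray(bpdf(cand)) + 1e-12)
    return float(cand[int(np.argmax(ratio))])


def _tpe_categorical(good: list, bad: list, choices: tuple, rng: np.random.Generator):
    choices = list(choices)
    pg = np.array([1.0 + sum(g == c for g in good) for c in choices])
    pb = np.array([1.0 + sum(b == c for b in bad) for c in choices])
    weights = (pg / pg.sum()) / (pb / pb.sum())
    probs = weights / weights.sum()
    return choices[int(rng.choice(len(choices), p=probs))]


def sample_config(
    space: SearchSpace,
    history: list[TrialRecord],
    rng: np.random.Generator,
    sampler: str = "tpe",
    n_startup: int = 10,
    gamma: float = 0.25,
) -> dict:
    """Propose the next configuration.

    Random until ``n_startup`` completed trials exist (or always with
    ``sampler="random"``); afterwards a TPE-style good/bad density-ratio
    step biased toward higher-objective regions.  Deterministic given the
    rng state and history.
    """
    done = [t for t in history if t.status == "completed" and math.isfinite(t.objective)]
    if sampler == "random" or len(done) < n_startup:
        return _random_config(space, rng)

    done = sorted(done, key=lambda t: t.objective, reverse=True)
    n_good = max(1, math.ceil(gamma * len(done)))
    good, bad = done[:n_good], done[n_good:] or done[n_good - 1 :]

    g_lr = np.log10([t.config["lr"] for t in good])
    b_lr = np.log10([t.config["lr"] for t in bad])
    g_dr = np.array([t.config["drop_rate"] for t in good])
    b_dr = np.array([t.config["drop_rate"] for t in bad])
    lo, hi = math.log10(space.lr[0]), math.log10(space.lr[1])
    return {
        "lr": float(10 ** _tpe_continuous(g_lr, b_lr, lo, hi, rng)),
        "n_filters": int(_tpe_categorical([t.config["n_filters"] for t in good],
                                          [t.config["n_filters"] for t in bad],
                                          space.n_filters, rng)),
        "drop_rate": float(_tpe_continuous(g_dr, b_dr, *space.drop_rate, rng)),
        "cap_dim": int(_tpe_categorical([t.config["cap_dim"] for t in good],
                                        [t.config["cap_dim"] for t in bad],
                                        space.cap_dim, rng)),
        "batch_size": int(_tpe_categorical([t.config["batch_size"] for t in good],
                                           [t.config["batch_size"] for t in bad],
                                           space.batch_size, rng)),
    }


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_decision(value: float, peer_values: list[float], epoch: int, warmup: int = 2) -> bool:
    """True = prune.  Never prunes during warm-up epochs or without peers;
    otherwise prunes iff the intermediate is strictly below the median of
    peer intermediates at the same epoch (ties continue)."""
    if epoch < warmup or not peer_values:
        return False
    return value < float(np.median(peer_values))


# ---------------------------------------------------------------------------
# trials and the study loop
# ---------------------------------------------------------------------------

def _stratified_subsample(labels: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    keep = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n = max(1, int(round(len(idx) * fraction)))
        keep.append(rng.permutation(idx)[:n])
    return np.sort(np.concatenate(keep))


def objective_trial(
    config: dict,
    study_cfg: StudyConfig,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    space: SearchSpace,
    trial_id: int = 0,
    peers_at_epoch=None,
    model_kwargs: dict | None = None,
) -> TrialRecord:
    """Train one reduced-fidelity trial and report per-epoch val accuracy.

    ``data`` is (Xtr, ytr, Xval, yval), already at the trial image size
    and already subsampled to the study's data fraction (the subsample is
    fixed once per study so trials are comparable).  ``peers_at_epoch`` is
    a callable epoch -> list of peer intermediates, used for pruning.
    Objective = best epoch validation accuracy.
    """
    from .capsnet import CapsNet, CapsNetConfig, margin_loss_grad
    from .estimator import _Adam

    if not space.contains(config):
        raise ValueError(f"config outside the search space: {config}")
    record = TrialRecord(trial_id=trial_id, config=dict(config))
    Xtr, ytr, Xval, yval = data
    try:
        kwargs = dict(
            input_size=study_cfg.trial_image_size,
            in_channels=Xtr.shape[-1],
            n_filters=config["n_filters"],
            primary_caps_dim=config["cap_dim"],
            drop_rate=config["drop_rate"],
        )
        kwargs.update(model_kwargs or {})
        cfg = CapsNetConfig(**kwargs)
        model = CapsNet(cfg, seed=study_cfg.seed + trial_id)
    except (ValueError, MemoryError) as exc:
        record.status = "failed"
        record.config["error"] = str(exc)
        return record

    opt = _Adam(model.params, lr=config["lr"])
    eye = np.eye(cfg.n_classes)
    rng = np.random.default_rng(study_cfg.seed * 100003 + trial_id)
    bs = config["batch_size"]
    for epoch in range(1, study_cfg.trial_epochs_max + 1):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), bs):
            ids = order[start : start + bs]
            cache = model.forward(Xtr[ids], training=True, dropout_rng=rng)
            _, grads = model.backward(cache, eye[ytr[ids]])
            opt.step(model.params, grads)
        val_acc = float((model.lengths(Xval).argmax(-1) == yval).mean())
        record.intermediates.append(val_acc)
        if study_cfg.pruning and peers_at_epoch is not None:
            peers = peers_at_epoch(epoch)
            if prune_decision(val_acc, peers, epoch, study_cfg.warmup_epochs):
                record.status = "pruned"
                record.objective = max(record.intermediates)
                return record
    record.status = "completed"
    record.objective = max(record.intermediates)
    return record


def run_study(
    space: SearchSpace,
    study_cfg: StudyConfig,
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    journal_path: str | None = None,
    model_kwargs: dict | None = None,
) -> StudyResult:
    """Run the full search: sample, train, prune, stop at the first budget.

    ``data`` is the full (Xtr, ytr, Xval, yval) at trial resolution; the
    study draws its stratified ``data_fraction`` subsample once.  The best
    configuration is the completed trial with the highest objective.
    """
    rng = np.random.default_rng(study_cfg.seed)
    Xtr, ytr, Xval, yval = data
    sub = _stratified_subsample(np.asarray(ytr), study_cfg.data_fraction, rng)
    trial_data = (Xtr[sub], np.asarray(ytr)[sub], Xval, np.asarray(yval))

    trials: list[TrialRecord] = []
    start_time = time.monotonic()
    journal = Path(journal_path).open("w") if journal_path else None

    def peers_at_epoch(epoch: int) -> list[float]:
        return [t.intermediates[epoch - 1] for t in trials if len(t.intermediates) >= epoch]

    try:
        for trial_id in range(study_cfg.n_trials):
            if time.monotonic() - start_time > study_cfg.wall_budget_s:
                break
            config = sample_config(space, trials, rng, sampler=study_cfg.sampler)
            record = objective_trial(
                config, study_cfg, trial_data, space,
                trial_id=trial_id, peers_at_epoch=peers_at_epoch,
                model_kwargs=model_kwargs,
            )
            trials.append(record)
            if journal:
                journal.write(record.to_json() + "\n")
                journal.flush()
    finally:
        if journal:
            journal.close()

    completed = [t for t in trials if t.status == "completed" and math.isfinite(t.objective)]
    if not completed:
        raise RuntimeError(
            f"study finished with zero completed trials out of {len(trials)} "
            "(all pruned or failed)"
        )
    best = max(completed, key=lambda t: t.objective)
    return StudyResult(best_config=best.config, best_objective=best.objective, trials=trials)
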