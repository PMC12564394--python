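"""Hyperparameter search: sampling supports and distribution, the TPE
history bias, the median pruning rule, and the study loop budgets."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from pneumocaps.hyperopt import (
    SearchSpace,
    StudyConfig,
    TrialRecord,
    objective_trial,
    prune_decision,
    run_study,
    sample_config,
)
from pneumocaps.preprocess import PreprocessConfig
from pneumocaps.training import load_split_arrays

TOY_SPACE = SearchSpace(n_filters=(4, 8), cap_dim=(2, 4), batch_size=(8, 16))
TOY_MODEL = {"primary_caps_types": 2, "digit_caps_dim": 4}


@pytest.fixture(scope="module")
def study_data(small_dataset):
    pp = PreprocessConfig(target_size=32)
    Xtr, ytr, _ = load_split_arrays(small_dataset, "train", pp)
    Xval, yval, _ = load_split_arrays(small_dataset, "val", pp)
    classes = np.unique(ytr)
    return (Xtr, np.searchsorted(classes, ytr), Xval, np.searchsorted(classes, yval))


def _toy_study_cfg(**kw):
    base = dict(n_trials=5, wall_budget_s=300.0, trial_epochs_max=2,
                trial_image_size=32, data_fraction=0.5, seed=1)
    base.update(kw)
    return StudyConfig(**base)


class TestSampling:
    def test_supports_and_log_uniform_lr(self, rng):
        space = SearchSpace()
        draws = [sample_config(space, [], rng) for _ in range(1000)]
        assert all(space.contains(d) for d in draws)
        log_lr = np.log10([d["lr"] for d in draws])
        assert kstest(log_lr, "uniform", args=(-5, 2)).pvalue > 0.01

    def test_categoricals_in_declared_sets(self, rng):
        space = SearchSpace()
        for _ in range(200):
            d = sample_config(space, [], rng)
            assert d["n_filters"] in space.n_filters
            assert d["cap_dim"] in space.cap_dim
            assert d["batch_size"] in space.batch_size

    def test_seeded_determinism_with_history(self):
        rng = np.random.default_rng(0)
        hist = [
            TrialRecord(i, {"lr": float(10 ** rng.uniform(-5, -3)),
                            "n_filters": int(rng.choice([32, 64, 128])),
                            "drop_rate": float(rng.uniform(0, 0.5)),
                            "cap_dim": 8, "batch_size": 16},
                        status="completed", objective=float(rng.random()))
            for i in range(15)
        ]
        a = sample_config(SearchSpace(), hist, np.random.default_rng(9))
        b = sample_config(SearchSpace(), hist, np.random.default_rng(9))
        assert a == b
        assert SearchSpace().contains(a)

    def test_history_biases_toward_better_region(self):
        """With history concentrating high objectives at high lr, the
        TPE step must propose lr above the support midpoint far more
        often than uniform sampling would."""
        rng = np.random.default_rng(3)
        hist = []
        for i in range(40):
            lr = float(10 ** rng.uniform(-5, -3))
            hist.append(TrialRecord(i, {"lr": lr, "n_filters": 64,
                                        "drop_rate": 0.25, "cap_dim": 8, "batch_size": 16},
                                    status="completed",
                                    objective=1.0 if lr > 1e-4 else 0.1))
        picks = [sample_config(SearchSpace(), hist, np.random.default_rng(s))["lr"]
                 for s in range(60)]
        assert np.mean(np.array(picks) > 1e-4) > 0.8

    def test_random_sampler_flag(self, rng):
        hist = [TrialRecord(i, {"lr": 1e-4, "n_filters": 64, "drop_rate": 0.2,
                                "cap_dim": 8, "batch_size": 16},
                            status="completed", objective=0.9) for i in range(20)]
        d = sample_config(SearchSpace(), hist, rng, sampler="random")
        assert SearchSpace().contains(d)


class TestPruning:
    def test_never_prunes_during_warmup(self):
        assert prune_decision(0.0, [0.9, 0.9, 0.9], epoch=1, warmup=2) is False

    def test_prunes_below_median_after_warmup(self):
        assert prune_decision(0.50, [0.8, 0.8, 0.8], epoch=3, warmup=2) is True

    def test_tie_with_median_continues(self):
        assert prune_decision(0.8, [0.7, 0.8, 0.9], epoch=3, warmup=2) is False

    def test_no_peers_continues(self):
        assert prune_decision(0.1, [], epoch=5, warmup=2) is False

    def test_degenerate_trial_pruned_under_median_rule(self):
        """A constant-zero-accuracy trial with three healthy peers is cut
        at the first post-warmup epoch."""
        peers = {1: [0.6, 0.7, 0.8], 2: [0.7, 0.8, 0.85], 3: [0.75, 0.85, 0.9]}
        degenerate = [0.0, 0.0, 0.0]
        pruned_at = None
        for epoch, value in enumerate(degenerate, start=1):
            if prune_decision(value, peers[epoch], epoch, warmup=2):
                pruned_at = epoch
                break
        assert pruned_at == 2


class TestTrials:
    def test_record_has_bounded_intermediates(self, study_data):
        cfg = {"lr": 3e-4, "n_filters": 4, "drop_rate": 0.1, "cap_dim": 2, "batch_size": 8}
        rec = objective_trial(cfg, _toy_study_cfg(), study_data, TOY_SPACE,
                              model_kwargs=TOY_MODEL)
        assert rec.status == "completed"
        assert 1 <= len(rec.intermediates) <= 2
        assert rec.objective == max(rec.intermediates)

    def test_data_fraction_subsample_size(self):
        from pneumocaps.hyperopt import _stratified_subsample

        labels = np.array([0] * 50 + [1] * 50)
        idx = _stratified_subsample(labels, 0.4, np.random.default_rng(0))
        assert len(idx) == 40
        assert (labels[idx] == 0).sum() == 20

    def test_config_outside_space_rejected(self, study_data):
        bad = {"lr": 1.0, "n_filters": 4, "drop_rate": 0.1, "cap_dim": 2, "batch_size": 8}
        with pytest.raises(ValueError, match="outside"):
            objective_trial(bad, _toy_study_cfg(), study_data, TOY_SPACE)

    def test_invalid_derived_shape_fails_gracefully(self, study_data):
        space = SearchSpace(n_filters=(4,), cap_dim=(2,), batch_size=(8,),
                            drop_rate=(0.0, 0.99))
        cfg = {"lr": 3e-4, "n_filters": 4, "drop_rate": 0.1, "cap_dim": 2, "batch_size": 8}
        rec = objective_trial(cfg, _toy_study_cfg(trial_image_size=33), study_data, space,
                              model_kwargs=TOY_MODEL)
        assert rec.status == "failed"
        assert math.isnan(rec.objective)


class TestStudy:
    def test_five_trial_study_returns_argmax(self, study_data, tmp_path):
        res = run_study(TOY_SPACE, _toy_study_cfg(), study_data,
                        journal_path=str(tmp_path / "journal.jsonl"),
                        model_kwargs=TOY_MODEL)
        assert len(res.trials) == 5
        completed = [t for t in res.trials if t.status == "completed"]
        assert res.best_objective == max(t.objective for t in completed)
        assert all(res.best_objective >= t.objective for t in completed)
        assert TOY_SPACE.contains(res.best_config)
        # journal persisted, one record per line
        lines = (tmp_path / "journal.jsonl").read_text().strip().splitlines()
        assert len(lines) == 5

    def test_study_replays_to_same_best(self, study_data):
        a = run_study(TOY_SPACE, _toy_study_cfg(), study_data, model_kwargs=TOY_MODEL)
        b = run_study(TOY_SPACE, _toy_study_cfg(), study_data, model_kwargs=TOY_MODEL)
        assert a.best_config == b.best_config
        assert a.best_objective == b.best_objective

    def test_wall_budget_limits_trials(self, study_data, monkeypatch):
        import time

        import pneumocaps.hyperopt as ho

        def slow_trial(config, study_cfg, data, space, trial_id=0, **kw):
            time.sleep(0.05)
            return TrialRecord(trial_id, dict(config), intermediates=[0.5],
                               status="completed", objective=0.5)

        monkeypatch.setattr(ho, "objective_trial", slow_trial)
        res = ho.run_study(TOY_SPACE, _toy_study_cfg(n_trials=50, wall_budget_s=0.12),
                           study_data, model_kwargs=TOY_MODEL)
        assert 1 <= len(res.trials) < 50

    def test_zero_completed_trials_is_explicit_failure(self, study_data, monkeypatch):
        import pneumocaps.hyperopt as ho

        def failing_trial(config, study_cfg, data, space, trial_id=0, **kw):
            return TrialRecord(trial_id, dict(config), status="failed")

        monkeypatch.setattr(ho, "objective_trial", failing_trial)
        with pytest.raises(RuntimeError, match="zero completed"):
            ho.run_study(TOY_SPACE, _toy_study_cfg(n_trials=3), study_data)

    def test_budget_validation(self):
        with pytest.raises(ValueError):
            StudyConfig(n_trials=0)
        with pytest.raises(ValueError):
            StudyConfig(data_fraction=0.0)
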