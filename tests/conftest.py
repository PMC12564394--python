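"""Shared fixtures: a synthetic dataset on disk and a toy capsule
classifier trained on it, both session-scoped so the expensive training
run happens once."""

from __future__ import annotations

import numpy as np
import pytest

from pneumocaps.estimator import CapsNetClassifier
from pneumocaps.preprocess import PreprocessConfig
from pneumocaps.synthetic import SyntheticSpec, generate_dataset
from pneumocaps.training import SplitSpec, load_split_arrays, stratified_split

#: study conditions of the toy task: 420 synthetic radiographs at 96 px
#: (300 train / 60 val / 60 test), preprocessed to 64 px with CLAHE tiles
#: of the same anatomy-relative size as an 8x8 grid at full resolution
TOY_SEED = 7
TOY_PP = PreprocessConfig(target_size=64, clahe_tile_grid=(2, 2))
TOY_CLF_KWARGS = dict(
    input_size=64,
    n_filters=8,
    primary_caps_types=4,
    primary_caps_dim=4,
    digit_caps_dim=8,
    learning_rate=5e-4,
    batch_size=16,
    max_epochs=10,
    early_stop_patience=5,
    random_state=0,
)


@pytest.fixture(scope="session")
def toy_manifest(tmp_path_factory):
    spec = SyntheticSpec(n_images=420, class_balance=0.5, image_size=96, seed=TOY_SEED)
    manifest = generate_dataset(spec, tmp_path_factory.mktemp("toy") / "data")
    return stratified_split(
        manifest, SplitSpec(train=300 / 420, val=60 / 420, test=60 / 420, seed=TOY_SEED)
    )


@pytest.fixture(scope="session")
def toy_arrays(toy_manifest):
    out = {}
    for split in ("train", "val", "test"):
        out[split] = load_split_arrays(toy_manifest, split, TOY_PP)
    return out


@pytest.fixture(scope="session")
def trained_toy(toy_arrays):
    """Capsule classifier fitted on the toy task (best-epoch weights)."""
    Xtr, ytr, _ = toy_arrays["train"]
    Xval, yval, _ = toy_arrays["val"]
    clf = CapsNetClassifier(**TOY_CLF_KWARGS)
    clf.fit(Xtr, ytr, eval_set=(Xval, yval))
    return clf


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 60-image dataset at 64 px for fast non-training tests."""
    spec = SyntheticSpec(n_images=60, class_balance=0.5, image_size=64, seed=3)
    manifest = generate_dataset(spec, tmp_path_factory.mktemp("small") / "data")
    return stratified_split(manifest, SplitSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
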