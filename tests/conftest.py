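import numpy as np
import pytest

from minens import (
    PreprocessConfig,
    SyntheticSpec,
    adabelief_config,
    build_weak_classifier,
    compute_normalization_stats,
    generate_synthetic_dataset,
    stratified_split,
    train_weak_end_to_end,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small, easy synthetic image-folder dataset with everything the
    training protocols need: index, normalization stats, splits, preprocess."""
    root = tmp_path_factory.mktemp("synth") / "data"
    spec = SyntheticSpec(n_classes=4, counts=(12, 12, 12, 12), image_size=32,
                         difficulty=0.95, seed=7)
    index = generate_synthetic_dataset(spec, root)
    stats = compute_normalization_stats(index)
    splits = stratified_split(index, (0.7, 0.15, 0.15), seed=7)
    pre = PreprocessConfig(target_size=32)
    return {"root": root, "spec": spec, "index": index, "stats": stats,
            "splits": splits, "pre": pre}


@pytest.fixture(scope="session")
def trained_small_weak(small_dataset):
    """A tiny weak classifier trained end-to-end on the small dataset."""
    d = small_dataset
    weak = build_weak_classifier("tiny", d["index"].n_classes, seed=3)
    weak, history = train_weak_end_to_end(
        weak, d["splits"], d["index"], d["stats"],
        adabelief_config(seed=3, max_epochs=40), d["pre"])
    return weak, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
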