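"""Weak classifiers, truncation, ensemble assembly, parameter arithmetic."""

import numpy as np
import pytest

from minens import _nn, models
from minens.errors import (
    CheckpointError,
    ConfigError,
    PretrainedWeightsUnavailableError,
    RegistryError,
)


class TestBuildWeakClassifier:
    def test_output_length_equals_n_classes(self, rng):
        weak = models.build_weak_classifier("tiny", 7, seed=0)
        lp = models.forward_log_probs(weak, rng.random((3, 16, 16, 3)))
        assert lp.shape == (3, 7)
        assert np.allclose(np.exp(lp).sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_build_is_bit_identical(self):
        a = models.build_weak_classifier("tiny", 2, seed=7)
        b = models.build_weak_classifier("tiny", 2, seed=7)
        assert models.parameter_hash(a.parameters()) == \
            models.parameter_hash(b.parameters())
        c = models.build_weak_classifier("tiny", 2, seed=8)
        assert models.parameter_hash(a.parameters()) != \
            models.parameter_hash(c.parameters())

    def test_unknown_backbone(self):
        with pytest.raises(RegistryError):
            models.build_weak_classifier("b9", 5)

    def test_pretrained_without_weights_source(self):
        with pytest.raises(PretrainedWeightsUnavailableError):
            models.build_weak_classifier("tiny", 5, pretrained=True)

    def test_head_parameter_count(self):
        weak = models.build_weak_classifier("tiny", 5, seed=0)
        d = weak.feature_dim
        assert sum(p.size for p in weak.head_parameters()) == d * 5 + 5


class TestParameterCounts:
    def test_b0_total_in_1000_class_configuration(self):
        weak = models.build_weak_classifier("b0", 1000, seed=0)
        total = models.count_parameters(weak).total
        assert total == 5_288_548
        assert round(total / 1e6) == 5  # the "~5M" figure

    def test_b7_total(self):
        weak = models.build_weak_classifier("b7", 1000, seed=0)
        assert models.count_parameters(weak).total == 66_347_960

    @pytest.mark.parametrize("backbone,dim", [
        ("b0", 1280), ("b1", 1280), ("b2", 1408), ("b3", 1536),
        ("b4", 1792), ("b5", 2048), ("b6", 2304), ("b7", 2560), ("tiny", 64)])
    def test_feature_dims(self, backbone, dim):
        assert models.backbone_feature_dim(backbone) == dim

    def test_fusion_trainable_count_two_b0_39_classes(self):
        exts = [models.truncate_to_extractor(
            models.build_weak_classifier("b0", 39, seed=s)) for s in (0, 1)]
        ens = models.build_ensemble(exts[0], exts[1], 39, seed=2)
        counts = models.count_parameters(ens)
        assert counts.trainable == 2560 * 39 + 39 == 99_879
        # ensemble total = both extractors + fusion
        ta, tb = (models.count_parameters(e).total for e in exts)
        assert counts.total == ta + tb + 99_879

    def test_extractor_count_is_weak_minus_head(self):
        weak = models.build_weak_classifier("tiny", 5, seed=0)
        ext = models.truncate_to_extractor(weak)
        d, C = weak.feature_dim, 5
        assert models.count_parameters(ext).total == \
            models.count_parameters(weak).total - (d * C + C)

    def test_fully_frozen_model_has_zero_trainable(self):
        weak = models.build_weak_classifier("tiny", 5, seed=0)
        weak.set_trainable(False)
        assert models.count_parameters(weak).trainable == 0


class TestTruncationAndFusion:
    def test_decomposition_identity(self, rng):
        """head(extractor(x)) reproduces the weak model exactly."""
        weak = models.build_weak_classifier("tiny", 4, seed=1)
        ext = models.truncate_to_extractor(weak)
        x = rng.random((2, 3, 16, 16))
        feats = ext.forward(x)
        assert feats.shape == (2, weak.feature_dim)
        via_parts = weak.log_softmax.forward(weak.head.forward(feats))
        assert np.array_equal(via_parts, weak.forward(x))

    def test_block_weight_fusion_identity(self, rng):
        """Fusion weights [W_a | 0] with bias b_a reproduce weak model a;
        [0 | W_b] with b_b reproduce weak model b."""
        wa = models.build_weak_classifier("tiny", 4, seed=1)
        wb = models.build_weak_classifier("tiny", 4, seed=2)
        ens = models.build_ensemble(models.truncate_to_extractor(wa),
                                    models.truncate_to_extractor(wb), 4, seed=3)
        d = wa.feature_dim
        x = rng.random((3, 3, 16, 16))
        ens.fusion.weight.value[...] = 0.0
        ens.fusion.weight.value[:, :d] = wa.head.weight.value
        ens.fusion.bias.value[...] = wa.head.bias.value
        assert np.allclose(ens.forward(x), wa.forward(x), atol=1e-9)
        ens.fusion.weight.value[...] = 0.0
        ens.fusion.weight.value[:, d:] = wb.head.weight.value
        ens.fusion.bias.value[...] = wb.head.bias.value
        assert np.allclose(ens.forward(x), wb.forward(x), atol=1e-9)

    def test_zero_feature_stub_gives_log_softmax_of_bias(self, rng):
        class ZeroModule(_nn.Module):
            def forward(self, x, train=False):
                return np.zeros((x.shape[0], 8))

        ext = models.FeatureExtractor("tiny", ZeroModule(), feature_dim=8)
        ens = models.build_ensemble(ext, ext, 5, seed=0)
        x = rng.random((2, 3, 8, 8))
        out = ens.forward(x)
        expected = _nn.LogSoftmax().forward(ens.fusion.bias.value[None, :])
        assert np.allclose(out, np.tile(expected, (2, 1)))

    def test_build_ensemble_freezes_extractors(self):
        wa = models.build_weak_classifier("tiny", 3, seed=0)
        wb = models.build_weak_classifier("tiny", 3, seed=1)
        ens = models.build_ensemble(models.truncate_to_extractor(wa),
                                    models.truncate_to_extractor(wb), 3, seed=2)
        trainable = [p for p in ens.parameters() if p.trainable]
        assert trainable == ens.fusion_parameters()

    def test_same_seed_same_fusion_init(self):
        wa = models.build_weak_classifier("tiny", 3, seed=0)
        wb = models.build_weak_classifier("tiny", 3, seed=1)
        e1 = models.build_ensemble(models.truncate_to_extractor(wa),
                                   models.truncate_to_extractor(wb), 3, seed=5)
        e2 = models.build_ensemble(models.truncate_to_extractor(wa),
                                   models.truncate_to_extractor(wb), 3, seed=5)
        assert np.array_equal(e1.fusion.weight.value, e2.fusion.weight.value)


class TestCheckpoints:
    def test_weak_round_trip(self, tmp_path, rng):
        weak = models.build_weak_classifier("tiny", 4, seed=1)
        x = rng.random((2, 16, 16, 3))
        before = models.forward_log_probs(weak, x)
        path = models.save_checkpoint(weak, tmp_path / "w.npz",
                                      classes=["a", "b", "c", "d"], seed=1,
                                      phase="end_to_end")
        loaded, meta = models.load_checkpoint(path)
        assert np.array_equal(models.forward_log_probs(loaded, x), before)
        assert meta["phase"] == "end_to_end"
        assert meta["classes"] == ["a", "b", "c", "d"]

    def test_ensemble_round_trip(self, tmp_path, rng):
        wa = models.build_weak_classifier("tiny", 3, seed=0)
        wb = models.build_weak_classifier("tiny", 3, seed=1)
        ens = models.build_ensemble(models.truncate_to_extractor(wa),
                                    models.truncate_to_extractor(wb), 3, seed=2)
        x = rng.random((2, 16, 16, 3))
        before = models.forward_log_probs(ens, x)
        path = models.save_checkpoint(ens, tmp_path / "e.npz", phase="ensemble")
        loaded, meta = models.load_checkpoint(path)
        assert np.array_equal(models.forward_log_probs(loaded, x), before)
        assert meta["backbone_ids"] == ["tiny", "tiny"]

    def test_class_list_mismatch(self, tmp_path):
        weak = models.build_weak_classifier("tiny", 2, seed=0)
        path = models.save_checkpoint(weak, tmp_path / "w.npz", classes=["x", "y"])
        with pytest.raises(ConfigError):
            models.load_checkpoint(path, expected_classes=["x", "z"])

    def test_missing_file(self, tmp_path):
        with pytest.raises(CheckpointError):
            models.load_checkpoint(tmp_path / "absent.npz")

    def test_invalid_phase_rejected(self, tmp_path):
        weak = models.build_weak_classifier("tiny", 2, seed=0)
        with pytest.raises(ConfigError):
            models.save_checkpoint(weak, tmp_path / "w.npz", phase="bogus")


def test_clone_model_preserves_outputs_and_flags(rng):
    weak = models.build_weak_classifier("tiny", 3, seed=4)
    weak.freeze_backbone()
    clone = models.clone_model(weak)
    x = rng.random((2, 16, 16, 3))
    assert np.array_equal(models.forward_log_probs(clone, x),
                          models.forward_log_probs(weak, x))
    assert clone.backbone_frozen
    assert models.count_parameters(clone).trainable == \
        models.count_parameters(weak).trainable
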