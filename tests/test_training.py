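"""Training loop, phase protocols, selection, and grid combinatorics."""

import numpy as np
import pytest

from minens import _nn, models, training
from minens.errors import ConfigError, LabelError, SelectionError
from minens.metrics import EvalReport, evaluate_model


class TestRegularizedLoss:
    def _log_probs(self):
        return np.log(np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]]))

    def test_zero_lambda_is_plain_nll(self):
        lp = self._log_probs()
        params = [_nn.Parameter(np.array([1.0, -2.0, 3.0]))]
        expected = -(np.log(0.7) + np.log(0.8)) / 2
        got = training.regularized_loss(lp, [0, 1], params,
                                        training.RegularizationSpec())
        assert got == pytest.approx(expected)

    def test_probability_one_gives_zero_loss(self):
        lp = np.log(np.array([[1.0 - 1e-300, 1e-300]]))
        got = training.regularized_loss(lp, [0], [],
                                        training.RegularizationSpec())
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_l1_penalty_hand_computed(self):
        lp = self._log_probs()
        params = [_nn.Parameter(np.array([1.0, -2.0, 3.0]))]
        base = training.regularized_loss(lp, [0, 1], params,
                                         training.RegularizationSpec())
        reg = training.RegularizationSpec("L1", 1e-4)
        assert training.regularized_loss(lp, [0, 1], params, reg) == \
            pytest.approx(base + 6e-4)

    def test_l2_penalty(self):
        params = [_nn.Parameter(np.array([2.0, -1.0]))]
        reg = training.RegularizationSpec("L2", 0.5)
        base = training.regularized_loss(self._log_probs(), [0, 1], params,
                                         training.RegularizationSpec())
        got = training.regularized_loss(self._log_probs(), [0, 1], params, reg)
        assert got == pytest.approx(base + 0.5 * 5.0)

    def test_out_of_range_target(self):
        with pytest.raises(LabelError):
            training.regularized_loss(self._log_probs(), [0, 5], [],
                                      training.RegularizationSpec())

    def test_none_kind_with_nonzero_lambda_rejected(self):
        with pytest.raises(ConfigError):
            training.RegularizationSpec("none", 1e-3)


class TestFit:
    def test_empty_trainable_set(self, small_dataset):
        d = small_dataset
        weak = models.build_weak_classifier("tiny", 4, seed=0)
        with pytest.raises(ConfigError):
            training.fit(weak, [], d["splits"], d["index"], d["stats"],
                         training.adabelief_config())

    def test_seeded_determinism_of_histories_and_weights(self, small_dataset):
        d = small_dataset
        histories, hashes = [], []
        for _ in range(2):
            weak = models.build_weak_classifier("tiny", 4, seed=11)
            cfg = training.adabelief_config(seed=11, max_epochs=5, patience=3)
            _, hist = training.train_weak_end_to_end(
                weak, d["splits"], d["index"], d["stats"], cfg, d["pre"])
            histories.append(hist.records)
            hashes.append(models.parameter_hash(weak.parameters()))
        assert histories[0] == histories[1]
        assert hashes[0] == hashes[1]

    def test_early_stopping_bound_and_best_state(self, small_dataset,
                                                 trained_small_weak):
        d = small_dataset
        weak, hist = trained_small_weak
        if hist.stopped_epoch < 40:  # stopped early, not at the epoch cap
            assert hist.stopped_epoch - hist.best_epoch <= 10
        assert hist.best_epoch <= hist.stopped_epoch
        # the restored model reproduces the best recorded validation score
        report = evaluate_model(weak, d["splits"].indices("valid"), d["index"],
                                d["stats"], preprocess=d["pre"])
        assert report.weighted_f1 == pytest.approx(max(hist.valid_scores()))

    def test_reaches_high_f1_on_easy_data(self, trained_small_weak):
        _, hist = trained_small_weak
        assert max(hist.valid_scores()) >= 0.95


class TestFinetuneProtocols:
    def test_head_finetune_freezes_extractor(self, small_dataset,
                                             trained_small_weak):
        d = small_dataset
        weak = models.clone_model(trained_small_weak[0])
        before = models.parameter_hash(weak.extractor.parameters())
        buffers_before = [b.copy() for _, b in weak.extractor.named_buffers()]
        cfg = training.sgd_config(seed=1, max_epochs=5, patience=3)
        weak, _ = training.finetune_weak_head(
            weak, d["splits"], d["index"], d["stats"], cfg,
            training.RegularizationSpec("L2", 1e-4), d["pre"])
        assert models.parameter_hash(weak.extractor.parameters()) == before
        for old, (_, new) in zip(buffers_before, weak.extractor.named_buffers()):
            assert np.array_equal(old, new)

    def test_lambda_zero_matches_none_trajectory(self, small_dataset,
                                                 trained_small_weak):
        d = small_dataset
        records = []
        for reg in (training.RegularizationSpec(),
                    training.RegularizationSpec("L1", 0.0)):
            weak = models.clone_model(trained_small_weak[0])
            cfg = training.sgd_config(seed=2, max_epochs=4, patience=3)
            _, hist = training.finetune_weak_head(
                weak, d["splits"], d["index"], d["stats"], cfg, reg, d["pre"])
            records.append(hist.records)
        assert records[0] == records[1]

    def test_ensemble_finetune_freezes_both_extractors(self, small_dataset,
                                                       trained_small_weak):
        d = small_dataset
        wa = models.clone_model(trained_small_weak[0])
        wb = models.build_weak_classifier("tiny", 4, seed=5)
        ens = models.build_ensemble(models.truncate_to_extractor(wa),
                                    models.truncate_to_extractor(wb), 4, seed=6)
        hashes = [models.parameter_hash(e.parameters()) for e in ens.extractors]
        cfg = training.adabelief_config(seed=6, max_epochs=6, patience=3)
        ens, hist = training.finetune_ensemble(
            ens, d["splits"], d["index"], d["stats"], cfg, d["pre"])
        assert [models.parameter_hash(e.parameters())
                for e in ens.extractors] == hashes
        # only the fusion layer was trainable
        assert models.count_parameters(ens).trainable == \
            sum(p.size for p in ens.fusion_parameters())

    def test_ensemble_finetune_rejects_unfrozen_extractor(self, small_dataset):
        d = small_dataset
        wa = models.build_weak_classifier("tiny", 4, seed=0)
        wb = models.build_weak_classifier("tiny", 4, seed=1)
        ens = models.build_ensemble(models.truncate_to_extractor(wa),
                                    models.truncate_to_extractor(wb), 4, seed=2)
        ens.extractors[0].set_trainable(True)
        with pytest.raises(ConfigError):
            training.finetune_ensemble(ens, d["splits"], d["index"], d["stats"],
                                       training.adabelief_config())


def _candidate(wf1, seed):
    class Stub:
        pass

    model = Stub()
    model.seed = seed
    return model, EvalReport(split="valid", loss=0.0, accuracy=wf1,
                             weighted_f1=wf1)


class TestSelectTopK:
    def test_picks_two_best_validation_scores(self):
        scores = [0.999485, 0.998969, 0.998454, 0.997423, 0.999227]
        cands = [_candidate(s, seed=i) for i, s in enumerate(scores)]
        top = training.select_top_k(cands, 2)
        assert [r for r, _, _ in top] == [1, 2]
        assert [rep.weighted_f1 for _, _, rep in top] == [0.999485, 0.999227]

    def test_ties_break_by_seed_order(self):
        cands = [_candidate(0.9, seed=s) for s in (3, 1, 2)]
        top = training.select_top_k(cands, 2)
        assert [m.seed for _, m, _ in top] == [1, 2]

    def test_k_zero_and_k_too_large(self):
        cands = [_candidate(0.5, 0)]
        assert training.select_top_k(cands, 0) == []
        with pytest.raises(SelectionError):
            training.select_top_k(cands, 2)


class TestGridCombinatorics:
    def test_full_grid_end_to_end_count(self):
        grid = training.GridSpec(mode="full",
                                 backbones=tuple(f"b{i}" for i in range(8)),
                                 seeds=(0, 1, 2), datasets=("original",))
        plan = training.plan_experiment_grid(grid)
        e2e = [p for p in plan if p.phase == "end_to_end"]
        ft = [p for p in plan if p.phase == "fine_tuned"]
        assert len(e2e) == 24
        assert len(ft) == 24 * 2 * 4 == 192

    def test_full_grid_two_datasets(self):
        grid = training.GridSpec(mode="full",
                                 backbones=tuple(f"b{i}" for i in range(8)),
                                 seeds=(0, 1, 2),
                                 datasets=("original", "augmented"))
        plan = training.plan_experiment_grid(grid)
        assert sum(1 for p in plan if p.phase == "fine_tuned") == 384

    def test_ensemble_scheme_is_2n_per_dataset(self):
        grid = training.GridSpec(mode="ensemble_scheme", backbones=("b0",),
                                 seeds=(0, 1, 2, 3, 4), datasets=("original",))
        plan = training.plan_experiment_grid(grid)
        assert len(plan) == 10
        assert sum(1 for p in plan if p.phase == "end_to_end") == 5
        assert sum(1 for p in plan if p.phase == "ensemble") == 5

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ConfigError):
            training.GridSpec(seeds=(0, 0, 1))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            training.GridSpec(mode="bogus")
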