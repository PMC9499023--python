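"""Training protocols.

Every model goes through a shared early-stopping loop (:func:`fit`) that
optimizes an explicit subset of parameters and tracks validation weighted F1
after each epoch. On top of it sit the three phase protocols:

1. *End-to-end training* of a weak classifier (AdaBelief, no regularization).
2. *Head fine-tuning* — the feature extractor is frozen and only the affine
   output head is retrained (SGD with momentum, optional L1/L2 penalty on the
   head weights).
3. *Ensemble fine-tuning* — both extractors of the minimal ensemble are
   frozen and only the fusion layer is trained (AdaBelief, no penalty).

A single seed drives model initialization, the stratified split, and the
per-epoch shuffle of its run, so independently seeded runs see different data
subsets — the bagging ingredient that makes the two weak models heterogeneous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .data_io import (
    DEFAULT_FRACTIONS,
    DatasetIndex,
    NormalizationStats,
    PreprocessConfig,
    SplitAssignment,
    compute_normalization_stats,
    preprocess_image,
    scan_image_folder,
    stratified_split,
)
from .errors import ConfigError, DivergenceError, LabelError, SelectionError
from .metrics import EvalReport, evaluate_model, weighted_f1
from .models import (
    EnsembleModel,
    WeakClassifier,
    build_ensemble,
    build_weak_classifier,
    clone_model,
    count_parameters,
    truncate_to_extractor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "RegularizationSpec",
    "TrainingHistory",
    "adabelief_config",
    "sgd_config",
    "regularized_loss",
    "fit",
    "train_weak_end_to_end",
    "finetune_weak_head",
    "finetune_ensemble",
    "select_top_k",
    "GridSpec",
    "RunPlan",
    "plan_experiment_grid",
    "run_experiment_grid",
    "REPORT_COLUMNS",
]


# ---------------------------------------------------------------------------
# configuration records


@dataclass(frozen=True)
class TrainingConfig:
    """All loop hyperparameters in one declarative record.

    Defaults are the fixed values used throughout: batch size 32, early
    stopping with patience 10 on validation weighted F1, AdaBelief with
    lr 5e-4, betas (0.9, 0.999), eps 1e-16, decoupled weight decay and no
    rectification; the SGD alternative uses lr 3e-3 with momentum 0.9.
    """

    optimizer: str = "adabelief"
    lr: float = 5e-4
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-16
    weight_decouple: bool = True
    rectify: bool = False
    momentum: float = 0.9
    batch_size: int = 32
    patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in ("adabelief", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("patience, batch_size and max_epochs must be >= 1")

    def build_optimizer(self, params):
        if self.optimizer == "adabelief":
            return _nn.AdaBelief(params, lr=self.lr, betas=self.betas, eps=self.eps,
                                 weight_decouple=self.weight_decouple,
                                 rectify=self.rectify)
        return _nn.SGD(params, lr=self.lr, momentum=self.momentum)


def adabelief_config(seed: int = 0, **overrides) -> TrainingConfig:
    """End-to-end / ensemble phase settings: AdaBelief, lr 5e-4."""
    return replace(TrainingConfig(seed=seed), **overrides)


def sgd_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Head fine-tuning settings: SGD, lr 3e-3, momentum 0.9."""
    return replace(TrainingConfig(optimizer="sgd", lr=3e-3, seed=seed), **overrides)


@dataclass(frozen=True)
class RegularizationSpec:
    """Parameter-norm penalty: none, L1 (lasso) or L2 (ridge)."""

    kind: str = "none"
    lam: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "L1", "L2"):
            raise ConfigError(f"unknown regularization kind {self.kind!r}")
        if self.lam < 0:
            raise ConfigError("regularization factor must be nonnegative")
        if self.kind == "none" and self.lam != 0.0:
            raise ConfigError("kind 'none' requires lambda = 0")

    @property
    def active(self) -> bool:
        return self.kind != "none" and self.lam > 0.0


#: The factor grid explored during head fine-tuning.
REG_LAMBDA_GRID = (0.0, 1e-4, 5e-4, 1e-3)
REG_KINDS = ("L1", "L2")


@dataclass
class TrainingHistory:
    """Per-epoch loop record (1-based epochs)."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def valid_scores(self) -> list[float]:
        return [r["valid_wf1"] for r in self.records]


# ---------------------------------------------------------------------------
# loss


def regularized_loss(log_probs: np.ndarray, targets: np.ndarray,
                     trainable_params, reg: RegularizationSpec) -> float:
    """Mean NLL of the true classes plus the parameter-norm penalty.

    The penalty covers the *trainable* parameters only: ``lam * sum |w|`` for
    L1, ``lam * sum w^2`` for L2.
    """
    log_probs = np.asarray(log_probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64)
    if targets.min() < 0 or targets.max() >= log_probs.shape[1]:
        raise LabelError(f"targets outside [0, {log_probs.shape[1]})")
    loss = -float(log_probs[np.arange(len(targets)), targets].mean())
    return loss + _penalty_value(trainable_params, reg)


def _penalty_value(params, reg: RegularizationSpec) -> float:
    if not reg.active:
        return 0.0
    if reg.kind == "L1":
        return reg.lam * float(sum(np.abs(p.value).sum() for p in params))
    return reg.lam * float(sum((p.value ** 2).sum() for p in params))


def _apply_penalty_grads(params, reg: RegularizationSpec) -> None:
    if not reg.active:
        return
    for p in params:
        if reg.kind == "L1":
            p.grad += reg.lam * np.sign(p.value)
        else:
            p.grad += 2.0 * reg.lam * p.value


# ---------------------------------------------------------------------------
# shared loop


def _preload(data: DatasetIndex, stats: NormalizationStats, indices: list[int],
             preprocess: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([preprocess_image(data.items[i][0], preprocess, stats)
                   for i in indices]).transpose(0, 3, 1, 2)
    ys = data.labels_as_indices()[indices]
    return xs, ys


def _snapshot(model) -> dict:
    state = {f"param.{n}": p.value.copy() for n, p in model.named_parameters()}
    state.update({f"buffer.{n}": b.copy() for n, b in model.named_buffers()})
    return state


def _restore(model, state: dict) -> None:
    for n, p in model.named_parameters():
        p.value[...] = state[f"param.{n}"]
    for n, _ in model.named_buffers():
        model.set_buffer(n, state[f"buffer.{n}"])


def fit(model, trainable_set, splits: SplitAssignment, data: DatasetIndex,
        stats: NormalizationStats, config: TrainingConfig,
        reg: RegularizationSpec = RegularizationSpec(),
        preprocess: PreprocessConfig | None = None) -> tuple[dict, TrainingHistory]:
    """Early-stopping loop over ``trainable_set`` only.

    After each epoch the validation weighted F1 is computed; a strict increase
    marks a new best epoch, and training stops once ``patience`` epochs pass
    without improvement (or at ``max_epochs``). The model is left in — and the
    returned state is — the best-epoch state. Parameters outside
    ``trainable_set`` are untouched.
    """
    trainable_set = list(trainable_set)
    if not trainable_set:
        raise ConfigError("trainable_set must be nonempty")
    preprocess = preprocess or PreprocessConfig()
    train_idx = splits.indices("train")
    valid_idx = splits.indices("valid")
    if not train_idx or not valid_idx:
        raise ConfigError("train and valid splits must be nonempty")
    x_train, y_train = _preload(data, stats, train_idx, preprocess)
    x_valid, y_valid = _preload(data, stats, valid_idx, preprocess)
    n_classes = data.n_classes

    # with a frozen feature stack, features are a fixed function of the input:
    # compute them once and train the head on the cache (same trajectory)
    hooks = getattr(model, "feature_cache_hooks", lambda: None)()
    if hooks is not None:
        transform, fwd, bwd = hooks
        x_train = transform(x_train, config.batch_size)
        x_valid = transform(x_valid, config.batch_size)
    else:
        fwd, bwd = model.forward, model.backward

    rng = np.random.default_rng(config.seed)
    optimizer = config.build_optimizer(trainable_set)
    history = TrainingHistory()
    best_wf1 = -np.inf
    best_state: dict = _snapshot(model)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            model.zero_grad()
            log_probs = fwd(x_train[sel], train=True)
            loss, grad = _nn.nll_loss(log_probs, y_train[sel])
            loss += _penalty_value(trainable_set, reg)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            bwd(grad)
            _apply_penalty_grads(trainable_set, reg)
            optimizer.step()
            losses.append(loss)
        preds = []
        for start in range(0, len(valid_idx), config.batch_size):
            preds.append(fwd(x_valid[start:start + config.batch_size],
                             train=False).argmax(axis=1))
        valid_wf1 = weighted_f1(y_valid, np.concatenate(preds), n_classes)
        history.records.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                                "valid_wf1": valid_wf1})
        if valid_wf1 > best_wf1:  # strict improvement; ties do not reset patience
            best_wf1 = valid_wf1
            history.best_epoch = epoch
            best_state = _snapshot(model)
        history.stopped_epoch = epoch
        if epoch - history.best_epoch >= config.patience:
            break
    _restore(model, best_state)
    return best_state, history


# ---------------------------------------------------------------------------
# phase protocols


def train_weak_end_to_end(weak: WeakClassifier, splits, data, stats,
                          config: TrainingConfig | None = None,
                          preprocess: PreprocessConfig | None = None
                          ) -> tuple[WeakClassifier, TrainingHistory]:
    """Phase 1: train every parameter of the weak classifier (no penalty)."""
    config = config or adabelief_config()
    _, history = fit(weak, weak.parameters(), splits, data, stats, config,
                     RegularizationSpec(), preprocess)
    return weak, history


def finetune_weak_head(weak: WeakClassifier, splits, data, stats,
                       config: TrainingConfig | None = None,
                       reg: RegularizationSpec = RegularizationSpec(),
                       preprocess: PreprocessConfig | None = None
                       ) -> tuple[WeakClassifier, TrainingHistory]:
    """Phase 2: freeze the extractor, retrain the head only (SGD + penalty)."""
    config = config or sgd_config()
    weak.freeze_backbone()
    _, history = fit(weak, weak.head_parameters(), splits, data, stats, config,
                     reg, preprocess)
    return weak, history


def finetune_ensemble(ensemble: EnsembleModel, splits, data, stats,
                      config: TrainingConfig | None = None,
                      preprocess: PreprocessConfig | None = None
                      ) -> tuple[EnsembleModel, TrainingHistory]:
    """Phase 3: train only the fusion layer over frozen extractors."""
    config = config or adabelief_config()
    for ext in ensemble.extractors:
        if any(p.trainable for p in ext.parameters()):
            raise ConfigError("ensemble extractors must be frozen before fine-tuning")
    _, history = fit(ensemble, ensemble.fusion_parameters(), splits, data, stats,
                     config, RegularizationSpec(), preprocess)
    return ensemble, history


def select_top_k(candidates: list[tuple], k: int) -> list[tuple]:
    """Rank (model, EvalReport) candidates by validation weighted F1.

    Descending score; ties broken by lower model seed, then earlier position
    in ``candidates``. Returns ``[(rank, model, report), ...]`` of length k.
    """
    if k > len(candidates):
        raise SelectionError(f"asked for top {k} of {len(candidates)} candidates")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i][1].weighted_f1,
                       getattr(candidates[i][0], "seed", 0), i))
    return [(rank + 1, *candidates[i]) for rank, i in enumerate(order[:k])]


# ---------------------------------------------------------------------------
# experiment grid


REPORT_COLUMNS = ["run_id", "dataset", "backbone", "seed", "phase", "reg_kind",
                  "lambda", "train_wf1", "valid_wf1", "test_wf1", "test_acc",
                  "total_params", "trainable_params", "best_epoch"]


@dataclass(frozen=True)
class RunPlan:
    run_id: str
    dataset: str
    backbone: str
    seed: int
    phase: str
    reg_kind: str = "none"
    lam: float = 0.0


@dataclass(frozen=True)
class GridSpec:
    """Declarative description of an experiment campaign.

    ``mode='full'`` enumerates end-to-end runs over backbones x seeds, then a
    head fine-tuning run for every end-to-end result x regularization type x
    factor. ``mode='ensemble_scheme'`` runs, per dataset, N end-to-end weak
    trainings followed by N ensemble fine-tunings of the two best weak models,
    each ensemble run with its own seed and split.
    """

    mode: str = "full"
    backbones: tuple[str, ...] = ("b0",)
    seeds: tuple[int, ...] = (0, 1, 2)
    reg_kinds: tuple[str, ...] = REG_KINDS
    lambdas: tuple[float, ...] = REG_LAMBDA_GRID
    datasets: tuple[str, ...] = ("original",)
    ensemble_seeds: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.mode not in ("full", "ensemble_scheme"):
            raise ConfigError(f"unknown grid mode {self.mode!r}")
        if not (self.backbones and self.seeds and self.datasets):
            raise ConfigError("backbones, seeds and datasets must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ConfigError("duplicate seeds in grid")
        if self.ensemble_seeds is not None and \
                len(set(self.ensemble_seeds)) != len(self.ensemble_seeds):
            raise ConfigError("duplicate ensemble seeds in grid")

    def resolved_ensemble_seeds(self) -> tuple[int, ...]:
        if self.ensemble_seeds is not None:
            return self.ensemble_seeds
        return tuple(s + 1000 for s in self.seeds)


def plan_experiment_grid(grid: GridSpec) -> list[RunPlan]:
    """Enumerate the runs a grid implies, without executing anything."""
    plan: list[RunPlan] = []
    if grid.mode == "full":
        for ds in grid.datasets:
            for backbone in grid.backbones:
                for seed in grid.seeds:
                    plan.append(RunPlan(f"{ds}/{backbone}/s{seed}/e2e", ds, backbone,
                                        seed, "end_to_end"))
            for backbone in grid.backbones:
                for seed in grid.seeds:
                    for kind in grid.reg_kinds:
                        for lam in grid.lambdas:
                            plan.append(RunPlan(
                                f"{ds}/{backbone}/s{seed}/ft/{kind}/{lam:g}",
                                ds, backbone, seed, "fine_tuned", kind, lam))
    else:
        for ds in grid.datasets:
            for backbone in grid.backbones:
                for seed in grid.seeds:
                    plan.append(RunPlan(f"{ds}/{backbone}/s{seed}/e2e", ds, backbone,
                                        seed, "end_to_end"))
                for seed in grid.resolved_ensemble_seeds():
                    plan.append(RunPlan(f"{ds}/{backbone}/s{seed}/ens", ds, backbone,
                                        seed, "ensemble"))
    return plan


def _report_row(plan: RunPlan, model, history, reports: dict[str, EvalReport]) -> dict:
    counts = count_parameters(model)
    return {
        "run_id": plan.run_id, "dataset": plan.dataset, "backbone": plan.backbone,
        "seed": plan.seed, "phase": plan.phase, "reg_kind": plan.reg_kind,
        "lambda": plan.lam,
        "train_wf1": reports["train"].weighted_f1,
        "valid_wf1": reports["valid"].weighted_f1,
        "test_wf1": reports["test"].weighted_f1,
        "test_acc": reports["test"].accuracy,
        "total_params": counts.total, "trainable_params": counts.trainable,
        "best_epoch": history.best_epoch,
    }


def _evaluate_all(model, splits, data, stats, preprocess) -> dict[str, EvalReport]:
    return {name: evaluate_model(model, splits.indices(name), data, stats,
                                 split_name=name, preprocess=preprocess)
            for name in ("train", "valid", "test")}


def _overlap_fraction(train_idx: list[int], test_idx: list[int]) -> float:
    test = set(test_idx)
    return len(test.intersection(train_idx)) / len(test) if test else 0.0


def run_experiment_grid(grid: GridSpec, dataset_roots: dict[str, Path | str],
                        *, fractions=DEFAULT_FRACTIONS,
                        base_config: TrainingConfig | None = None,
                        preprocess: PreprocessConfig | None = None,
                        pretrained: bool = False,
                        out_csv: Path | str | None = None
                        ) -> tuple[list[RunPlan], pd.DataFrame]:
    """Execute a grid and return (plan, report table).

    Each run derives its stratified split from its own seed, so independently
    seeded weak models train on different random subsets. In ensemble mode the
    fraction of ensemble-test items seen during a weak model's training is
    logged (the per-run splits make some overlap unavoidable).
    """
    plan = plan_experiment_grid(grid)
    base_config = base_config or adabelief_config()
    rows: list[dict] = []
    for ds in grid.datasets:
        if ds not in dataset_roots:
            raise ConfigError(f"no dataset root given for {ds!r}")
        data = scan_image_folder(dataset_roots[ds])
        stats = compute_normalization_stats(data)
        if grid.mode == "full":
            rows.extend(_run_full(grid, ds, data, stats, fractions, base_config,
                                  preprocess, pretrained))
        else:
            rows.extend(_run_ensemble_scheme(grid, ds, data, stats, fractions,
                                             base_config, preprocess, pretrained))
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return plan, table


def _run_full(grid, ds, data, stats, fractions, base_config, preprocess, pretrained):
    rows = []
    trained: dict[tuple[str, int], tuple[WeakClassifier, SplitAssignment]] = {}
    for backbone in grid.backbones:
        for seed in grid.seeds:
            splits = stratified_split(data, fractions, seed)
            weak = build_weak_classifier(backbone, data.n_classes,
                                         pretrained=pretrained, seed=seed)
            cfg = replace(base_config, seed=seed)
            weak, hist = train_weak_end_to_end(weak, splits, data, stats, cfg,
                                               preprocess)
            reports = _evaluate_all(weak, splits, data, stats, preprocess)
            rows.append(_report_row(
                RunPlan(f"{ds}/{backbone}/s{seed}/e2e", ds, backbone, seed,
                        "end_to_end"), weak, hist, reports))
            trained[(backbone, seed)] = (weak, splits)
    for backbone in grid.backbones:
        for seed in grid.seeds:
            weak0, splits = trained[(backbone, seed)]
            for kind in grid.reg_kinds:
                for lam in grid.lambdas:
                    weak = clone_model(weak0)
                    reg = (RegularizationSpec(kind, lam) if lam > 0
                           else RegularizationSpec())
                    cfg = sgd_config(seed=seed, batch_size=base_config.batch_size,
                                     patience=base_config.patience,
                                     max_epochs=base_config.max_epochs)
                    weak, hist = finetune_weak_head(weak, splits, data, stats, cfg,
                                                    reg, preprocess)
                    reports = _evaluate_all(weak, splits, data, stats, preprocess)
                    rows.append(_report_row(
                        RunPlan(f"{ds}/{backbone}/s{seed}/ft/{kind}/{lam:g}", ds,
                                backbone, seed, "fine_tuned", kind, lam),
                        weak, hist, reports))
    return rows


def _run_ensemble_scheme(grid, ds, data, stats, fractions, base_config, preprocess,
                         pretrained):
    rows = []
    for backbone in grid.backbones:
        candidates = []
        weak_splits = {}
        for seed in grid.seeds:
            splits = stratified_split(data, fractions, seed)
            weak = build_weak_classifier(backbone, data.n_classes,
                                         pretrained=pretrained, seed=seed)
            cfg = replace(base_config, seed=seed)
            weak, hist = train_weak_end_to_end(weak, splits, data, stats, cfg,
                                               preprocess)
            reports = _evaluate_all(weak, splits, data, stats, preprocess)
            rows.append(_report_row(
                RunPlan(f"{ds}/{backbone}/s{seed}/e2e", ds, backbone, seed,
                        "end_to_end"), weak, hist, reports))
            candidates.append((weak, reports["valid"]))
            weak_splits[seed] = splits
        top2 = select_top_k(candidates, 2)
        best = [clone_model(model) for _, model, _ in top2]
        for ens_seed in grid.resolved_ensemble_seeds():
            exts = [truncate_to_extractor(clone_model(w)) for w in best]
            ensemble = build_ensemble(exts[0], exts[1], data.n_classes,
                                      seed=ens_seed)
            splits = stratified_split(data, fractions, ens_seed)
            for _, weak, _ in top2:
                frac = _overlap_fraction(
                    weak_splits[weak.seed].indices("train"), splits.indices("test"))
                logger.info("ensemble seed %d: %.1f%% of test items were in weak "
                            "seed %d training split", ens_seed, 100 * frac, weak.seed)
            cfg = replace(base_config, seed=ens_seed)
            ensemble, hist = finetune_ensemble(ensemble, splits, data, stats, cfg,
                                               preprocess)
            reports = _evaluate_all(ensemble, splits, data, stats, preprocess)
            rows.append(_report_row(
                RunPlan(f"{ds}/{backbone}/s{ens_seed}/ens", ds, backbone, ens_seed,
                        "ensemble"), ensemble, hist, reports))
    return rows
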