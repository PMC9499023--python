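"""Model construction: weak classifiers, truncation, and the minimal ensemble.

A *weak classifier* is a convolutional feature extractor (ending in global
average pooling, producing a flat ``d``-vector) topped by an affine head and a
log-softmax over ``C`` classes. The *minimal ensemble* truncates exactly two
trained weak classifiers at the deep-feature level and learns a single affine
fusion layer over the concatenated features — ``(d1 + d2) -> C`` followed by
log-softmax — while both extractors stay frozen.

The backbone registry offers the EfficientNet family (``b0``..``b7``: MBConv
inverted bottlenecks with squeeze-excitation, compound-scaled widths/depths)
and a small ``tiny`` CNN (``d = 64``) for desk-scale experiments. All
architectures are built on the package's own NumPy layer stack, so parameter
counting, forward passes and training need no external framework.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    LogSoftmax,
    MaxPool2d,
    MBConv,
    Module,
    ReLU,
    Sequential,
    SiLU,
    parameter_hash,
)
from .data_io import NormalizationStats
from .errors import (
    CheckpointError,
    ConfigError,
    PretrainedWeightsUnavailableError,
    RegistryError,
    ShapeError,
)

__all__ = [
    "WeakClassifier",
    "FeatureExtractor",
    "EnsembleModel",
    "ParameterCount",
    "available_backbones",
    "backbone_feature_dim",
    "build_weak_classifier",
    "forward_log_probs",
    "truncate_to_extractor",
    "build_ensemble",
    "clone_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "register_pretrained_weights",
    "parameter_hash",
]

# ---------------------------------------------------------------------------
# backbone registry

#: (width_mult, depth_mult) of each EfficientNet variant.
_EFFNET_COEFFS = {
    "b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2), "b3": (1.2, 1.4),
    "b4": (1.4, 1.8), "b5": (1.6, 2.2), "b6": (1.8, 2.6), "b7": (2.0, 3.1),
}

#: Base stage table: (expand_ratio, kernel, stride, out_channels, repeats).
_EFFNET_STAGES = (
    (1, 3, 1, 16, 1),
    (6, 3, 2, 24, 2),
    (6, 5, 2, 40, 2),
    (6, 3, 2, 80, 3),
    (6, 5, 1, 112, 3),
    (6, 5, 2, 192, 4),
    (6, 3, 1, 320, 1),
)

_EFFNET_STEM = 32
_EFFNET_HEAD = 1280

TINY_FEATURE_DIM = 64

_PRETRAINED_WEIGHTS: dict[str, Path] = {}


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def available_backbones() -> list[str]:
    return ["tiny"] + sorted(_EFFNET_COEFFS)


def _check_backbone(backbone_id: str) -> None:
    if backbone_id not in available_backbones():
        raise RegistryError(
            f"unknown backbone {backbone_id!r}; available: {available_backbones()}")


def backbone_feature_dim(backbone_id: str) -> int:
    """Width of the flat feature vector the backbone emits after pooling."""
    _check_backbone(backbone_id)
    if backbone_id == "tiny":
        return TINY_FEATURE_DIM
    width, _ = _EFFNET_COEFFS[backbone_id]
    return _make_divisible(_EFFNET_HEAD * width)


def _build_efficientnet_extractor(backbone_id: str, rng: np.random.Generator) -> Sequential:
    width, depth = _EFFNET_COEFFS[backbone_id]
    stem = _make_divisible(_EFFNET_STEM * width)
    layers: list[Module] = [
        Conv2d(3, stem, 3, rng, stride=2, padding=1), BatchNorm2d(stem), SiLU()]
    in_c = stem
    for expand, kernel, stride, out_base, repeats in _EFFNET_STAGES:
        out_c = _make_divisible(out_base * width)
        for r in range(math.ceil(repeats * depth)):
            layers.append(MBConv(
                in_channels=in_c, out_channels=out_c, expand_ratio=expand,
                kernel_size=kernel, stride=stride if r == 0 else 1,
                squeeze_channels=max(1, in_c // 4), rng=rng))
            in_c = out_c
    head = _make_divisible(_EFFNET_HEAD * width)
    layers += [Conv2d(in_c, head, 1, rng), BatchNorm2d(head), SiLU(), GlobalAvgPool()]
    return Sequential(layers)


def _build_tiny_extractor(rng: np.random.Generator) -> Sequential:
    def block(cin, cout):
        return [Conv2d(cin, cout, 3, rng, padding=1), BatchNorm2d(cout), ReLU()]

    return Sequential(block(3, 16) + [MaxPool2d(2)]
                      + block(16, 32) + [MaxPool2d(2)]
                      + block(32, TINY_FEATURE_DIM) + [GlobalAvgPool()])


def _build_extractor(backbone_id: str, rng: np.random.Generator) -> Sequential:
    if backbone_id == "tiny":
        return _build_tiny_extractor(rng)
    return _build_efficientnet_extractor(backbone_id, rng)


def register_pretrained_weights(backbone_id: str, path: Path | str) -> None:
    """Register a local ``.npz`` of extractor weights to serve as the
    pretrained initialization for ``backbone_id``."""
    _check_backbone(backbone_id)
    _PRETRAINED_WEIGHTS[backbone_id] = Path(path)


# ---------------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class ParameterCount:
    total: int
    trainable: int

    def __post_init__(self):
        if not 0 <= self.trainable <= self.total:
            raise ConfigError("trainable count must lie in [0, total]")


class WeakClassifier(Module):
    """Feature extractor + affine head + log-softmax over ``n_classes``."""

    def __init__(self, backbone_id: str, n_classes: int, extractor: Sequential,
                 head: Linear, seed: int, pretrained: bool):
        self.backbone_id = backbone_id
        self.n_classes = n_classes
        self.feature_dim = backbone_feature_dim(backbone_id)
        self.extractor = extractor
        self.head = head
        self.log_softmax = LogSoftmax()
        self.seed = seed
        self.pretrained = pretrained
        self.backbone_frozen = False

    def children(self):
        return [("extractor", self.extractor), ("head", self.head)]

    def head_parameters(self):
        return self.head.parameters()

    def freeze_backbone(self) -> None:
        self.extractor.set_trainable(False)
        self.backbone_frozen = True

    def forward(self, x, train=False):
        feats = self.extractor.forward(x, train=train and not self.backbone_frozen)
        return self.log_softmax.forward(self.head.forward(feats), train=train)

    def backward(self, grad):
        g = self.head.backward(self.log_softmax.backward(grad))
        if not self.backbone_frozen:
            g = self.extractor.backward(g)
        return g

    def feature_cache_hooks(self):
        """When the extractor is frozen its output is a pure function of the
        input, so the training loop may precompute features once and train the
        head on them. Returns (transform, head_forward, head_backward), or
        None when the backbone is still trainable."""
        if not self.backbone_frozen:
            return None

        def transform(x, batch_size=32):
            return np.concatenate([
                self.extractor.forward(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)])

        def head_forward(feats, train=False):
            return self.log_softmax.forward(self.head.forward(feats), train=train)

        def head_backward(grad):
            return self.head.backward(self.log_softmax.backward(grad))

        return transform, head_forward, head_backward


class FeatureExtractor(Module):
    """A weak classifier truncated before its head; emits flat ``d``-vectors."""

    def __init__(self, backbone_id: str, module: Module,
                 feature_dim: int | None = None):
        self.backbone_id = backbone_id
        self.feature_dim = (feature_dim if feature_dim is not None
                            else backbone_feature_dim(backbone_id))
        self.module = module

    def children(self):
        return [("module", self.module)]

    def forward(self, x, train=False):
        return self.module.forward(x, train=train)

    def backward(self, grad):
        return self.module.backward(grad)


class EnsembleModel(Module):
    """Two frozen extractors fused by one affine + log-softmax layer."""

    def __init__(self, ext_a: FeatureExtractor, ext_b: FeatureExtractor,
                 fusion: Linear, n_classes: int, seed: int):
        self.extractors = (ext_a, ext_b)
        self.fusion = fusion
        self.log_softmax = LogSoftmax()
        self.n_classes = n_classes
        self.seed = seed
        self.frozen_flags = (True, True)
        self.backbone_id = f"{ext_a.backbone_id}+{ext_b.backbone_id}"

    def children(self):
        return [("ext_a", self.extractors[0]), ("ext_b", self.extractors[1]),
                ("fusion", self.fusion)]

    def fusion_parameters(self):
        return self.fusion.parameters()

    def forward_features(self, x, train=False):
        parts = []
        for ext, frozen in zip(self.extractors, self.frozen_flags):
            parts.append(ext.forward(x, train=train and not frozen))
        return np.concatenate(parts, axis=1)

    def forward(self, x, train=False):
        feats = self.forward_features(x, train=train)
        return self.log_softmax.forward(self.fusion.forward(feats), train=train)

    def backward(self, grad):
        # extractors are frozen during ensemble training: gradient stops at
        # the fusion layer
        return self.fusion.backward(self.log_softmax.backward(grad))

    def feature_cache_hooks(self):
        """Concatenated extractor features are constant while both extractors
        are frozen; see :meth:`WeakClassifier.feature_cache_hooks`."""
        if not all(self.frozen_flags):
            return None

        def transform(x, batch_size=32):
            return np.concatenate([
                self.forward_features(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)])

        def head_forward(feats, train=False):
            return self.log_softmax.forward(self.fusion.forward(feats), train=train)

        def head_backward(grad):
            return self.fusion.backward(self.log_softmax.backward(grad))

        return transform, head_forward, head_backward


# ---------------------------------------------------------------------------
# construction operations


def build_weak_classifier(backbone_id: str, n_classes: int, pretrained: bool = False,
                          seed: int = 0) -> WeakClassifier:
    """Build a weak classifier with a freshly seeded ``d -> n_classes`` head.

    With ``pretrained`` set, extractor weights are loaded from a registered
    local weights file (see :func:`register_pretrained_weights`); the head is
    always freshly initialized from ``seed``.
    """
    _check_backbone(backbone_id)
    if n_classes < 2:
        raise ConfigError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    extractor = _build_extractor(backbone_id, rng)
    if pretrained:
        src = _PRETRAINED_WEIGHTS.get(backbone_id)
        if src is None:
            raise PretrainedWeightsUnavailableError(
                f"no pretrained weights registered for {backbone_id!r}; "
                "register a local weights file or build with pretrained=False")
        with np.load(src) as npz:
            arrays = dict(npz)
        _load_state(extractor, arrays, prefix="")
    head = Linear(backbone_feature_dim(backbone_id), n_classes, rng)
    return WeakClassifier(backbone_id, n_classes, extractor, head,
                          seed=seed, pretrained=pretrained)


def forward_log_probs(model: Module, batch: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Run a model on HWC-formatted images and return per-example log-probs.

    ``batch`` is ``(N, H, W, 3)`` (a single ``(H, W, 3)`` image is promoted);
    rows of the result exponentiate to probability distributions.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.ndim != 4 or batch.shape[-1] != 3:
        raise ShapeError(f"expected (N, H, W, 3) batch, got {batch.shape}")
    x = batch.transpose(0, 3, 1, 2)
    outs = [model.forward(x[i:i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def truncate_to_extractor(weak: WeakClassifier) -> FeatureExtractor:
    """Drop the output head, keeping the (shared) below-head parameters."""
    return FeatureExtractor(weak.backbone_id, weak.extractor)


def build_ensemble(ext_a: FeatureExtractor, ext_b: FeatureExtractor,
                   n_classes: int, seed: int = 0) -> EnsembleModel:
    """Assemble the minimal ensemble: frozen ``(ext_a, ext_b)`` (in that
    order) and a freshly seeded fusion layer ``(d1 + d2) -> n_classes``."""
    if n_classes < 2:
        raise ConfigError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    fusion = Linear(ext_a.feature_dim + ext_b.feature_dim, n_classes, rng)
    for ext in (ext_a, ext_b):
        ext.set_trainable(False)
    return EnsembleModel(ext_a, ext_b, fusion, n_classes, seed=seed)


def clone_model(model: Module) -> Module:
    """Deep copy via rebuild-and-restore (values, buffers, trainable flags)."""
    arrays = _state_arrays(model)
    if isinstance(model, WeakClassifier):
        new: Module = build_weak_classifier(model.backbone_id, model.n_classes,
                                            seed=model.seed)
        if model.backbone_frozen:
            new.freeze_backbone()
    elif isinstance(model, EnsembleModel):
        exts = []
        for ext in model.extractors:
            weak = build_weak_classifier(ext.backbone_id, model.n_classes,
                                         seed=model.seed)
            exts.append(truncate_to_extractor(weak))
        new = build_ensemble(exts[0], exts[1], model.n_classes, seed=model.seed)
    else:
        raise ConfigError(f"cannot clone model of type {type(model).__name__}")
    _load_state(new, arrays)
    flags = {n: p.trainable for n, p in model.named_parameters()}
    for n, p in new.named_parameters():
        p.trainable = flags[n]
    return new


def count_parameters(model: Module) -> ParameterCount:
    total = trainable = 0
    for p in model.parameters():
        total += p.size
        if p.trainable:
            trainable += p.size
    return ParameterCount(total=total, trainable=trainable)


# ---------------------------------------------------------------------------
# checkpoints


def _state_arrays(model: Module) -> dict[str, np.ndarray]:
    arrays = {f"param.{name}": p.value for name, p in model.named_parameters()}
    arrays.update({f"buffer.{name}": b for name, b in model.named_buffers()})
    return arrays


def _load_state(model: Module, arrays: dict[str, np.ndarray], prefix: str = "param.") -> None:
    params = dict(model.named_parameters())
    for name, p in params.items():
        key = prefix + name if prefix else name
        if key not in arrays:
            raise CheckpointError(f"checkpoint missing parameter {name}")
        if arrays[key].shape != p.value.shape:
            raise CheckpointError(f"shape mismatch for {name}")
        p.value[...] = arrays[key]
    for name, _ in model.named_buffers():
        key = ("buffer." + name) if prefix else name
        if key in arrays:
            model.set_buffer(name, arrays[key])


def save_checkpoint(model: WeakClassifier | EnsembleModel, path: Path | str, *,
                    classes: list[str] | None = None,
                    stats: NormalizationStats | None = None,
                    seed: int | None = None, phase: str | None = None) -> Path:
    """Serialize weights (npz) with a JSON metadata side-car.

    ``phase`` records the training stage: ``end_to_end``, ``fine_tuned`` or
    ``ensemble``.
    """
    if phase is not None and phase not in ("end_to_end", "fine_tuned", "ensemble"):
        raise ConfigError(f"unknown phase {phase!r}")
    path = Path(path)
    np.savez_compressed(path, **_state_arrays(model))
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "kind": "ensemble" if isinstance(model, EnsembleModel) else "weak",
        "n_classes": model.n_classes,
        "classes": classes,
        "seed": seed if seed is not None else model.seed,
        "phase": phase,
        "mean": list(stats.mean) if stats else None,
        "sd": list(stats.sd) if stats else None,
    }
    if isinstance(model, EnsembleModel):
        meta["backbone_ids"] = [e.backbone_id for e in model.extractors]
    else:
        meta["backbone_id"] = model.backbone_id
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: Path | str, expected_classes: list[str] | None = None
                    ) -> tuple[Module, dict]:
    """Rebuild the model recorded at ``path`` and restore its weights."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not path.exists() or not sidecar.exists():
        raise CheckpointError(f"checkpoint {path} (or its metadata side-car) is missing")
    try:
        meta = json.loads(sidecar.read_text())
        with np.load(path) as npz:
            arrays = dict(npz)
    except (json.JSONDecodeError, OSError, ValueError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if expected_classes is not None and meta.get("classes") is not None:
        if list(expected_classes) != list(meta["classes"]):
            raise ConfigError(
                f"class list mismatch: checkpoint has {meta['classes']}, "
                f"expected {list(expected_classes)}")
    n_classes = meta["n_classes"]
    seed = meta.get("seed") or 0
    if meta["kind"] == "weak":
        model: Module = build_weak_classifier(meta["backbone_id"], n_classes, seed=seed)
    elif meta["kind"] == "ensemble":
        exts = []
        for bid in meta["backbone_ids"]:
            weak = build_weak_classifier(bid, n_classes, seed=seed)
            exts.append(truncate_to_extractor(weak))
        model = build_ensemble(exts[0], exts[1], n_classes, seed=seed)
    else:
        raise CheckpointError(f"unknown checkpoint kind {meta['kind']!r}")
    _load_state(model, arrays)
    return model, meta
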