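"""Evaluation metrics: weighted F1, accuracy, and per-split reports.

Validation-time model selection uses the support-weighted F1 score, which
keeps heavily and lightly populated classes on comparable footing; accuracy is
reported on the test split for comparability with prior work. Scores are kept
in [0, 1] internally; percentage formatting happens only at the CLI surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import DatasetIndex, NormalizationStats, PreprocessConfig, preprocess_image
from .errors import ConfigError, InputError, LabelError

__all__ = ["EvalReport", "weighted_f1", "accuracy", "evaluate_model"]


@dataclass(frozen=True)
class EvalReport:
    split: str
    loss: float
    accuracy: float
    weighted_f1: float
    per_class: dict[str, tuple[float, float, float, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.weighted_f1 <= 1.0):
            raise ConfigError("accuracy and weighted F1 must lie in [0, 1]")

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps({
            "split": self.split, "loss": self.loss, "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "per_class": {k: list(v) for k, v in self.per_class.items()},
        }, indent=2))


def _check_labels(y_true, y_pred, n_classes=None):
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise InputError("y_true and y_pred must be equal-length nonempty 1-D arrays")
    if n_classes is not None:
        for name, y in (("y_true", y_true), ("y_pred", y_pred)):
            if y.min() < 0 or y.max() >= n_classes:
                raise LabelError(f"{name} contains labels outside [0, {n_classes})")
    return y_true, y_pred


def per_class_prf(y_true, y_pred, n_classes: int
                  ) -> list[tuple[float, float, float, int]]:
    """(precision, recall, F1, support) per class; 0 where undefined."""
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    out = []
    for c in range(n_classes):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out.append((precision, recall, f1, tp + fn))
    return out


def weighted_f1(y_true, y_pred, n_classes: int) -> float:
    """Support-weighted mean of per-class F1 scores.

    Classes absent from ``y_true`` carry zero support and drop out of the
    weighting; a class that is present but never correctly retrieved
    contributes F1 = 0.
    """
    prf = per_class_prf(y_true, y_pred, n_classes)
    total = sum(s for _, _, _, s in prf)
    return sum(f1 * s for _, _, f1, s in prf) / total


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact label matches."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def evaluate_model(model, split_indices: list[int], data: DatasetIndex,
                   stats: NormalizationStats, *, split_name: str = "eval",
                   preprocess: PreprocessConfig | None = None,
                   batch_size: int = 32) -> EvalReport:
    """Evaluate a model on the given item indices of a dataset.

    Predictions are the argmax of the log-probabilities (ties resolve to the
    lowest class index). Deterministic for a fixed model and split.
    """
    if not split_indices:
        raise InputError("split is empty")
    if model.n_classes != data.n_classes:
        raise ConfigError(
            f"model has {model.n_classes} classes but dataset has {data.n_classes}")
    preprocess = preprocess or PreprocessConfig()
    labels = data.labels_as_indices()[split_indices]
    log_probs = []
    for start in range(0, len(split_indices), batch_size):
        chunk = split_indices[start:start + batch_size]
        batch = np.stack([
            preprocess_image(data.items[i][0], preprocess, stats) for i in chunk])
        log_probs.append(model.forward(batch.transpose(0, 3, 1, 2), train=False))
    log_probs = np.concatenate(log_probs, axis=0)
    preds = log_probs.argmax(axis=1)
    n = len(labels)
    loss = float(-log_probs[np.arange(n), labels].mean())
    prf = per_class_prf(labels, preds, data.n_classes)
    return EvalReport(
        split=split_name, loss=loss, accuracy=accuracy(labels, preds),
        weighted_f1=weighted_f1(labels, preds, data.n_classes),
        per_class={cls: prf[i] for i, cls in enumerate(data.classes)})
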