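"""Deterministic synthetic datasets for desk-scale experiments.

Generates class-structured RGB image folders whose classes differ along three
independent visual factors — base hue, texture frequency, and blob count — so
that independently trained weak models can pick up partially different
features, leaving the feature-fusion ensemble headroom to improve on either.
Per-image perturbations are scaled by ``1 - difficulty``: at ``difficulty``
near 1 the classes are cleanly separable, near 0 they dissolve into noise.

Also provides Gaussian feature-pair fixtures to exercise the fusion layer in
isolation, without any image pipeline.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data_io import DatasetIndex, scan_image_folder
from .errors import ConfigError, InputError

__all__ = ["SyntheticSpec", "generate_synthetic_dataset", "generate_feature_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Description of a synthetic image-folder dataset.

    ``counts`` may be uneven to emulate the heavy class imbalance of real
    plant-disease collections. ``difficulty`` in (0, 1] is a separation
    parameter: higher values mean less per-image perturbation and therefore
    more separable classes.
    """

    n_classes: int = 5
    counts: tuple[int, ...] = field(default=())
    image_size: int = 64
    difficulty: float = 0.9
    seed: int = 0

    def __post_init__(self):
        counts = self.counts or tuple([40] * self.n_classes)
        object.__setattr__(self, "counts", tuple(counts))
        if len(self.counts) != self.n_classes:
            raise ConfigError("counts must have one entry per class")
        if any(c < 1 for c in self.counts):
            raise ConfigError("all class counts must be >= 1")
        if self.image_size < 8:
            raise ConfigError("image_size must be >= 8")
        if not 0.0 < self.difficulty <= 1.0:
            raise ConfigError("difficulty must lie in (0, 1]")


def _class_signature(spec: SyntheticSpec, c: int) -> dict:
    """Three independent per-class factors, deterministic in (seed, class)."""
    rng = np.random.default_rng((spec.seed, c))
    return {
        # hues evenly spaced on the wheel, with a small seeded offset
        "hue": (c / spec.n_classes + rng.uniform(0, 0.5 / spec.n_classes)) % 1.0,
        "freq": 2 + (c % 4) + rng.integers(0, 2),
        "blobs": 1 + ((c + 1) % 4),
        "blob_radius": spec.image_size * rng.uniform(0.08, 0.14),
    }


def _render_image(spec: SyntheticSpec, sig: dict, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    noise_scale = 1.0 - spec.difficulty
    yy, xx = np.mgrid[0:s, 0:s] / s
    hue = (sig["hue"] + rng.normal(0, 0.15 * noise_scale)) % 1.0
    base = np.array(colorsys.hsv_to_rgb(hue, 0.7, 0.7))
    img = np.broadcast_to(base, (s, s, 3)).copy()
    # sinusoidal texture modulates brightness at a class-specific frequency
    phase = rng.uniform(0, 2 * np.pi)
    texture = 0.15 * np.sin(2 * np.pi * sig["freq"] * xx + phase) \
        * np.sin(2 * np.pi * sig["freq"] * yy + phase)
    img += texture[:, :, None]
    # bright Gaussian blobs, count fixed per class, positions per image
    for _ in range(sig["blobs"]):
        cy, cx = rng.uniform(0.15, 0.85, size=2) * s
        r = sig["blob_radius"] * (1 + rng.normal(0, 0.2 * noise_scale))
        dist2 = (np.arange(s)[:, None] - cy) ** 2 + (np.arange(s)[None, :] - cx) ** 2
        img += 0.3 * np.exp(-dist2 / (2 * max(r, 1.0) ** 2))[:, :, None]
    img += rng.normal(0, 0.35 * noise_scale + 0.02, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir: Path | str) -> DatasetIndex:
    """Write the image-folder tree and return its index.

    Images are PNG (lossless), so regeneration with the same spec and seed is
    byte-identical. The spec is echoed to ``spec.json`` beside the classes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    width = len(str(spec.n_classes - 1))
    for c in range(spec.n_classes):
        sig = _class_signature(spec, c)
        cdir = out_dir / f"class_{c:0{width}d}"
        cdir.mkdir(exist_ok=True)
        rng = np.random.default_rng((spec.seed, c, 1))
        for i in range(spec.counts[c]):
            img = _render_image(spec, sig, rng)
            Image.fromarray((img * 255).round().astype(np.uint8)).save(
                cdir / f"img_{i:04d}.png")
    (out_dir / "spec.json").write_text(json.dumps({
        "n_classes": spec.n_classes, "counts": list(spec.counts),
        "image_size": spec.image_size, "difficulty": spec.difficulty,
        "seed": spec.seed}, indent=2))
    return scan_image_folder(out_dir)


def generate_feature_fixture(n_classes: int, d1: int, d2: int, n_per_class: int,
                             separation: float, seed: int = 0
                             ) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Class-conditional Gaussian feature pairs for fusion-layer tests.

    Class means sit ``separation`` apart (in within-class SD units, which are
    1) along random orthogonal directions of each feature space; at
    ``separation >= 4`` the classes are linearly separable with overwhelming
    probability. Returns ``((X1, X2), y)`` with ``X1: (N, d1)``,
    ``X2: (N, d2)``.
    """
    if d1 < 1 or d2 < 1:
        raise ConfigError("feature dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    y = np.repeat(np.arange(n_classes), n_per_class)
    blocks = []
    for d in (d1, d2):
        raw = rng.normal(size=(max(d, n_classes), n_classes))
        q, _ = np.linalg.qr(raw)
        means = (separation / np.sqrt(2)) * q[:d, :n_classes].T  # (C, d)
        x = means[y] + rng.normal(size=(n, d))
        blocks.append(x)
    return (blocks[0], blocks[1]), y
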