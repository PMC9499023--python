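"""Dataset indexing, stratified splitting, normalization and preprocessing.

The on-disk layout is the standard image-folder convention: one directory per
class, each holding RGB images. The only preprocessing applied to images is a
square resize followed by per-channel standardization ``(x - mean) / sd`` on
intensities rescaled to [0, 1]; no enhancement or augmentation is performed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    ChannelError,
    ConfigError,
    DatasetStructureError,
    InputError,
    NumericError,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

SPLIT_NAMES = ("train", "valid", "test")

#: 90/7/3 split used for comparability with prior PlantVillage benchmarks.
DEFAULT_FRACTIONS = (0.90, 0.07, 0.03)
#: Traditional 80/10/10 split.
CLASSIC_FRACTIONS = (0.80, 0.10, 0.10)


@dataclass(frozen=True)
class DatasetIndex:
    """Catalogue of (path, label) pairs with per-class counts.

    ``classes`` is sorted lexicographically and fixes the label-index mapping
    used everywhere downstream.
    """

    items: tuple[tuple[Path, str], ...]
    classes: tuple[str, ...]
    counts: dict[str, int] = field(compare=False)

    def __post_init__(self):
        if list(self.classes) != sorted(set(self.classes)):
            raise DatasetStructureError("classes must be unique and sorted")
        if sum(self.counts.values()) != len(self.items):
            raise DatasetStructureError("counts do not sum to the number of items")
        for _, label in self.items:
            if label not in self.counts:
                raise DatasetStructureError(f"item label {label!r} not in classes")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_index(self, label: str) -> int:
        return self.classes.index(label)

    def labels_as_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[label] for _, label in self.items], dtype=np.int64)


@dataclass(frozen=True)
class SplitAssignment:
    """Total partition of item indices into train/valid/test."""

    assignment: dict[int, str]
    fractions: tuple[float, float, float]
    seed: int

    def indices(self, split: str) -> list[int]:
        return sorted(i for i, s in self.assignment.items() if s == split)

    def to_csv(self, index: DatasetIndex, path: Path | str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "split", "seed"])
            for i, (p, label) in enumerate(index.items):
                writer.writerow([str(p), label, self.assignment[i], self.seed])


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and population SD of [0, 1]-rescaled intensities."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self):
        if len(self.mean) != 3 or len(self.sd) != 3:
            raise ChannelError("normalization stats must have exactly 3 channels")
        if any(s < 0 for s in self.sd):
            raise NumericError("standard deviations must be nonnegative")

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps({"mean": list(self.mean), "sd": list(self.sd)}))

    @classmethod
    def from_json(cls, path: Path | str) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(mean=tuple(d["mean"]), sd=tuple(d["sd"]))


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 256
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.target_size <= 0:
            raise ConfigError("target_size must be positive")
        if self.interpolation not in _RESAMPLING:
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")


_RESAMPLING = {
    "nearest": Image.Resampling.NEAREST,
    "bilinear": Image.Resampling.BILINEAR,
    "bicubic": Image.Resampling.BICUBIC,
}


def scan_image_folder(root: Path | str) -> DatasetIndex:
    """Index an image-folder tree (``root/<class>/<image>.{png,jpg,jpeg}``).

    Non-image files are skipped with a logged warning. A missing root raises
    :class:`InputError`; an empty tree or an empty class directory raises
    :class:`DatasetStructureError`.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DatasetStructureError(f"no class directories under {root}")
    items: list[tuple[Path, str]] = []
    counts: dict[str, int] = {}
    for cdir in class_dirs:
        files = sorted(cdir.iterdir())
        images = [f for f in files if f.suffix.lower() in IMAGE_EXTENSIONS]
        for f in files:
            if f.is_file() and f.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.warning("skipping non-image file %s", f)
        if not images:
            raise DatasetStructureError(f"class directory {cdir} contains no images")
        counts[cdir.name] = len(images)
        items.extend((f, cdir.name) for f in images)
    return DatasetIndex(items=tuple(items), classes=tuple(d.name for d in class_dirs),
                        counts=counts)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Hamilton apportionment of n items to len(fractions) bins."""
    quotas = [n * f for f in fractions]
    alloc = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(alloc)
    # distribute leftovers by descending fractional part; ties go to the
    # earlier split (train before valid before test)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - alloc[i]), i))
    for i in order[:remainder]:
        alloc[i] += 1
    return alloc


def stratified_split(index: DatasetIndex, fractions: tuple[float, float, float],
                     seed: int) -> SplitAssignment:
    """Per-class largest-remainder allocation with a seeded within-class shuffle.

    Each class's items are shuffled with a generator derived from ``seed`` and
    dealt to train/valid/test in allocation order, so every split preserves the
    class ratio to within one item.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigError("need three positive split fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    assignment: dict[int, str] = {}
    per_class: dict[str, list[int]] = {c: [] for c in index.classes}
    for i, (_, label) in enumerate(index.items):
        per_class[label].append(i)
    for cls in index.classes:  # lexicographic order fixes the rng stream
        idxs = np.array(per_class[cls])
        rng.shuffle(idxs)
        alloc = _largest_remainder(len(idxs), fractions)
        pos = 0
        for split, k in zip(SPLIT_NAMES, alloc):
            for i in idxs[pos:pos + k]:
                assignment[int(i)] = split
            pos += k
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def split_from_csv(index: DatasetIndex, path: Path | str) -> SplitAssignment:
    """Load a split manifest written by :meth:`SplitAssignment.to_csv`."""
    by_path: dict[str, int] = {str(p): i for i, (p, _) in enumerate(index.items)}
    assignment: dict[int, str] = {}
    seed = 0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["path"] not in by_path:
                raise InputError(f"split manifest references unknown item {row['path']}")
            if row["split"] not in SPLIT_NAMES:
                raise InputError(f"unknown split name {row['split']!r}")
            assignment[by_path[row["path"]]] = row["split"]
            seed = int(row["seed"])
    if len(assignment) != len(index):
        raise InputError("split manifest does not cover every dataset item")
    counts = {s: sum(1 for v in assignment.values() if v == s) for s in SPLIT_NAMES}
    n = len(index)
    fractions = tuple(counts[s] / n for s in SPLIT_NAMES)
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


def load_image_rgb(path: Path | str) -> np.ndarray:
    """Decode an image strictly as 3-channel RGB, rescaled to [0, 1]."""
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ChannelError(f"{path}: expected RGB image, got mode {im.mode!r}")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except ChannelError:
        raise
    except OSError as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return arr


def compute_normalization_stats(index: DatasetIndex,
                                subset: set[int] | None = None) -> NormalizationStats:
    """Pooled per-channel mean and population SD over all pixels of the
    selected images (the whole dataset when ``subset`` is None)."""
    if subset is not None and not subset:
        raise InputError("subset must be nonempty when given")
    selected = [path for i, (path, _) in enumerate(index.items)
                if subset is None or i in subset]
    # two passes (mean, then centred second moment) to avoid the cancellation
    # of the one-pass formula on low-variance data
    total = np.zeros(3)
    n_pixels = 0
    for path in selected:
        arr = load_image_rgb(path)
        total += arr.sum(axis=(0, 1))
        n_pixels += arr.shape[0] * arr.shape[1]
    mean = total / n_pixels
    sq_dev = np.zeros(3)
    for path in selected:
        arr = load_image_rgb(path)
        sq_dev += ((arr - mean) ** 2).sum(axis=(0, 1))
    return NormalizationStats(mean=tuple(mean), sd=tuple(np.sqrt(sq_dev / n_pixels)))


def preprocess_image(image: Image.Image | Path | str, cfg: PreprocessConfig,
                     stats: NormalizationStats) -> np.ndarray:
    """Resize to ``target_size`` square and standardize per channel.

    Returns a ``(target_size, target_size, 3)`` float array. Channels whose SD
    is zero are accepted only when the channel is constant and equal to the
    mean (the standardized value is then 0 everywhere); otherwise a
    :class:`NumericError` is raised.
    """
    if isinstance(image, (str, Path)):
        arr = load_image_rgb(image)
        im = Image.fromarray((arr * 255).round().astype(np.uint8))
    else:
        if image.mode != "RGB":
            raise ChannelError(f"expected RGB image, got mode {image.mode!r}")
        im = image
    if im.size != (cfg.target_size, cfg.target_size):
        im = im.resize((cfg.target_size, cfg.target_size), _RESAMPLING[cfg.interpolation])
    x = np.asarray(im, dtype=np.float64) / 255.0
    mean = np.asarray(stats.mean)
    sd = np.asarray(stats.sd)
    out = np.empty_like(x)
    for c in range(3):
        if sd[c] == 0.0:
            if not np.allclose(x[:, :, c], mean[c], atol=1e-12):
                raise NumericError(f"channel {c} has zero SD but non-constant data")
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = (x[:, :, c] - mean[c]) / sd[c]
    return out


def denormalize(x: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse of the standardization step (no resize undo)."""
    return x * np.asarray(stats.sd) + np.asarray(stats.mean)
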