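"""Long-tail dataset construction and synthetic data generators.

Provides the imbalance builder (select per-class subsets so the class counts
follow a requested imbalance factor ``beta = Nmax / Nmin``), a Gaussian-mixture
feature generator whose head classes contain internal subclusters, a tiny
procedural-image generator, and readers for the standard on-disk layouts
(label+pixel-string CSV, one-directory-per-class image folders).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import _round_half_up

__all__ = [
    "LongTailSpec",
    "SyntheticConfig",
    "GaussianSample",
    "BlobImageSample",
    "apply_imbalance",
    "generate_gaussian_longtail",
    "generate_blob_images",
    "load_pixel_csv",
    "load_image_folder",
]

PROFILES = ("exponential", "endpoints_only")


@dataclass(frozen=True)
class LongTailSpec:
    """Per-class training counts (descending by rank) under imbalance ``beta``."""

    class_counts: tuple[int, ...]
    beta: float
    profile: str

    def __post_init__(self):
        counts = tuple(int(c) for c in self.class_counts)
        if len(counts) == 0:
            raise ValueError("class_counts must be non-empty")
        if any(c < 1 for c in counts):
            raise ValueError("all class counts must be >= 1")
        if list(counts) != sorted(counts, reverse=True):
            raise ValueError("class_counts must be descending by rank")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")
        # the realised ratio must match beta up to +-1 sample on the min count
        if abs(min(counts) - max(counts) / self.beta) > 1.0:
            raise ValueError(
                f"counts {counts} do not realise beta={self.beta} within rounding"
            )
        object.__setattr__(self, "class_counts", counts)

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    @property
    def n_max(self) -> int:
        return max(self.class_counts)

    @property
    def n_min(self) -> int:
        return min(self.class_counts)

    def to_dict(self) -> dict:
        return {
            "class_counts": list(self.class_counts),
            "beta": self.beta,
            "profile": self.profile,
        }


def apply_imbalance(
    class_counts_available: Sequence[int],
    beta: float,
    profile: str = "exponential",
    seed: int = 0,
) -> tuple[LongTailSpec, dict[int, np.ndarray]]:
    """Choose per-class sample subsets realising imbalance factor ``beta``.

    Classes are ranked by available count (descending, ties by class index).
    Under the ``exponential`` profile the rank-r class keeps
    ``round(Nmax * beta**(-r / (C-1)))`` samples, the standard geometric decay
    between the endpoints; ``endpoints_only`` keeps observed intermediate
    counts and only trims the last-ranked class to ``round(Nmax / beta)``.
    Subsets are drawn without replacement, reproducibly from ``seed``, and are
    meant for the training split only — test data is never subsetted.

    Returns the spec (counts in rank order) and a dict mapping each original
    class index to the sorted indices kept within that class.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    avail = np.asarray(class_counts_available, dtype=np.int64)
    if avail.ndim != 1 or avail.size == 0:
        raise ValueError("class_counts_available must be a non-empty vector")
    if avail.min() < 1:
        raise ValueError("every class must have at least one available sample")

    C = avail.size
    rank_order = sorted(range(C), key=lambda c: (-avail[c], c))
    n_max = int(avail[rank_order[0]])

    if C == 1:
        targets = [n_max]
    elif profile == "exponential":
        ranks = np.arange(C, dtype=np.float64)
        targets = np.maximum(
            1, _round_half_up(n_max * beta ** (-ranks / (C - 1)))
        ).tolist()
    else:  # endpoints_only
        n_min = max(1, int(_round_half_up(n_max / beta)))
        targets = [n_max]
        for r in range(1, C - 1):
            cls = rank_order[r]
            kept = int(min(avail[cls], n_max))
            if kept < n_min:
                raise ValueError(
                    f"class {cls} has only {avail[cls]} samples, below the "
                    f"minimum count {n_min} required by beta={beta}"
                )
            targets.append(kept)
        targets.append(n_min)

    for r, cls in enumerate(rank_order):
        if avail[cls] < targets[r]:
            raise ValueError(
                f"class {cls} has only {avail[cls]} samples but {targets[r]} "
                f"are required for beta={beta} ({profile} profile)"
            )

    rng = np.random.default_rng(seed)
    subsets: dict[int, np.ndarray] = {}
    for r, cls in enumerate(rank_order):
        chosen = rng.choice(int(avail[cls]), size=int(targets[r]), replace=False)
        subsets[cls] = np.sort(chosen)

    spec = LongTailSpec(
        class_counts=tuple(int(t) for t in targets), beta=float(beta), profile=profile
    )
    return spec, subsets


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the synthetic generators.

    ``subclusters_per_class`` encodes the structural premise the clustering
    method relies on: majority (head) classes occupy broad regions of feature
    space with internal substructure, so their entries exceed 1 while tail
    classes are unimodal.  ``cluster_spread`` is the isotropic within-cluster
    standard deviation; ``between_cluster_distance`` sets both the distance of
    class centers from the origin and the distance of subcluster centers from
    their class center.
    """

    n_classes: int
    counts: tuple[int, ...]
    subclusters_per_class: tuple[int, ...]
    feature_dim: int = 8
    cluster_spread: float = 1.0
    between_cluster_distance: float = 2.5
    seed: int = 0

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        subs = tuple(int(s) for s in self.subclusters_per_class)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(counts) != self.n_classes or len(subs) != self.n_classes:
            raise ValueError(
                "counts and subclusters_per_class must both have length n_classes"
            )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if any(s < 1 for s in subs):
            raise ValueError("all subcluster counts must be >= 1")
        if any(c < s for c, s in zip(counts, subs)):
            bad = next(i for i, (c, s) in enumerate(zip(counts, subs)) if c < s)
            raise ValueError(
                f"class {bad}: counts[{bad}]={counts[bad]} is smaller than its "
                f"subcluster count {subs[bad]}"
            )
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.cluster_spread < 0:
            raise ValueError("cluster_spread must be non-negative")
        if self.between_cluster_distance <= 0:
            raise ValueError("between_cluster_distance must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "subclusters_per_class", subs)


@dataclass(frozen=True)
class GaussianSample:
    """Labelled feature set; ``subclusters`` is hidden ground truth."""

    features: np.ndarray
    labels: np.ndarray
    subclusters: np.ndarray
    config: SyntheticConfig

    @property
    def beta(self) -> float:
        return max(self.config.counts) / min(self.config.counts)


def _unit_rows(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    v = rng.normal(size=(n, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_gaussian_longtail(config: SyntheticConfig) -> GaussianSample:
    """Sample an imbalanced Gaussian-mixture feature set.

    Class centers sit at ``between_cluster_distance`` from the origin in
    random directions; each subcluster center is displaced from its class
    center by the same distance, again in a random direction, so head-class
    subclusters are as far apart as whole classes.  Samples are isotropic
    Gaussian around their subcluster center with std ``cluster_spread``.
    Pure function of the config (seed included): identical configs give
    bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    C, M = config.n_classes, config.feature_dim
    class_centers = _unit_rows(rng, C, M) * config.between_cluster_distance

    feats, labels, subids = [], [], []
    for c in range(C):
        k = config.subclusters_per_class[c]
        if k == 1:
            centers = class_centers[c][None, :]
        else:
            offsets = _unit_rows(rng, k, M) * config.between_cluster_distance
            centers = class_centers[c][None, :] + offsets
        # spread class members across subclusters as evenly as possible
        assignment = np.concatenate(
            [np.full(len(chunk), j, dtype=np.int64)
             for j, chunk in enumerate(np.array_split(np.arange(config.counts[c]), k))]
        )
        noise = rng.normal(size=(config.counts[c], M)) * config.cluster_spread
        feats.append(centers[assignment] + noise)
        labels.append(np.full(config.counts[c], c, dtype=np.int64))
        subids.append(assignment)

    return GaussianSample(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        subclusters=np.concatenate(subids),
        config=config,
    )


@dataclass(frozen=True)
class BlobImageSample:
    """Labelled procedural images in [0, 1]; one shape family per class."""

    images: np.ndarray
    labels: np.ndarray
    subclusters: np.ndarray
    config: SyntheticConfig

    @property
    def beta(self) -> float:
        return max(self.config.counts) / min(self.config.counts)


_SHAPES = ("disk", "square", "cross", "ring", "triangle", "hbar", "vbar")


def _render_shape(shape: str, size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    if shape == "disk":
        mask = dx**2 + dy**2 <= radius**2
    elif shape == "square":
        mask = (np.abs(dx) <= radius) & (np.abs(dy) <= radius)
    elif shape == "cross":
        arm = max(1.0, radius / 3.0)
        mask = ((np.abs(dx) <= arm) & (np.abs(dy) <= radius)) | (
            (np.abs(dy) <= arm) & (np.abs(dx) <= radius)
        )
    elif shape == "ring":
        r2 = dx**2 + dy**2
        mask = (r2 <= radius**2) & (r2 >= (0.55 * radius) ** 2)
    elif shape == "triangle":
        mask = (dy >= -radius) & (dy <= radius) & (np.abs(dx) <= (dy + radius) / 2.0)
    elif shape == "hbar":
        mask = (np.abs(dy) <= radius / 2.5) & (np.abs(dx) <= radius)
    elif shape == "vbar":
        mask = (np.abs(dx) <= radius / 2.5) & (np.abs(dy) <= radius)
    else:  # pragma: no cover - guarded by the shape table
        raise ValueError(f"unknown shape {shape!r}")
    return mask.astype(np.float64)


def generate_blob_images(config: SyntheticConfig, image_size: int = 32) -> BlobImageSample:
    """Render small grayscale images: one shape per class, subcluster = pose.

    Each class draws a distinct shape; subclusters within a class differ in a
    nuisance attribute (anchor position and scale), so intra-class structure
    exists in pixel space too.  Per-sample jitter keeps samples distinct.
    Deterministic in the config seed.
    """
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    rng = np.random.default_rng(config.seed)
    C = config.n_classes
    anchors = [(0.5, 0.5), (0.3, 0.3), (0.7, 0.7), (0.3, 0.7), (0.7, 0.3), (0.5, 0.3)]

    images, labels, subids = [], [], []
    for c in range(C):
        shape = _SHAPES[c % len(_SHAPES)]
        k = config.subclusters_per_class[c]
        assignment = np.concatenate(
            [np.full(len(chunk), j, dtype=np.int64)
             for j, chunk in enumerate(np.array_split(np.arange(config.counts[c]), k))]
        )
        for j in assignment:
            ax, ay = anchors[int(j) % len(anchors)]
            scale = 0.18 + 0.06 * (int(j) % 3)
            jitter = rng.uniform(-0.03, 0.03, size=3)
            cx = (ax + jitter[0]) * (image_size - 1)
            cy = (ay + jitter[1]) * (image_size - 1)
            radius = max(2.0, (scale + jitter[2] * 0.5) * image_size)
            img = _render_shape(shape, image_size, cx, cy, radius)
            img = np.clip(img * 0.9 + rng.uniform(0.0, 0.1, size=img.shape), 0.0, 1.0)
            images.append(img)
        labels.append(np.full(config.counts[c], c, dtype=np.int64))
        subids.append(assignment)

    return BlobImageSample(
        images=np.stack(images),
        labels=np.concatenate(labels),
        subclusters=np.concatenate(subids),
        config=config,
    )


def load_pixel_csv(
    path: str | Path,
    image_side: int,
    split_column: str | int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Read a label+pixel-string CSV into images scaled to [0, 1].

    Expected row layout: an integer label followed by one string of
    ``image_side**2`` space-separated grayscale values in 0-255, optionally
    followed by a split/usage column.  A header row is detected by a
    non-integer first field.  Returns ``(images [N x S x S], labels, splits)``
    with ``splits`` None when no split column applies.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: file is empty")

    header: list[str] | None = None
    try:
        int(rows[0][0])
    except (ValueError, IndexError):
        header = [h.strip() for h in rows[0]]
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")

    split_idx: int | None = None
    if split_column is not None:
        if isinstance(split_column, int):
            split_idx = split_column
        elif header is not None and split_column in header:
            split_idx = header.index(split_column)
        else:
            raise ValueError(f"split column {split_column!r} not found in header")
    elif header is not None and len(header) > 2:
        split_idx = 2

    n_pix = image_side * image_side
    images, labels, splits = [], [], []
    for i, row in enumerate(rows, start=2 if header else 1):
        if len(row) < 2:
            raise ValueError(f"{path}: row {i} has fewer than 2 columns")
        try:
            label = int(row[0])
        except ValueError:
            raise ValueError(f"{path}: row {i} has a non-integer label {row[0]!r}")
        tokens = row[1].split()
        if len(tokens) != n_pix:
            raise ValueError(
                f"{path}: row {i} has {len(tokens)} pixel tokens, expected {n_pix}"
            )
        pixels = np.array(tokens, dtype=np.float64).reshape(image_side, image_side)
        images.append(pixels / 255.0)
        labels.append(label)
        if split_idx is not None:
            if split_idx >= len(row):
                raise ValueError(f"{path}: row {i} is missing the split column")
            splits.append(row[split_idx].strip())

    return (
        np.stack(images),
        np.asarray(labels, dtype=np.int64),
        splits if split_idx is not None else None,
    )


def load_image_folder(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a one-directory-per-class image tree as grayscale arrays in [0, 1].

    Class names are the sorted directory names; files within a class are read
    in sorted order.  All images must share one size.
    """
    from PIL import Image

    path = Path(path)
    class_dirs = sorted(p for p in path.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"{path}: no class directories found")
    images, labels = [], []
    names = [p.name for p in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        files = sorted(
            p for p in cdir.iterdir()
            if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        for f in files:
            arr = np.asarray(Image.open(f).convert("L"), dtype=np.float64) / 255.0
            images.append(arr)
            labels.append(ci)
    if not images:
        raise ValueError(f"{path}: no images found")
    return np.stack(images), np.asarray(labels, dtype=np.int64), names
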