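"""Dynamic intra-class clustering: EMA centroids and subclass pseudo-labels.

Each class keeps an exponential-moving-average centroid of its features,
updated batch by batch.  Within a batch, every class present is split into a
planned number of subclasses by distance to its centroid — either by cutting
the [0, max distance] range into equal-width intervals, or by splitting the
distance-sorted samples into near-equal rank blocks — and each sample receives
a pseudo-label ``subclass_index + class_offset`` in a global pseudo-label
space of size ``P = sum(ns)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LabeledBatch",
    "CentroidState",
    "SubclassPlan",
    "PseudoLabelBatch",
    "update_centroids",
    "compute_distances",
    "partition_equal_width",
    "partition_equal_rank",
    "derive_subclass_plan",
    "assign_pseudo_labels",
]


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    # avoid banker's rounding: 21.5 -> 22
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


@dataclass(frozen=True)
class LabeledBatch:
    """A mini-batch of feature vectors with integer class labels.

    ``batch_index`` is the 1-based position of the batch in the training
    stream; the EMA bookkeeping itself counts updates per class.
    """

    features: np.ndarray
    labels: np.ndarray
    batch_index: int = 1

    def __post_init__(self):
        f = np.asarray(self.features, dtype=np.float64)
        lab = np.asarray(self.labels)
        if f.ndim != 2:
            raise ValueError("features must be a 2-D [B x M] matrix")
        if not np.all(np.isfinite(f)):
            raise ValueError("features contain non-finite values")
        if lab.shape != (f.shape[0],):
            raise ValueError("labels must be a vector of length B")
        lab = lab.astype(np.int64)
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative class indices")
        if self.batch_index < 1:
            raise ValueError("batch_index must be >= 1")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", lab)

    @property
    def size(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class CentroidState:
    """Per-class EMA feature centers with decay ``alpha``.

    ``updates_seen[c] == 0`` means class c has never been observed and its
    center row is meaningless; the first observation sets the center to the
    batch mean, later ones apply ``mu <- alpha * y + (1 - alpha) * mu``.
    """

    centers: np.ndarray
    alpha: float
    updates_seen: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=np.float64)
        seen = np.asarray(self.updates_seen, dtype=np.int64)
        if centers.ndim != 2:
            raise ValueError("centers must be a [C x M] matrix")
        if seen.shape != (centers.shape[0],):
            raise ValueError("updates_seen must have one entry per class")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "updates_seen", seen)

    @classmethod
    def initial(cls, n_classes: int, feature_dim: int, alpha: float = 0.99) -> "CentroidState":
        return cls(
            centers=np.zeros((n_classes, feature_dim)),
            alpha=alpha,
            updates_seen=np.zeros(n_classes, dtype=np.int64),
        )

    @property
    def n_classes(self) -> int:
        return self.centers.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "alpha": self.alpha,
            "updates_seen": self.updates_seen.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidState":
        return cls(
            centers=np.asarray(d["centers"], dtype=np.float64),
            alpha=float(d["alpha"]),
            updates_seen=np.asarray(d["updates_seen"], dtype=np.int64),
        )


@dataclass(frozen=True)
class SubclassPlan:
    """Per-class subclass counts, their cumulative offsets, and the total P.

    The pseudo-label range of class c is ``[offsets[c], offsets[c] + ns[c])``;
    the ranges partition ``[0, total)`` exactly.
    """

    ns: tuple[int, ...]
    offsets: tuple[int, ...]
    total: int

    def __post_init__(self):
        ns = tuple(int(n) for n in self.ns)
        offsets = tuple(int(o) for o in self.offsets)
        if len(ns) == 0:
            raise ValueError("plan must cover at least one class")
        if any(n < 1 for n in ns):
            raise ValueError("every subclass count must be >= 1")
        expected = np.concatenate([[0], np.cumsum(ns)[:-1]])
        if offsets != tuple(int(o) for o in expected):
            raise ValueError("offsets must be the cumulative sums of ns")
        if self.total != sum(ns):
            raise ValueError("total must equal sum(ns)")
        object.__setattr__(self, "ns", ns)
        object.__setattr__(self, "offsets", offsets)

    @classmethod
    def from_ns(cls, ns: Sequence[int]) -> "SubclassPlan":
        ns = tuple(int(n) for n in ns)
        offsets = tuple(int(o) for o in np.concatenate([[0], np.cumsum(ns)[:-1]]))
        return cls(ns=ns, offsets=offsets, total=int(sum(ns)))

    @property
    def n_classes(self) -> int:
        return len(self.ns)

    def class_of(self, pseudo_label: int) -> int:
        """The unique class whose pseudo-label range contains ``pseudo_label``."""
        if not (0 <= pseudo_label < self.total):
            raise ValueError(f"pseudo-label {pseudo_label} outside [0, {self.total})")
        return int(np.searchsorted(self.offsets, pseudo_label, side="right") - 1)

    def to_dict(self) -> dict:
        return {"ns": list(self.ns)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubclassPlan":
        return cls.from_ns(d["ns"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SubclassPlan":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PseudoLabelBatch:
    """Per-sample pseudo-labels, tied to the plan that produced them."""

    pseudo_labels: np.ndarray
    plan: SubclassPlan

    def __post_init__(self):
        pl = np.asarray(self.pseudo_labels, dtype=np.int64)
        if pl.ndim != 1:
            raise ValueError("pseudo_labels must be a vector")
        if pl.size and (pl.min() < 0 or pl.max() >= self.plan.total):
            raise ValueError(f"pseudo-labels must lie in [0, {self.plan.total})")
        object.__setattr__(self, "pseudo_labels", pl)

    def __len__(self) -> int:
        return self.pseudo_labels.shape[0]


def update_centroids(state: CentroidState, batch: LabeledBatch) -> CentroidState:
    """Apply one EMA step for every class present in the batch.

    For a present class c with batch mean y: the first ever update sets
    ``mu_c = y``; afterwards ``mu_c = alpha * y + (1 - alpha) * mu_c``.
    Absent classes are untouched.
    """
    if batch.feature_dim != state.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: batch {batch.feature_dim}, state {state.feature_dim}"
        )
    if batch.labels.size and batch.labels.max() >= state.n_classes:
        raise ValueError("batch contains a label outside the centroid state")
    centers = state.centers.copy()
    seen = state.updates_seen.copy()
    for c in np.unique(batch.labels):
        y = batch.features[batch.labels == c].mean(axis=0)
        if seen[c] == 0:
            centers[c] = y
        else:
            centers[c] = state.alpha * y + (1.0 - state.alpha) * centers[c]
        seen[c] += 1
    return CentroidState(centers=centers, alpha=state.alpha, updates_seen=seen)


def compute_distances(features: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Euclidean distance of each feature row to the center."""
    features = np.asarray(features, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    if features.ndim != 2 or center.ndim != 1 or features.shape[1] != center.shape[0]:
        raise ValueError("features must be [B x M] and center length M")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(center))):
        raise ValueError("non-finite inputs")
    return np.linalg.norm(features - center, axis=1)


def partition_equal_width(distances: np.ndarray, n_sub: int) -> np.ndarray:
    """Cut [0, max(distances)] into ``n_sub`` equal-width intervals.

    Sample i gets index ``min(floor(d_i / d_t), n_sub - 1)`` with
    ``d_t = max(distances) / n_sub``; intervals are half-open with the last
    one closed so every sample is assigned.  A degenerate batch whose
    distances are all equal (to relative precision 1e-9, absorbing float
    noise in genuinely tied distances) carries no spread information and maps
    everything to subclass 0.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty vector")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    dmax = d.max()
    if dmax - d.min() <= 1e-9 * dmax:
        return np.zeros(d.shape, dtype=np.int64)
    dt = dmax / n_sub
    return np.minimum(np.floor(d / dt).astype(np.int64), n_sub - 1)


def partition_equal_rank(distances: np.ndarray, n_sub: int) -> np.ndarray:
    """Split the distance-sorted samples into ``n_sub`` contiguous rank blocks.

    The stable ascending sort order is divided into blocks whose sizes differ
    by at most one (earlier blocks take the remainder); a sample's subclass
    index is its block number.  Ties keep input order.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty vector")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    order = np.argsort(d, kind="stable")
    out = np.empty(d.shape, dtype=np.int64)
    for block_idx, block in enumerate(np.array_split(order, n_sub)):
        out[block] = block_idx
    return out


def derive_subclass_plan(
    class_counts: Sequence[int],
    manual_ns: Sequence[int] | None = None,
    cap: int | None = None,
) -> SubclassPlan:
    """Derive per-class subclass counts from the training class sizes.

    The tail class (smallest count) is the unit: class c is split into
    ``max(1, round(N_c / N_min))`` subclasses, optionally clipped to ``cap``.
    A ``manual_ns`` vector (e.g. a hand-tuned plan from a config file) is used
    verbatim instead.
    """
    counts = np.asarray(class_counts, dtype=np.int64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty vector")
    if counts.min() < 1:
        raise ValueError("every class count must be >= 1")
    if manual_ns is not None:
        manual = [int(n) for n in manual_ns]
        if len(manual) != counts.size:
            raise ValueError(
                f"manual_ns has length {len(manual)}, expected {counts.size}"
            )
        if any(n < 1 for n in manual):
            raise ValueError("manual subclass counts must be >= 1")
        return SubclassPlan.from_ns(manual)
    ns = np.maximum(1, _round_half_up(counts / counts.min()))
    if cap is not None:
        ns = np.minimum(ns, int(cap))
    return SubclassPlan.from_ns(ns.tolist())


def assign_pseudo_labels(
    batch: LabeledBatch,
    state: CentroidState,
    plan: SubclassPlan,
    mode: str = "equal_width",
) -> tuple[PseudoLabelBatch, CentroidState]:
    """Assign subclass pseudo-labels to a batch and advance the centroids.

    For each class present in the batch, in class-index order: update its EMA
    centroid from the batch-class mean, compute each member's distance to the
    updated centroid, partition into ``ns[c]`` subclasses in the requested
    mode, and emit ``offsets[c] + subclass_index``.  Centroids of absent
    classes are untouched.
    """
    if mode not in ("equal_width", "equal_rank"):
        raise ValueError(f"unknown mode {mode!r}")
    if plan.n_classes != state.n_classes:
        raise ValueError("plan and centroid state cover different class counts")
    if batch.labels.size and batch.labels.max() >= plan.n_classes:
        raise ValueError("batch contains a class with no subclass-plan entry")
    partition = partition_equal_width if mode == "equal_width" else partition_equal_rank

    new_state = update_centroids(state, batch)
    pseudo = np.empty(batch.size, dtype=np.int64)
    for c in np.unique(batch.labels):
        members = batch.labels == c
        dist = compute_distances(batch.features[members], new_state.centers[c])
        pseudo[members] = plan.offsets[c] + partition(dist, plan.ns[c])
    return PseudoLabelBatch(pseudo_labels=pseudo, plan=plan), new_state
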