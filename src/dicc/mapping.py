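"""Label mapping: from the P-dimensional pseudo-label space back to C classes.

Two routes are provided.  ``init_mapping`` builds the learnable head — a
three-affine-layer fully connected network whose input width is the total
pseudo-label count P and whose output width is the true class count C.
``canonical_projection`` is its deterministic counterpart derived purely from
the subclass plan's offset bookkeeping: a pseudo->class lookup and the 0/1
matrix that sums subclass scores within each class.  The projection serves as
an exact oracle for what the learned mapper should be able to represent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Linear, ReLU, Sequential
from .core import SubclassPlan

__all__ = [
    "MappingNetworkSpec",
    "CanonicalProjection",
    "init_mapping",
    "canonical_projection",
    "map_scores",
]


@dataclass(frozen=True)
class MappingNetworkSpec:
    """Architecture of the mapping head.

    ``hidden_dims`` defaults to ``(2P, P + C)``, a monotone taper from the
    pseudo space down to the label space.
    """

    input_dim: int
    output_dim: int
    hidden_dims: tuple[int, int] | None = None
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self):
        if self.output_dim < 2:
            raise ValueError("output_dim must be >= 2")
        if self.input_dim < self.output_dim:
            raise ValueError(
                f"pseudo-label space ({self.input_dim}) must not be smaller than "
                f"the label space ({self.output_dim})"
            )
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        hidden = self.hidden_dims
        if hidden is None:
            hidden = (2 * self.input_dim, self.input_dim + self.output_dim)
        hidden = (int(hidden[0]), int(hidden[1]))
        if len(hidden) != 2 or any(h < 1 for h in hidden):
            raise ValueError("hidden_dims must be two positive integers")
        object.__setattr__(self, "hidden_dims", hidden)


def init_mapping(spec: MappingNetworkSpec) -> Sequential:
    """Build the three-affine-layer mapping network, seeded for reproducibility."""
    rng = np.random.default_rng(spec.seed)
    h1, h2 = spec.hidden_dims
    return Sequential(
        [
            Linear(spec.input_dim, h1, rng),
            ReLU(),
            Linear(h1, h2, rng),
            ReLU(),
            Linear(h2, spec.output_dim, rng, init="head"),
        ]
    )


@dataclass(frozen=True)
class CanonicalProjection:
    """Exact pseudo->class projection induced by a subclass plan."""

    pseudo_to_class: np.ndarray
    matrix: np.ndarray
    plan: SubclassPlan

    def lookup(self, pseudo_label: int) -> int:
        """The unique class whose pseudo-label range contains ``pseudo_label``."""
        if not (0 <= pseudo_label < self.plan.total):
            raise ValueError(
                f"pseudo-label {pseudo_label} outside [0, {self.plan.total})"
            )
        return int(self.pseudo_to_class[pseudo_label])

    def __call__(self, subclass_scores: np.ndarray) -> np.ndarray:
        """Sum subclass scores within each class: [B x P] -> [B x C]."""
        scores = np.asarray(subclass_scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[1] != self.plan.total:
            raise ValueError(f"scores must be [B x {self.plan.total}]")
        return scores @ self.matrix

    @property
    def input_dim(self) -> int:
        return self.plan.total

    forward = __call__


def canonical_projection(plan: SubclassPlan) -> CanonicalProjection:
    """Build the lookup vector and the P x C 0/1 summation matrix for a plan."""
    lookup = np.repeat(np.arange(plan.n_classes, dtype=np.int64), plan.ns)
    matrix = np.zeros((plan.total, plan.n_classes), dtype=np.float64)
    matrix[np.arange(plan.total), lookup] = 1.0
    return CanonicalProjection(pseudo_to_class=lookup, matrix=matrix, plan=plan)


def map_scores(mapping, subclass_scores: np.ndarray) -> np.ndarray:
    """Apply a mapping (learned network or canonical projection) row-wise."""
    scores = np.asarray(subclass_scores, dtype=np.float64)
    if scores.ndim != 2:
        raise ValueError("subclass_scores must be a [B x P] matrix")
    expected = mapping.input_dim
    if scores.shape[1] != expected:
        raise ValueError(
            f"score width {scores.shape[1]} does not match mapping input {expected}"
        )
    return mapping.forward(scores)
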