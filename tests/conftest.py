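"""Shared fixtures: reference subclass plans and random batch generation."""

import numpy as np
import pytest

from dicc import SubclassPlan

# Hand-tuned per-class subclass-count vectors for seven-class expression
# datasets at various imbalance factors, as they would appear in a config
# file.  Used to exercise plan bookkeeping on realistic shapes.
SEVEN_CLASS_REFERENCE_PLANS = [
    [8, 1, 20, 100, 40, 4, 80],
    [4, 1, 6, 10, 8, 2, 8],
    [6, 1, 2, 60, 100, 30, 20],
    [2, 1, 2, 8, 10, 6, 4],
    [20, 6, 1, 100, 60, 2, 30],
    [2, 1, 1, 10, 8, 1, 4],
]


@pytest.fixture(params=SEVEN_CLASS_REFERENCE_PLANS, ids=lambda ns: "-".join(map(str, ns)))
def reference_plan(request) -> SubclassPlan:
    return SubclassPlan.from_ns(request.param)


def random_batch(rng: np.random.Generator, max_b=64, max_c=7, max_m=16, min_per_class=1):
    """A random (features, labels, n_classes) triple for oracle comparisons.

    ``min_per_class`` matters for centroid-sensitive oracles: a class whose
    first centroid update comes from exactly two samples puts both of them
    mathematically equidistant from their mean, so their subclass membership
    is undefined up to floating-point noise.  Three or more members per class
    keep distances off such knife edges.
    """
    C = int(rng.integers(2, max_c + 1))
    M = int(rng.integers(2, max_m + 1))
    B = int(rng.integers(max(C * min_per_class, C), max_b + 1))
    features = rng.normal(size=(B, M)) * rng.uniform(0.5, 3.0)
    labels = np.concatenate(
        [np.repeat(np.arange(C), min_per_class), rng.integers(0, C, size=B - C * min_per_class)]
    )  # every class present at least min_per_class times
    rng.shuffle(labels)
    return features, labels, C
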