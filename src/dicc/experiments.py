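"""Desk-scale experiments: the minority-class recovery study.

Trains the two-phase framework twice on the same imbalanced Gaussian-mixture
data — once with subclass counts derived from the tail-class unit rule, once
with one subclass per class (which reduces phase 1 to ordinary cross-entropy)
— and compares tail-class recall on a balanced held-out test set.  This is
the package's operational check that splitting head classes into subclass
pseudo-labels helps minority-class recognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import SubclassPlan, derive_subclass_plan
from .evaluation import evaluate
from .synthetic import SyntheticConfig, generate_gaussian_longtail
from .training import TrainConfig, predict, train_two_phase

__all__ = ["RecoveryConditions", "RecoveryResult", "run_recovery_experiment"]


@dataclass(frozen=True)
class RecoveryConditions:
    """Study conditions for the recovery experiment.

    Four classes with training counts 400/200/100/20 (imbalance factor 20);
    the two head classes are bimodal in feature space, the premise the
    clustering step exploits.  The test set is balanced (100 per class) and
    drawn from the same mixture.  The derived subclass plan under the
    tail-unit rule is [20, 10, 5, 1], i.e. P = 36.
    """

    train_counts: tuple[int, ...] = (400, 200, 100, 20)
    val_per_class: int = 50
    test_per_class: int = 100
    subclusters: tuple[int, ...] = (2, 2, 1, 1)
    feature_dim: int = 8
    cluster_spread: float = 1.0
    between_cluster_distance: float = 2.5
    epochs: int = 30
    batch_size: int = 32
    lr: float = 0.05
    backbone_hidden: tuple[int, ...] = (32, 16)
    mode: str = "equal_width"
    rule: str = "none"


@dataclass
class RecoveryResult:
    seeds: list[int]
    tail_recall_dicc: list[float]
    tail_recall_baseline: list[float]
    top1_dicc: list[float]
    top1_baseline: list[float]
    n_train: int
    n_test: int

    @property
    def mean_tail_recall_dicc(self) -> float:
        return float(np.mean(self.tail_recall_dicc))

    @property
    def mean_tail_recall_baseline(self) -> float:
        return float(np.mean(self.tail_recall_baseline))

    @property
    def tail_recall_delta(self) -> float:
        return self.mean_tail_recall_dicc - self.mean_tail_recall_baseline

    @property
    def mean_top1_dicc(self) -> float:
        return float(np.mean(self.top1_dicc))

    @property
    def mean_top1_baseline(self) -> float:
        return float(np.mean(self.top1_baseline))


def _make_split(cond: RecoveryConditions, seed: int):
    """One mixture split into imbalanced train / balanced val / balanced test.

    The validation split drives best-epoch model selection (true-label top-1
    only); the test split is untouched by any selection.
    """
    C = len(cond.train_counts)
    totals = tuple(
        t + cond.val_per_class + cond.test_per_class for t in cond.train_counts
    )
    sample = generate_gaussian_longtail(
        SyntheticConfig(
            n_classes=C,
            counts=totals,
            subclusters_per_class=cond.subclusters,
            feature_dim=cond.feature_dim,
            cluster_spread=cond.cluster_spread,
            between_cluster_distance=cond.between_cluster_distance,
            seed=seed,
        )
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    train_idx, val_idx, test_idx = [], [], []
    for c in range(C):
        members = np.flatnonzero(sample.labels == c)
        members = rng.permutation(members)  # mix subclusters before splitting
        n_tr, n_val = cond.train_counts[c], cond.val_per_class
        train_idx.append(members[:n_tr])
        val_idx.append(members[n_tr : n_tr + n_val])
        test_idx.append(members[n_tr + n_val :])
    splits = []
    for idx in (train_idx, val_idx, test_idx):
        keep = np.concatenate(idx)
        splits.append((sample.features[keep], sample.labels[keep]))
    return tuple(splits)


def run_recovery_experiment(
    seeds: list[int] | None = None,
    conditions: RecoveryConditions | None = None,
) -> RecoveryResult:
    """Run the paired DICC vs. one-subclass-baseline comparison over seeds."""
    cond = conditions or RecoveryConditions()
    if seeds is None:
        seeds = [1, 2, 3, 4, 5]
    C = len(cond.train_counts)
    tail = C - 1

    base_cfg = TrainConfig(
        mode=cond.mode,
        rule=cond.rule,
        lr=cond.lr,
        epochs=cond.epochs,
        batch_size=cond.batch_size,
        backbone="mlp",
        backbone_hidden=cond.backbone_hidden,
    )

    result = RecoveryResult(
        seeds=list(seeds),
        tail_recall_dicc=[],
        tail_recall_baseline=[],
        top1_dicc=[],
        top1_baseline=[],
        n_train=int(sum(cond.train_counts)),
        n_test=int(cond.test_per_class * C),
    )
    for seed in seeds:
        train, val, test = _make_split(cond, seed)
        dicc_plan = derive_subclass_plan(cond.train_counts)
        flat_plan = SubclassPlan.from_ns([1] * C)
        for plan, rec, acc in (
            (dicc_plan, result.tail_recall_dicc, result.top1_dicc),
            (flat_plan, result.tail_recall_baseline, result.top1_baseline),
        ):
            cfg = replace(base_cfg, plan=plan, seed=seed)
            model = train_two_phase(train, val, cfg)
            preds, scores = predict(model, test[0])
            report = evaluate(preds, scores, test[1], n_classes=C)
            rec.append(100.0 * float(report.recall[tail]))
            acc.append(report.top1)
    return result
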