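"""Two-phase alternating training with subclass pseudo-labels.

Phase 1 trains the backbone and the P-way classifier on pseudo-labels
produced by the dynamic intra-class clustering step (Loss1, cross-entropy in
the pseudo space).  Phase 2 trains the mapping head on true labels from the
classifier's detached outputs (Loss2, cross-entropy in the class space).  The
phases alternate per batch by default; the clustering module is active only
during training and inference runs backbone -> classifier -> mapper.

Class rebalancing follows the effective-number-of-samples rule
``E_c = (1 - b**N_c) / (1 - b)``: ``resample`` draws training samples with
probability proportional to ``1 / E_c`` of their class; ``reweight`` scales
each class's loss by ``1 / E_c`` (normalised to sum to C), with every pseudo
class inheriting its parent class's weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Identity,
    Linear,
    ReLU,
    SGD,
    Sequential,
    make_mlp,
    param_checksum,
    softmax,
    softmax_cross_entropy,
)
from .core import (
    CentroidState,
    LabeledBatch,
    PseudoLabelBatch,
    SubclassPlan,
    assign_pseudo_labels,
    derive_subclass_plan,
)
from .mapping import MappingNetworkSpec, init_mapping

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "Rebalancing",
    "TrainingDiverged",
    "effective_number",
    "build_rebalancing",
    "loss_backbone",
    "loss_mapper",
    "train_two_phase",
    "train_plain",
    "predict",
    "save_model",
    "load_model",
]

RULES = ("none", "resample", "reweight")
MODES = ("equal_width", "equal_rank")
ALTERNATIONS = ("per_batch", "per_epoch")
BACKBONES = ("mlp", "identity")


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Everything needed to reproduce a training run.

    Optimizer defaults (SGD, momentum 0.9, lr 1e-4, 200 epochs, batch 32) are
    the full-scale settings; desk-scale experiments override ``lr`` and
    ``epochs``.  ``plan=None`` derives subclass counts from the training class
    sizes with the tail class as the unit.
    """

    plan: SubclassPlan | None = None
    alpha: float = 0.99
    mode: str = "equal_width"
    rule: str = "none"
    effective_number_beta: float = 0.999
    momentum: float = 0.9
    lr: float = 1e-4
    epochs: int = 200
    batch_size: int = 32
    alternation: str = "per_batch"
    select_best: bool = True
    seed: int = 0
    backbone: str = "mlp"
    backbone_hidden: tuple[int, ...] = (64, 32)
    mapper_hidden: tuple[int, int] | None = None
    mapper_input: str = "logits"
    subclass_cap: int | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.alternation not in ALTERNATIONS:
            raise ValueError(f"alternation must be one of {ALTERNATIONS}")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.mapper_input not in ("logits", "softmax"):
            raise ValueError("mapper_input must be 'logits' or 'softmax'")
        if not (0.0 < self.effective_number_beta < 1.0):
            raise ValueError("effective_number_beta must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class Rebalancing:
    """Sampling and loss weights produced by a rebalancing rule."""

    rule: str
    class_sampling_weight: np.ndarray | None
    class_loss_weight: np.ndarray

    def sample_probabilities(self, labels: np.ndarray) -> np.ndarray | None:
        """Per-sample draw probabilities (None means uniform shuffling)."""
        if self.class_sampling_weight is None:
            return None
        w = self.class_sampling_weight[labels]
        return w / w.sum()


def effective_number(class_counts: Sequence[int], b: float) -> np.ndarray:
    """Effective number of samples ``E_c = (1 - b**N_c) / (1 - b)``."""
    if not (0.0 < b < 1.0):
        raise ValueError(f"effective-number beta must lie in (0, 1), got {b}")
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.min() < 1:
        raise ValueError("class counts must be >= 1")
    return (1.0 - b**counts) / (1.0 - b)


def build_rebalancing(
    rule: str, class_counts: Sequence[int], effective_number_beta: float = 0.999
) -> Rebalancing:
    """Turn a rule name into concrete sampling / loss weights.

    ``none``: uniform sampling, unit loss weights.  ``resample``: sampling
    weight per class proportional to ``1 / E_c``, unit loss weights.
    ``reweight``: loss weight per class proportional to ``1 / E_c``,
    normalised to sum to C, uniform sampling.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    counts = np.asarray(class_counts, dtype=np.int64)
    C = counts.size
    if rule == "none":
        return Rebalancing(rule, None, np.ones(C))
    inv_e = 1.0 / effective_number(counts, effective_number_beta)
    if rule == "resample":
        return Rebalancing(rule, inv_e, np.ones(C))
    weights = inv_e / inv_e.sum() * C
    return Rebalancing(rule, None, weights)


def loss_backbone(
    subclass_logits: np.ndarray,
    pseudo_labels: PseudoLabelBatch | np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    """Loss1: cross-entropy of the P-way logits against the pseudo-labels."""
    labels = (
        pseudo_labels.pseudo_labels
        if isinstance(pseudo_labels, PseudoLabelBatch)
        else np.asarray(pseudo_labels, dtype=np.int64)
    )
    loss, _ = softmax_cross_entropy(subclass_logits, labels, class_weights)
    return loss


def loss_mapper(
    class_scores: np.ndarray,
    true_labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    """Loss2: cross-entropy of the mapped C-way scores against true labels."""
    loss, _ = softmax_cross_entropy(
        class_scores, np.asarray(true_labels, dtype=np.int64), class_weights
    )
    return loss


@dataclass
class TrainedModel:
    """Trained backbone, P-way classifier and mapping head plus bookkeeping."""

    backbone: Sequential
    classifier: Linear
    mapper: Sequential
    plan: SubclassPlan
    centroids: CentroidState
    config: TrainConfig
    history: dict[str, list]
    n_classes: int
    input_dim: int


def _build_backbone(
    config: TrainConfig, input_dim: int, rng: np.random.Generator
) -> tuple[Sequential, int]:
    if config.backbone == "identity":
        return Sequential([Identity()]), input_dim
    dims = [input_dim, *config.backbone_hidden]
    layers: list = []
    for i in range(len(dims) - 1):
        layers.append(Linear(dims[i], dims[i + 1], rng))
        layers.append(ReLU())
    return Sequential(layers), dims[-1]


def _epoch_batches(
    rng: np.random.Generator,
    n: int,
    batch_size: int,
    sample_probs: np.ndarray | None,
) -> list[np.ndarray]:
    if sample_probs is None:
        order = rng.permutation(n)
    else:
        order = rng.choice(n, size=n, replace=True, p=sample_probs)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    x, y = data
    x = np.asarray(x, dtype=np.float64)
    if x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    return x, np.asarray(y, dtype=np.int64)


def _check_finite(value: float, what: str, epoch: int, batch: int) -> None:
    if not np.isfinite(value):
        raise TrainingDiverged(
            f"{what} became non-finite at epoch {epoch}, batch {batch}"
        )


def train_two_phase(train_data, val_data, config: TrainConfig) -> TrainedModel:
    """Run the full alternating training loop.

    ``train_data`` and ``val_data`` are ``(X, y)`` pairs (images are flattened
    to vectors).  Per alternation unit: phase 1 forwards backbone+classifier,
    assigns pseudo-labels (updating the persistent centroid state), and steps
    SGD on Loss1 touching only backbone/classifier parameters; phase 2
    forwards the mapper on the detached classifier outputs and steps SGD on
    Loss2 touching only mapper parameters.  Fully reproducible from
    ``config.seed``.

    When ``val_data`` is given and ``config.select_best`` is set, the returned
    model carries the parameters of the epoch with the highest validation
    top-1 (true labels only — pseudo-labels are never computed at validation
    time); the per-epoch history always reflects the raw end-of-epoch state.
    """
    x_train, y_train = _as_xy(train_data)
    n, input_dim = x_train.shape
    n_classes = int(y_train.max()) + 1
    class_counts = np.bincount(y_train, minlength=n_classes)
    if class_counts.min() < 1:
        raise ValueError("every class in [0, C) must appear in the training data")

    plan = config.plan
    if plan is None:
        plan = derive_subclass_plan(class_counts, cap=config.subclass_cap)
    if plan.n_classes != n_classes:
        raise ValueError(
            f"plan covers {plan.n_classes} classes but data has {n_classes}"
        )

    children = np.random.SeedSequence(config.seed).spawn(3)
    rng_model = np.random.default_rng(children[0])
    rng_mapper = np.random.default_rng(children[1])
    rng_order = np.random.default_rng(children[2])

    backbone, feature_dim = _build_backbone(config, input_dim, rng_model)
    classifier = Linear(feature_dim, plan.total, rng_model, init="head")
    mapper_seed = int(rng_mapper.integers(0, 2**31 - 1))
    mapper = init_mapping(
        MappingNetworkSpec(
            input_dim=plan.total,
            output_dim=n_classes,
            hidden_dims=config.mapper_hidden,
            seed=mapper_seed,
        )
    )

    rebalance = build_rebalancing(
        config.rule, class_counts, config.effective_number_beta
    )
    loss_w_class = rebalance.class_loss_weight if config.rule == "reweight" else None
    loss_w_pseudo = (
        np.repeat(loss_w_class, plan.ns) if loss_w_class is not None else None
    )
    sample_probs = rebalance.sample_probabilities(y_train)

    opt1 = SGD(backbone.params() + classifier.params(), config.lr, config.momentum)
    opt2 = SGD(mapper.params(), config.lr, config.momentum)

    state = CentroidState.initial(n_classes, feature_dim, config.alpha)
    history: dict[str, list] = {
        "epoch": [],
        "loss1": [],
        "loss2": [],
        "val_top1": [],
        "checksum_backbone": [],
        "checksum_mapper": [],
    }
    model = TrainedModel(
        backbone=backbone,
        classifier=classifier,
        mapper=mapper,
        plan=plan,
        centroids=state,
        config=config,
        history=history,
        n_classes=n_classes,
        input_dim=input_dim,
    )

    t = 0
    best_snapshot: tuple[float, int, list[np.ndarray]] | None = None
    for epoch in range(1, config.epochs + 1):
        batches = _epoch_batches(rng_order, n, config.batch_size, sample_probs)
        loss1_sum, loss2_sum = 0.0, 0.0
        phase2_inputs: list[tuple[np.ndarray, np.ndarray]] = []

        for b_idx, idx in enumerate(batches, start=1):
            t += 1
            xb, yb = x_train[idx], y_train[idx]
            feats = backbone.forward(xb)
            logits = classifier.forward(feats)
            if not (np.all(np.isfinite(feats)) and np.all(np.isfinite(logits))):
                raise TrainingDiverged(
                    f"non-finite activations at epoch {epoch}, batch {b_idx}"
                )
            pseudo, state = assign_pseudo_labels(
                LabeledBatch(feats, yb, batch_index=t), state, plan, config.mode
            )
            loss1, grad1 = softmax_cross_entropy(
                logits, pseudo.pseudo_labels, loss_w_pseudo
            )
            _check_finite(loss1, "Loss1", epoch, b_idx)
            opt1.zero_grad()
            backbone.backward(classifier.backward(grad1))
            opt1.step()
            loss1_sum += loss1 * len(idx)

            if config.alternation == "per_batch":
                loss2_sum += _mapper_step(
                    mapper, opt2, logits, yb, loss_w_class, config, epoch, b_idx
                ) * len(idx)
            else:
                phase2_inputs.append((idx, None))

        if config.alternation == "per_epoch":
            # second pass: recompute detached classifier outputs with the
            # post-phase-1 weights, then step the mapper on each batch
            for b_idx, (idx, _) in enumerate(phase2_inputs, start=1):
                xb, yb = x_train[idx], y_train[idx]
                logits = classifier.forward(backbone.forward(xb))
                loss2_sum += _mapper_step(
                    mapper, opt2, logits, yb, loss_w_class, config, epoch, b_idx
                ) * len(idx)

        model.centroids = state
        history["epoch"].append(epoch)
        history["loss1"].append(loss1_sum / n)
        history["loss2"].append(loss2_sum / n)
        if val_data is not None:
            xv, yv = _as_xy(val_data)
            preds, _ = predict(model, xv)
            val_top1 = 100.0 * float((preds == yv).mean())
            history["val_top1"].append(val_top1)
            if config.select_best and (
                best_snapshot is None or val_top1 > best_snapshot[0]
            ):
                all_params = (
                    backbone.params() + classifier.params() + mapper.params()
                )
                best_snapshot = (val_top1, epoch, [p.data.copy() for p in all_params])
        else:
            history["val_top1"].append(float("nan"))
        history["checksum_backbone"].append(
            param_checksum(backbone.params() + classifier.params())
        )
        history["checksum_mapper"].append(param_checksum(mapper.params()))

    if best_snapshot is not None:
        _, best_epoch, saved = best_snapshot
        all_params = backbone.params() + classifier.params() + mapper.params()
        for p, data in zip(all_params, saved):
            p.data = data
        history["best_epoch"] = best_epoch

    return model


def _mapper_step(
    mapper: Sequential,
    opt2: SGD,
    logits: np.ndarray,
    yb: np.ndarray,
    loss_w_class: np.ndarray | None,
    config: TrainConfig,
    epoch: int,
    b_idx: int,
) -> float:
    mapper_in = softmax(logits) if config.mapper_input == "softmax" else logits
    scores = mapper.forward(mapper_in)
    loss2, grad2 = softmax_cross_entropy(scores, yb, loss_w_class)
    _check_finite(loss2, "Loss2", epoch, b_idx)
    opt2.zero_grad()
    mapper.backward(grad2)
    opt2.step()
    return loss2


@dataclass
class PlainModel:
    """Plain cross-entropy baseline: backbone + C-way classifier, no mapper."""

    backbone: Sequential
    classifier: Linear
    config: TrainConfig
    history: dict[str, list]
    n_classes: int
    input_dim: int


def train_plain(train_data, val_data, config: TrainConfig) -> PlainModel:
    """Ordinary cross-entropy training with the same data order and init.

    Mirrors ``train_two_phase`` exactly — same seed-derived RNG streams, same
    parameter initialisation, same batch schedule and optimizer — but trains a
    C-way classifier on true labels with no clustering and no mapper.  With a
    one-subclass-per-class plan, the two-phase loop's phase 1 reproduces this
    trajectory bit for bit.
    """
    x_train, y_train = _as_xy(train_data)
    n, input_dim = x_train.shape
    n_classes = int(y_train.max()) + 1
    class_counts = np.bincount(y_train, minlength=n_classes)

    children = np.random.SeedSequence(config.seed).spawn(3)
    rng_model = np.random.default_rng(children[0])
    rng_order = np.random.default_rng(children[2])

    backbone, feature_dim = _build_backbone(config, input_dim, rng_model)
    classifier = Linear(feature_dim, n_classes, rng_model, init="head")

    rebalance = build_rebalancing(
        config.rule, class_counts, config.effective_number_beta
    )
    loss_w = rebalance.class_loss_weight if config.rule == "reweight" else None
    sample_probs = rebalance.sample_probabilities(y_train)

    opt = SGD(backbone.params() + classifier.params(), config.lr, config.momentum)
    history: dict[str, list] = {
        "epoch": [],
        "loss": [],
        "val_top1": [],
        "checksum_backbone": [],
    }

    for epoch in range(1, config.epochs + 1):
        batches = _epoch_batches(rng_order, n, config.batch_size, sample_probs)
        loss_sum = 0.0
        for b_idx, idx in enumerate(batches, start=1):
            xb, yb = x_train[idx], y_train[idx]
            logits = classifier.forward(backbone.forward(xb))
            loss, grad = softmax_cross_entropy(logits, yb, loss_w)
            _check_finite(loss, "loss", epoch, b_idx)
            opt.zero_grad()
            backbone.backward(classifier.backward(grad))
            opt.step()
            loss_sum += loss * len(idx)
        history["epoch"].append(epoch)
        history["loss"].append(loss_sum / n)
        if val_data is not None:
            xv, yv = _as_xy(val_data)
            logits = classifier.forward(backbone.forward(xv))
            preds = logits.argmax(axis=1)
            history["val_top1"].append(100.0 * float((preds == yv).mean()))
        else:
            history["val_top1"].append(float("nan"))
        history["checksum_backbone"].append(
            param_checksum(backbone.params() + classifier.params())
        )
    return PlainModel(
        backbone=backbone,
        classifier=classifier,
        config=config,
        history=history,
        n_classes=n_classes,
        input_dim=input_dim,
    )


def predict(model: TrainedModel, inputs) -> tuple[np.ndarray, np.ndarray]:
    """Inference: backbone -> classifier -> mapper -> argmax.

    The clustering module plays no role here — no centroid access, no
    pseudo-labels.  Returns ``(predicted classes, class scores [N x C])``.
    """
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise ValueError(
            f"inputs must be [N x {model.input_dim}], got shape {x.shape}"
        )
    logits = model.classifier.forward(model.backbone.forward(x))
    mapper_in = softmax(logits) if model.config.mapper_input == "softmax" else logits
    class_scores = model.mapper.forward(mapper_in)
    return class_scores.argmax(axis=1), class_scores


def _serialize_net(net: Sequential) -> list[dict]:
    out = []
    for layer in net.layers:
        if isinstance(layer, Linear):
            out.append(
                {"type": "linear", "W": layer.W.data.tolist(), "b": layer.b.data.tolist()}
            )
        elif isinstance(layer, ReLU):
            out.append({"type": "relu"})
        elif isinstance(layer, Identity):
            out.append({"type": "identity"})
        else:  # pragma: no cover
            raise TypeError(f"cannot serialize layer {type(layer).__name__}")
    return out


def _deserialize_net(spec: list[dict]) -> Sequential:
    rng = np.random.default_rng(0)
    layers: list = []
    for entry in spec:
        if entry["type"] == "linear":
            W = np.asarray(entry["W"], dtype=np.float64)
            layer = Linear(W.shape[0], W.shape[1], rng)
            layer.W.data = W
            layer.b.data = np.asarray(entry["b"], dtype=np.float64)
            layers.append(layer)
        elif entry["type"] == "relu":
            layers.append(ReLU())
        elif entry["type"] == "identity":
            layers.append(Identity())
        else:
            raise ValueError(f"unknown layer type {entry['type']!r}")
    return Sequential(layers)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a JSON checkpoint bundling nets, plan, centroids and config."""
    cfg = model.config
    payload = {
        "backbone": _serialize_net(model.backbone),
        "classifier": _serialize_net(Sequential([model.classifier])),
        "mapper": _serialize_net(model.mapper),
        "plan": model.plan.to_dict(),
        "centroids": model.centroids.to_dict(),
        "n_classes": model.n_classes,
        "input_dim": model.input_dim,
        "config": {
            "alpha": cfg.alpha,
            "mode": cfg.mode,
            "rule": cfg.rule,
            "effective_number_beta": cfg.effective_number_beta,
            "momentum": cfg.momentum,
            "lr": cfg.lr,
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "alternation": cfg.alternation,
            "seed": cfg.seed,
            "backbone": cfg.backbone,
            "backbone_hidden": list(cfg.backbone_hidden),
            "mapper_input": cfg.mapper_input,
        },
        "history": model.history,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from a JSON checkpoint."""
    payload = json.loads(Path(path).read_text())
    cfg_d = dict(payload["config"])
    cfg_d["backbone_hidden"] = tuple(cfg_d.get("backbone_hidden", ()))
    config = TrainConfig(plan=SubclassPlan.from_dict(payload["plan"]), **cfg_d)
    classifier_net = _deserialize_net(payload["classifier"])
    return TrainedModel(
        backbone=_deserialize_net(payload["backbone"]),
        classifier=classifier_net.layers[0],
        mapper=_deserialize_net(payload["mapper"]),
        plan=SubclassPlan.from_dict(payload["plan"]),
        centroids=CentroidState.from_dict(payload["centroids"]),
        config=config,
        history=payload.get("history", {}),
        n_classes=int(payload["n_classes"]),
        input_dim=int(payload["input_dim"]),
    )
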