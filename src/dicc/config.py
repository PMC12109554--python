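"""YAML experiment configuration: data block + training block.

A config file looks like::

    data:
      kind: gaussian            # gaussian | blobs | pixel_csv
      n_classes: 4
      counts: [400, 200, 100, 20]
      subclusters_per_class: [2, 2, 1, 1]
      feature_dim: 8
      cluster_spread: 1.0
      between_cluster_distance: 2.5
      seed: 0
      test_per_class: 100       # synthetic kinds only
      # pixel_csv kind instead uses: path, image_side, split_column
    longtail:                   # optional: re-imbalance the training split
      beta: 20
      profile: exponential
      seed: 0
    train:
      ns: [2, 1, 1, 10, 8, 1, 4]   # optional manual subclass plan
      mode: equal_width
      rule: none
      alpha: 0.99
      lr: 0.05
      epochs: 30
      batch_size: 32
      seed: 0
      backbone: mlp
      backbone_hidden: [32, 16]
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .core import SubclassPlan
from .synthetic import (
    SyntheticConfig,
    apply_imbalance,
    generate_blob_images,
    generate_gaussian_longtail,
    load_pixel_csv,
)
from .training import TrainConfig

__all__ = ["load_config", "build_train_config", "load_dataset"]


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "data" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with a 'data' block")
    return cfg


def build_train_config(cfg: dict, class_counts=None) -> TrainConfig:
    t = dict(cfg.get("train", {}))
    ns = t.pop("ns", None)
    plan = SubclassPlan.from_ns(ns) if ns is not None else None
    if "backbone_hidden" in t:
        t["backbone_hidden"] = tuple(t["backbone_hidden"])
    if "mapper_hidden" in t:
        t["mapper_hidden"] = tuple(t["mapper_hidden"])
    return TrainConfig(plan=plan, **t)


def _synthetic_config(d: dict, counts) -> SyntheticConfig:
    return SyntheticConfig(
        n_classes=int(d["n_classes"]),
        counts=tuple(counts),
        subclusters_per_class=tuple(d["subclusters_per_class"]),
        feature_dim=int(d.get("feature_dim", 8)),
        cluster_spread=float(d.get("cluster_spread", 1.0)),
        between_cluster_distance=float(d.get("between_cluster_distance", 2.5)),
        seed=int(d.get("seed", 0)),
    )


def load_dataset(cfg: dict) -> dict:
    """Materialise the train/test arrays described by a config.

    Returns ``{"train": (X, y), "test": (X, y), "class_counts": array}``.
    For synthetic kinds a balanced test set of ``test_per_class`` samples per
    class is carved out of the same generated mixture; a ``longtail`` block
    further subsets the training split to the requested imbalance factor
    (the test split is never modified).
    """
    d = cfg["data"]
    kind = d.get("kind", "gaussian")
    test_per_class = int(d.get("test_per_class", 0))

    if kind in ("gaussian", "blobs"):
        counts = [int(c) + test_per_class for c in d["counts"]]
        syn = _synthetic_config(d, counts)
        if kind == "gaussian":
            sample = generate_gaussian_longtail(syn)
            x_all = sample.features
        else:
            sample = generate_blob_images(syn, image_size=int(d.get("image_size", 32)))
            x_all = sample.images.reshape(sample.images.shape[0], -1)
        y_all = sample.labels
        rng = np.random.default_rng(np.random.SeedSequence([syn.seed, 1]))
        tr_idx, te_idx = [], []
        for c in range(syn.n_classes):
            members = rng.permutation(np.flatnonzero(y_all == c))
            n_train = int(d["counts"][c])
            tr_idx.append(members[:n_train])
            te_idx.append(members[n_train : n_train + test_per_class])
        tr = np.concatenate(tr_idx)
        te = np.concatenate(te_idx) if test_per_class else np.empty(0, dtype=np.int64)
        x_train, y_train = x_all[tr], y_all[tr]
        x_test, y_test = x_all[te], y_all[te]
    elif kind == "pixel_csv":
        images, labels, splits = load_pixel_csv(
            d["path"], int(d["image_side"]), d.get("split_column")
        )
        x_all = images.reshape(images.shape[0], -1)
        if splits is not None:
            train_tag = d.get("train_split", "Training")
            is_train = np.array([s == train_tag for s in splits])
            x_train, y_train = x_all[is_train], labels[is_train]
            x_test, y_test = x_all[~is_train], labels[~is_train]
        else:
            x_train, y_train = x_all, labels
            x_test = np.empty((0, x_all.shape[1]))
            y_test = np.empty(0, dtype=np.int64)
    else:
        raise ValueError(f"unknown data kind {kind!r}")

    lt = cfg.get("longtail")
    if lt:
        n_classes = int(y_train.max()) + 1
        avail = np.bincount(y_train, minlength=n_classes)
        _, subsets = apply_imbalance(
            avail,
            float(lt["beta"]),
            lt.get("profile", "exponential"),
            int(lt.get("seed", 0)),
        )
        keep = np.concatenate(
            [np.flatnonzero(y_train == c)[subsets[c]] for c in sorted(subsets)]
        )
        x_train, y_train = x_train[keep], y_train[keep]

    return {
        "train": (x_train, y_train),
        "test": (x_test, y_test),
        "class_counts": np.bincount(y_train, minlength=int(y_train.max()) + 1),
    }
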