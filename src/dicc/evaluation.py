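"""Evaluation surface: top-1 accuracy, confusion matrix, per-class PR/F1.

Metrics are computed with scikit-learn; classes that are never predicted (or
absent from the truth) get precision/recall 0 with a logged warning rather
than NaN, so reports stay total on degenerate tail classes.  PR curves are
one-vs-rest over the mapped class scores, the inference-time surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_curve,
    precision_recall_fscore_support,
)

__all__ = ["EvalReport", "evaluate", "render_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    top1: float
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    pr_curves: list[dict[str, np.ndarray]]
    n_samples: int

    @property
    def n_classes(self) -> int:
        return self.confusion.shape[0]


def evaluate(
    predictions: np.ndarray,
    class_scores: np.ndarray,
    true_labels: np.ndarray,
    n_classes: int | None = None,
) -> EvalReport:
    """Compute the full report from predictions, scores and truth.

    ``confusion[r, c]`` counts samples of true class r predicted as c;
    ``top1`` is ``100 * trace / total``.  PR curves sweep a threshold over
    each class's score column one-vs-rest.
    """
    preds = np.asarray(predictions, dtype=np.int64)
    truth = np.asarray(true_labels, dtype=np.int64)
    scores = np.asarray(class_scores, dtype=np.float64)
    if preds.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if not (preds.shape == truth.shape and scores.shape[0] == preds.shape[0]):
        raise ValueError("predictions, scores and labels must agree in length")
    C = n_classes if n_classes is not None else scores.shape[1]
    if truth.min() < 0 or truth.max() >= C:
        raise ValueError(f"labels must lie in [0, {C})")

    labels = np.arange(C)
    conf = confusion_matrix(truth, preds, labels=labels)
    precision, recall, f1, support = precision_recall_fscore_support(
        truth, preds, labels=labels, zero_division=0
    )
    never_predicted = np.setdiff1d(labels, np.unique(preds))
    if never_predicted.size:
        logger.warning(
            "classes never predicted (precision reported as 0): %s",
            never_predicted.tolist(),
        )
    absent = np.setdiff1d(labels, np.unique(truth))
    if absent.size:
        logger.warning(
            "classes absent from the truth (recall reported as 0): %s",
            absent.tolist(),
        )

    pr_curves = []
    for c in range(C):
        prec_c, rec_c, _ = precision_recall_curve(
            (truth == c).astype(int), scores[:, c]
        )
        pr_curves.append({"precision": prec_c, "recall": rec_c})

    return EvalReport(
        top1=100.0 * float(np.trace(conf)) / preds.size,
        confusion=conf,
        precision=precision,
        recall=recall,
        f1=f1,
        pr_curves=pr_curves,
        n_samples=int(preds.size),
    )


def render_report(
    report: EvalReport,
    out_dir: str | Path,
    class_names: list[str] | None = None,
) -> list[Path]:
    """Write metrics.json, confusion CSV + heatmap, and one PR plot per class.

    File names are deterministic and the CSV/JSON content is byte-stable for
    a given report.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = report.n_classes
    names = class_names if class_names is not None else [str(c) for c in range(C)]
    if len(names) != C:
        raise ValueError("class_names length must match the class count")
    written: list[Path] = []

    metrics = {
        "top1": report.top1,
        "per_class": [
            {
                "class": names[c],
                "precision": float(report.precision[c]),
                "recall": float(report.recall[c]),
                "f1": float(report.f1[c]),
            }
            for c in range(C)
        ],
        "n_samples": report.n_samples,
    }
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    written.append(metrics_path)

    conf_path = out / "confusion.csv"
    header = ",".join(["true\\pred", *names])
    lines = [header] + [
        ",".join([names[r], *map(str, report.confusion[r].tolist())])
        for r in range(C)
    ]
    conf_path.write_text("\n".join(lines) + "\n")
    written.append(conf_path)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_xticks(range(C), names, rotation=45, ha="right")
    ax.set_yticks(range(C), names)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    heat_path = out / "confusion.png"
    fig.savefig(heat_path)
    plt.close(fig)
    written.append(heat_path)

    for c in range(C):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(report.pr_curves[c]["recall"], report.pr_curves[c]["precision"])
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"class {names[c]}")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        pr_path = out / f"pr_class_{c}.png"
        fig.savefig(pr_path)
        plt.close(fig)
        written.append(pr_path)

    return written
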