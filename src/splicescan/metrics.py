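"""Window-level and per-gene ranked-retrieval evaluation statistics.

Two families of metrics live here:

* window-level classification statistics (accuracy, per-class one-vs-rest
  specificity/recall/precision/F1, macro ROC-AUC and PR-AUC, confusion
  matrix) over held-out labeled windows;
* per-gene scan statistics computed from a :class:`PredictionTrack` against
  the annotated sites of one type — site-level accuracy (fraction of
  annotated sites recovered by argmax calls), top-k and top-percent
  ranked-retrieval accuracy, and the false-positive percentage
  (non-matching calls as a fraction of sequence length).

Ranked lists always order by the site-type probability descending with ties
broken by ascending position. Undefined quantities (k = 0, empty truth,
absent class) are reported as ``None`` rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, confusion_matrix, roc_auc_score

from .genome_scanner import CLASS_NAMES, PredictionTrack, rank_positions

DEFAULT_TOP_PERCENTS = (10, 25, 50, 65, 75, 85, 95)


@dataclass
class ClassStats:
    specificity: float
    recall: float
    precision: float
    f1: float


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, ClassStats]
    roc_auc: float | None
    pr_auc: float | None
    confusion: np.ndarray  # (3, 3) counts, rows = true class
    per_class_roc_auc: dict[str, float | None] = field(default_factory=dict)
    per_class_pr_auc: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "per_class": {
                name: vars(stats).copy() for name, stats in self.per_class.items()
            },
            "per_class_roc_auc": self.per_class_roc_auc,
            "per_class_pr_auc": self.per_class_pr_auc,
            "confusion": self.confusion.tolist(),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def classification_report(
    true_labels: Sequence[int] | np.ndarray, predicted_probabilities: np.ndarray
) -> MetricsReport:
    """Window-level statistics from integer labels and (n, 3) probabilities.

    Labels index ``(donor, acceptor, other)``. AUCs for classes absent from
    ``true_labels`` are ``None``; the macro AUC averages the defined classes
    and is ``None`` when no class has both positives and negatives.
    """
    y_true = np.asarray(true_labels, dtype=np.int64)
    probs = np.asarray(predicted_probabilities, dtype=np.float64)
    if len(y_true) != len(probs):
        raise ValueError("true_labels and predicted_probabilities differ in length")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    y_pred = probs.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
    accuracy = float((y_true == y_pred).mean())

    per_class: dict[str, ClassStats] = {}
    roc_aucs: dict[str, float | None] = {}
    pr_aucs: dict[str, float | None] = {}
    for c, name in enumerate(CLASS_NAMES):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        recall = _safe_div(tp, tp + fn)
        precision = _safe_div(tp, tp + fp)
        per_class[name] = ClassStats(
            specificity=_safe_div(tn, tn + fp),
            recall=recall,
            precision=precision,
            f1=_safe_div(2 * precision * recall, precision + recall),
        )
        is_c = (y_true == c).astype(int)
        if 0 < is_c.sum() < len(is_c):
            roc_aucs[name] = float(roc_auc_score(is_c, probs[:, c]))
            pr_aucs[name] = float(average_precision_score(is_c, probs[:, c]))
        else:
            roc_aucs[name] = None
            pr_aucs[name] = None

    defined_roc = [v for v in roc_aucs.values() if v is not None]
    defined_pr = [v for v in pr_aucs.values() if v is not None]
    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        roc_auc=float(np.mean(defined_roc)) if defined_roc else None,
        pr_auc=float(np.mean(defined_pr)) if defined_pr else None,
        confusion=cm,
        per_class_roc_auc=roc_aucs,
        per_class_pr_auc=pr_aucs,
    )


# ---------------------------------------------------------------------------
# Per-gene ranked-retrieval metrics
# ---------------------------------------------------------------------------

def top_k_accuracy(
    track: PredictionTrack,
    true_sites: Iterable[int],
    site_type: str,
    k: int | None = None,
) -> float | None:
    """Fraction of the top-k ranked positions that are annotated sites.

    ``k`` defaults to the number of true sites. Returns ``None`` when k = 0.
    """
    truth = set(int(p) for p in true_sites)
    if k is None:
        k = len(truth)
    if k == 0:
        return None
    top = rank_positions(track, site_type)[:k]
    return len(set(top.tolist()) & truth) / k


def top_percent_accuracy(
    track: PredictionTrack, true_sites: Iterable[int], site_type: str, percent: float
) -> float | None:
    """Fraction of true sites ranked within the top ``percent`` of positions.

    ``m = floor(percent/100 * length)`` positions are taken from the ranked
    list; returns ``None`` when m = 0 or there are no true sites.
    """
    if not 0 < percent <= 100:
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    truth = set(int(p) for p in true_sites)
    m = int(np.floor(percent / 100.0 * track.length))
    if m == 0 or not truth:
        return None
    top = set(rank_positions(track, site_type)[:m].tolist())
    return len(top & truth) / len(truth)


def false_positive_pct(
    track: PredictionTrack, true_sites: Iterable[int], site_type: str
) -> float:
    """Calls of ``site_type`` not matching annotated sites, over track length.

    Returns the raw fraction; multiply by 100 (or use :func:`as_percent`)
    for display. Invariant to call ordering and bounded by calls / length.
    """
    called = set(track.called_positions(site_type).tolist())
    truth = set(int(p) for p in true_sites)
    return (len(called) - len(called & truth)) / track.length


def site_level_accuracy(
    track: PredictionTrack, true_sites: Iterable[int], site_type: str
) -> float | None:
    """Fraction of annotated sites recovered by argmax calls (site recall)."""
    truth = set(int(p) for p in true_sites)
    if not truth:
        return None
    called = set(track.called_positions(site_type).tolist())
    return len(called & truth) / len(truth)


def as_percent(fraction: float | None, decimals: int = 2) -> float | None:
    """Display convention: fractions shown as percentages, rounded."""
    if fraction is None:
        return None
    return round(fraction * 100.0, decimals) if decimals else round(fraction * 100.0)


# ---------------------------------------------------------------------------
# Per-gene evaluation rows and table aggregation
# ---------------------------------------------------------------------------

@dataclass
class GeneSiteEvaluation:
    """One evaluation row: a gene's track scored for one site type.

    Display fields follow the table convention: accuracies and
    false-positive percentages as percentages with 2 decimals, top-k and
    top-percent accuracies as whole percentages.
    """

    gene_id: str
    length: int
    n_true_sites: int
    site_type: str
    accuracy_pct: float | None       # site-level recall, 2 decimals
    top_k_pct: float | None          # whole percent
    top_percent_pct: dict[int, float | None]
    n_predicted_sites: int
    false_positive_pct: float        # 2 decimals


def evaluate_gene_sites(
    track: PredictionTrack,
    true_sites: Sequence[int],
    site_type: str,
    percents: Iterable[int] = (50,),
) -> GeneSiteEvaluation:
    """Score one track against one site type's annotated positions."""
    return GeneSiteEvaluation(
        gene_id=track.gene_id,
        length=track.length,
        n_true_sites=len(set(true_sites)),
        site_type=site_type,
        accuracy_pct=as_percent(site_level_accuracy(track, true_sites, site_type)),
        top_k_pct=as_percent(top_k_accuracy(track, true_sites, site_type), decimals=0),
        top_percent_pct={
            int(p): as_percent(top_percent_accuracy(track, true_sites, site_type, p), decimals=0)
            for p in percents
        },
        n_predicted_sites=len(track.called_positions(site_type)),
        false_positive_pct=as_percent(false_positive_pct(track, true_sites, site_type)),
    )


def aggregate_rows(rows: Sequence[GeneSiteEvaluation]) -> dict[str, float | None]:
    """Column means over evaluation rows, as displayed (2-decimal rounding).

    Averages the display-rounded row values — the convention used when a
    table's per-row percentages are summarized — skipping undefined entries.
    """
    def mean_of(values: list[float | None]) -> float | None:
        defined = [v for v in values if v is not None]
        return round(float(np.mean(defined)), 2) if defined else None

    out = {
        "accuracy_pct": mean_of([r.accuracy_pct for r in rows]),
        "top_k_pct": mean_of([r.top_k_pct for r in rows]),
        "false_positive_pct": mean_of([r.false_positive_pct for r in rows]),
    }
    percents = sorted({p for r in rows for p in r.top_percent_pct})
    for p in percents:
        out[f"top_{p}_pct"] = mean_of([r.top_percent_pct.get(p) for r in rows])
    return out


# ---------------------------------------------------------------------------
# Plots (training-history and confusion-matrix figures)
# ---------------------------------------------------------------------------

def plot_history(history: Sequence, path: str) -> None:
    """Accuracy and loss vs. epoch for train/validation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def get(rec, name):
        return rec[name] if isinstance(rec, dict) else getattr(rec, name)

    epochs = [get(r, "epoch") for r in history]
    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_acc.plot(epochs, [get(r, "train_accuracy") for r in history], label="train")
    ax_loss.plot(epochs, [get(r, "train_loss") for r in history], label="train")
    if get(history[0], "val_accuracy") is not None:
        ax_acc.plot(epochs, [get(r, "val_accuracy") for r in history], label="validation")
        ax_loss.plot(epochs, [get(r, "val_loss") for r in history], label="validation")
    for ax, title in ((ax_acc, "accuracy"), (ax_loss, "loss")):
        ax.set_xlabel("epoch")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(report: MetricsReport, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion.astype(float)
    frac = cm / cm.sum(axis=1, keepdims=True).clip(min=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(frac, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(3), CLASS_NAMES)
    ax.set_yticks(range(3), CLASS_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{int(cm[i, j])}\n{frac[i, j]:.2%}", ha="center", va="center",
                    color="white" if frac[i, j] > 0.5 else "black", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
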