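"""Segmentation evaluation: confusion counts, overlap metrics, label matching.

Per-class metrics are one-vs-rest within the full image, so the specificity
of the background class is meaningful.  Cluster ids are arbitrary, so
predicted clusters are matched to ground-truth classes by an optimal
one-to-one assignment on the contingency table before scoring.  Rates with a
0/0 form are reported as NaN (not 0) and excluded from macro averages, to
avoid silently inflating them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "jaccard",
    "dice",
    "sensitivity",
    "specificity",
    "fdr",
    "lr_plus",
    "match_labels",
    "macro_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise 2x2 tally of a binary prediction against a binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts between two same-shape boolean masks."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def jaccard(counts: ConfusionCounts) -> float:
    """Jaccard overlap TP / (FP + TP + FN); 0 when both sets are empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        logger.info("jaccard of two empty sets reported as 0 by convention")
        return 0.0
    return counts.tp / denom


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN); 0 when both sets are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / denom if denom else 0.0


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN); NaN when the truth set is empty."""
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.warning("sensitivity undefined (empty truth set); reporting NaN")
        return math.nan
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP); NaN when the truth covers all."""
    denom = counts.tn + counts.fp
    if denom == 0:
        logger.warning("specificity undefined (truth covers image); reporting NaN")
        return math.nan
    return counts.tn / denom


def fdr(counts: ConfusionCounts) -> float:
    """False discovery rate FP / (FP + TP); NaN when nothing is predicted."""
    denom = counts.fp + counts.tp
    if denom == 0:
        logger.warning("FDR undefined (empty prediction); reporting NaN")
        return math.nan
    return counts.fp / denom


def lr_plus(counts: ConfusionCounts) -> float:
    """Positive likelihood ratio SN / (1 - SP); +inf at perfect specificity."""
    sn = sensitivity(counts)
    sp = specificity(counts)
    if math.isnan(sn) or math.isnan(sp):
        return math.nan
    if sp == 1.0:
        return math.nan if sn == 0.0 else math.inf
    return sn / (1.0 - sp)


def match_labels(
    pred: np.ndarray, truth: np.ndarray, pin_zero: bool = True
) -> dict[int, int | None]:
    """Optimal one-to-one mapping of predicted labels to truth labels.

    Maximizes the total pixel overlap over the contingency table (optimal
    assignment, not greedy, so the result is deterministic and independent
    of label order).  Labels left unmatched map to ``None``.

    Label 0 marks background/outside-mask in both images, so when it occurs
    in both it is pinned to 0 and kept out of the assignment (cluster ids
    are arbitrary; the background id is not).  Pass ``pin_zero=False`` to
    let 0 compete like any other label.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    plabels = np.unique(pred)
    tlabels = np.unique(truth)
    mapping: dict[int, int | None] = {int(p): None for p in plabels}
    pinned = pin_zero and 0 in plabels and 0 in tlabels
    if pinned:
        mapping[0] = 0
        plabels = plabels[plabels != 0]
        tlabels = tlabels[tlabels != 0]
    table = np.zeros((plabels.size, tlabels.size), dtype=np.int64)
    for a, p in enumerate(plabels):
        pm = pred == p
        for b, t in enumerate(tlabels):
            table[a, b] = np.count_nonzero(pm & (truth == t))
    rows, cols = linear_sum_assignment(table, maximize=True)
    for a, b in zip(rows, cols):
        mapping[int(plabels[a])] = int(tlabels[b])
    return mapping


@dataclass
class MetricReport:
    """Per-class and macro-averaged metrics plus the label matching used."""

    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]
    mapping: dict[int, int | None]

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "mapping": {str(k): v for k, v in self.mapping.items()},
        }


_METRICS = {
    "jaccard": jaccard,
    "dice": dice,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "fdr": fdr,
    "lr_plus": lr_plus,
}


def macro_report(
    pred: np.ndarray,
    truth: np.ndarray,
    ignore: tuple[int, ...] = (),
    match: bool = True,
) -> MetricReport:
    """Score a label image against ground truth, class by class.

    Predicted labels are first matched one-to-one to truth labels (unless
    ``match=False``, when identical label ids are assumed).  For every truth
    class not in ``ignore``, one-vs-rest confusion counts over the full
    image yield Jaccard, Dice, sensitivity, specificity, FDR and LR+; the
    macro row is the unweighted mean over classes, with NaN (undefined)
    entries excluded.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    mapping = (
        match_labels(pred, truth)
        if match
        else {int(p): int(p) for p in np.unique(pred)}
    )
    # relabel predictions into truth-label space; unmatched -> -1
    mapped = np.full(pred.shape, -1, dtype=np.int64)
    for p, t in mapping.items():
        if t is not None:
            mapped[pred == p] = t

    per_class: dict[int, dict[str, float]] = {}
    for t in np.unique(truth):
        t = int(t)
        if t in ignore:
            continue
        counts = confusion(mapped == t, truth == t)
        per_class[t] = {name: fn(counts) for name, fn in _METRICS.items()}

    macro: dict[str, float] = {}
    for name in _METRICS:
        vals = [v[name] for v in per_class.values() if not math.isnan(v[name])]
        dropped = len(per_class) - len(vals)
        if dropped:
            logger.info("macro %s excludes %d undefined class value(s)", name, dropped)
        macro[name] = float(np.mean(vals)) if vals else math.nan
    return MetricReport(per_class=per_class, macro=macro, mapping=mapping)
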