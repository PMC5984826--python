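"""Validation metrics: per-target precision/recall/MCC and PLI recall.

True positives are predicted residues that are listed functional sites,
false positives are predicted residues not listed, false negatives are
listed sites the method missed, and true negatives the remaining residues
of the chain; precision = TP/(TP+FP), recall = TP/(TP+FN) and the Matthews
correlation coefficient is

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the convention that a zero factor in the denominator yields 0.
Predicted interaction labels are compared with structure-derived labels on
a (site, interaction type) cell grid; PLI recall is the fraction of
matching cells.  Aggregates are macro averages over targets, excluding
no-hit targets, with PLI recall pooled over cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConfusionCounts", "TargetMetrics", "confusion", "mcc",
           "target_metrics", "pli_recall", "aggregate", "PLI_GRID_TYPES"]

#: Default interaction types of the PLI evaluation grid (vdW excluded).
PLI_GRID_TYPES = ("NCOV", "NCOO", "NELE", "NHBD", "NHBA", "NPI")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def L(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class TargetMetrics:
    precision: float
    recall: float
    mcc: float
    no_hit: bool = False
    precision_undefined: bool = False


def confusion(predicted_positions: set[int], true_positions: set[int], L: int) -> ConfusionCounts:
    """Confusion counts over the residues of a chain of length L."""
    pred = set(predicted_positions)
    truth = set(true_positions)
    for p in pred | truth:
        if not 1 <= p <= L:
            raise ValueError(f"position {p} outside 1..{L}")
    tp = len(pred & truth)
    fp = len(pred - truth)
    fn = len(truth - pred)
    return ConfusionCounts(tp, fp, fn, L - tp - fp - fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def target_metrics(counts: ConfusionCounts, no_hit: bool = False) -> TargetMetrics:
    """Precision, recall and MCC of one target."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    return TargetMetrics(precision, recall, mcc(counts), no_hit, undefined)


def pli_recall(predicted_labels: dict, true_labels: dict):
    """Cell-wise overlap of predicted and structure-derived PLI labels.

    Both arguments map (site position, interaction type) cells to binary
    labels; the evaluated grid is the set of true-label cells, with missing
    predictions counted as 0.  Returns ``(correct, total, recall)``.
    """
    cells = sorted(true_labels)
    total = len(cells)
    if total == 0:
        raise ValueError("empty PLI evaluation grid")
    correct = sum(
        1 for cell in cells
        if int(bool(predicted_labels.get(cell, 0))) == int(bool(true_labels[cell]))
    )
    return correct, total, correct / total


def make_pli_grid(sites: list[int], labels: dict[int, tuple[int, ...]],
                  components: tuple[str, ...], types: tuple[str, ...] = PLI_GRID_TYPES) -> dict:
    """Expand per-site 7-component label tuples into a (site, type) cell map."""
    grid = {}
    for pos in sites:
        flags = labels.get(pos)
        for t in types:
            k = components.index(t)
            grid[(pos, t)] = int(bool(flags[k])) if flags is not None else 0
    return grid


def aggregate(per_target: list[TargetMetrics],
              pli_counts: list[tuple[int, int]] | None = None) -> dict:
    """Macro averages over non-no-hit targets plus pooled PLI recall.

    ``pli_counts`` is an optional list of (correct, total) pairs; the pooled
    recall is sum(correct) / sum(total).
    """
    scored = [t for t in per_target if not t.no_hit]
    if not scored:
        raise ValueError("all targets are no-hit; nothing to aggregate")
    out = {
        "n_targets": len(scored),
        "n_no_hit": len(per_target) - len(scored),
        "precision": sum(t.precision for t in scored) / len(scored),
        "recall": sum(t.recall for t in scored) / len(scored),
        "mcc": sum(t.mcc for t in scored) / len(scored),
    }
    if pli_counts:
        correct = sum(c for c, _ in pli_counts)
        total = sum(t for _, t in pli_counts)
        out["pli_correct"] = correct
        out["pli_total"] = total
        out["pli_recall"] = correct / total if total else 0.0
    return out
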