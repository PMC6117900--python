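"""Scoring binning calls against a known sample composition.

A barcode whose genome truly contributed reads (abundance > 0) and was
called present is a true positive; called absent, a false negative.  A
barcode for a genome absent from the sample is a false positive when
called present and a true negative otherwise.  Besides sensitivity and
specificity the headline tuning criterion is the ratio of true positives
over total false predictions, TP / (FP + FN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .read_binning import BinningResult
from .synthetic_data import SampleTruth

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class RocCurve:
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, 1-specificity)
    auc: float


def confusion_counts(calls: BinningResult, truth: SampleTruth) -> ConfusionCounts:
    """Count TP/FP/FN/TN over the barcode set."""
    tp = fp = fn = tn = 0
    for barcode_id, call in calls.calls.items():
        if barcode_id not in truth.abundances:
            raise KeyError(f"barcode {barcode_id!r} has no truth entry")
        truly_present = truth.abundances[barcode_id] > 0
        if truly_present and call.present:
            tp += 1
        elif truly_present:
            fn += 1
        elif call.present:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def performance_metrics(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, TP/(FP+FN)); undefined ratios are None."""
    sensitivity = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    specificity = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    tp_over_false = c.TP / (c.FP + c.FN) if (c.FP + c.FN) else None
    return sensitivity, specificity, tp_over_false


def roc_curve(
    score_table: list[tuple[float, bool]],
) -> RocCurve:
    """ROC over per-barcode scores pooled across replicates.

    ``score_table`` holds (score, truly_present) rows; thresholds sweep the
    observed score values (call = score >= threshold) and the AUC is the
    trapezoid-rule area under sensitivity vs 1 - specificity.
    """
    n_pos = sum(1 for _, t in score_table if t)
    n_neg = len(score_table) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need both present and absent barcodes")
    thresholds = sorted({s for s, _ in score_table}, reverse=True)
    points = [(float("inf"), 0.0, 0.0)]
    for thr in thresholds:
        tp = sum(1 for s, t in score_table if t and s >= thr)
        fp = sum(1 for s, t in score_table if not t and s >= thr)
        points.append((thr, tp / n_pos, fp / n_neg))
    xs = [p[2] for p in points]
    ys = [p[1] for p in points]
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc)


def cutoff_grid_search(
    score_tables: list[list[tuple[float, float, bool]]],
    grid1: list[float],
    grid2: list[float],
) -> dict:
    """Mean TP/(FP+FN) over replicates for every cut-off pair.

    Each replicate table holds (score1, score2, truly_present) rows; the
    present call uses the AND rule.  Replicates where the ratio is
    undefined (FP + FN = 0, i.e. a perfect separation) are excluded from
    the mean for that cell, with the count of contributing replicates
    reported; for the reported arg-max a cell ranks first by how many of
    its replicates separated perfectly, then by the mean finite ratio, so
    a cleanly separating cut-off pair always attains the maximum.
    """
    if not grid1 or not grid2:
        raise ValueError("empty cut-off grid")
    if not score_tables:
        raise ValueError("need at least one replicate")
    matrix = np.full((len(grid1), len(grid2)), np.nan)
    counts = np.zeros((len(grid1), len(grid2)), dtype=int)
    perfect = np.zeros((len(grid1), len(grid2)), dtype=int)
    for i, c1 in enumerate(grid1):
        for j, c2 in enumerate(grid2):
            ratios = []
            for table in score_tables:
                tp = sum(1 for s1, s2, t in table if t and s1 >= c1 and s2 >= c2)
                fp = sum(1 for s1, s2, t in table if not t and s1 >= c1 and s2 >= c2)
                fn = sum(1 for s1, s2, t in table if t and not (s1 >= c1 and s2 >= c2))
                if fp + fn:
                    ratios.append(tp / (fp + fn))
                else:
                    perfect[i, j] += 1
            if ratios:
                matrix[i, j] = float(np.mean(ratios))
                counts[i, j] = len(ratios)

    def cell_rank(i: int, j: int):
        mean = matrix[i, j]
        return (perfect[i, j], mean if not np.isnan(mean) else -np.inf)

    best = max(
        ((i, j) for i in range(len(grid1)) for j in range(len(grid2))),
        key=lambda ij: cell_rank(*ij),
        default=None,
    )
    if best is None or (perfect[best] == 0 and np.isnan(matrix[best])):
        argmax = None
    else:
        argmax = (grid1[best[0]], grid2[best[1]])
    return {
        "grid1": list(grid1),
        "grid2": list(grid2),
        "matrix": matrix,
        "counts": counts,
        "argmax": argmax,
    }


def score_table_from_result(
    result: BinningResult, truth: SampleTruth
) -> list[tuple[float, float, bool]]:
    """(score1, score2, truly_present) rows for one binning run."""
    table = []
    for barcode_id in sorted(result.calls):
        call = result.calls[barcode_id]
        if barcode_id not in truth.abundances:
            raise KeyError(f"barcode {barcode_id!r} has no truth entry")
        table.append((call.score1, call.score2, truth.abundances[barcode_id] > 0))
    return table
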