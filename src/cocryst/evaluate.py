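"""Evaluation of virtual-screening predictions against experiment.

Screening scores (hydrogen-bond-propensity multicomponent scores, MEP
pairing dE values, machine-learning scores, ...) are compared with the
experimentally observed cocrystallization outcome per coformer.  Scores
whose natural direction is "lower means cocrystal" (such as dE) declare
``orientation="lower-is-positive"`` and are negated before thresholding,
so that internally a higher normalized score always means a predicted
cocrystal.

Reported metrics: confusion counts at a cutoff, sensitivity/specificity/
accuracy/balanced accuracy in percent, and the ROC curve with its area
(equal to the Mann–Whitney probability that a random positive outscores a
random negative, ties credited 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "LabeledScore",
    "ConfusionCounts",
    "MetricReport",
    "RocResult",
    "confusion_counts",
    "metrics",
    "roc_curve",
    "mann_whitney_auc",
    "compare_models",
    "round_half_away",
]

Orientation = Literal["higher-is-positive", "lower-is-positive"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (0.05 -> 0.1, -0.05 -> -0.1).

    Python's built-in round is banker's rounding; reported percentages
    use the away-from-zero convention instead.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class LabeledScore:
    """One coformer's screening score with its experimental outcome."""

    coformer_id: str
    outcome: bool  # True = cocrystal formed
    score: float
    orientation: Orientation = "higher-is-positive"

    @property
    def normalized_score(self) -> float:
        """Score with 'higher predicts cocrystal' direction enforced."""
        return self.score if self.orientation == "higher-is-positive" else -self.score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percent metrics; unrounded, render-time rounding is the caller's job."""

    sensitivity: float  # TPR, %
    specificity: float  # TNR, %
    accuracy: float  # %
    balanced_accuracy: float  # %

    def rounded(self, ndigits: int = 1) -> "MetricReport":
        return MetricReport(*(round_half_away(v, ndigits) for v in (
            self.sensitivity, self.specificity,
            self.accuracy, self.balanced_accuracy)))


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), threshold high -> low
    auc: float


def _check_single_orientation(data: Sequence[LabeledScore]) -> None:
    if not data:
        raise ValueError("empty score list")
    orientations = {d.orientation for d in data}
    if len(orientations) > 1:
        raise ValueError(f"mixed score orientations in one dataset: {orientations}")


def confusion_counts(data: Sequence[LabeledScore], threshold: float = 0.0) -> ConfusionCounts:
    """Counts at a cutoff: predicted positive iff normalized score > threshold."""
    _check_single_orientation(data)
    tp = fp = tn = fn = 0
    for d in data:
        predicted = d.normalized_score > threshold
        if d.outcome:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Percent sensitivity, specificity, accuracy and balanced accuracy.

    Balanced accuracy is the mean of the unrounded rates.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive outcomes: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative outcomes: specificity undefined")
    tpr = 100.0 * counts.tp / (counts.tp + counts.fn)
    tnr = 100.0 * counts.tn / (counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    return MetricReport(tpr, tnr, acc, (tpr + tnr) / 2.0)


def roc_curve(data: Sequence[LabeledScore]) -> RocResult:
    """ROC step curve and its trapezoidal area over all score thresholds."""
    _check_single_orientation(data)
    y = np.array([d.outcome for d in data], dtype=int)
    s = np.array([d.normalized_score for d in data], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs both outcome classes present")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return RocResult(points=tuple(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def mann_whitney_auc(data: Sequence[LabeledScore]) -> float:
    """AUC as the Mann–Whitney pair statistic, ties credited 1/2.

    Independent of the threshold-sweep route: every positive/negative
    score pair is inspected directly.
    """
    _check_single_orientation(data)
    pos = np.array([d.normalized_score for d in data if d.outcome])
    neg = np.array([d.normalized_score for d in data if not d.outcome])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both outcome classes present")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins) / (pos.size * neg.size)


def compare_models(
    datasets: Mapping[str, Sequence[LabeledScore]],
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, dict]:
    """One evaluation row per screening method.

    Methods may cover different coformer subsets, but a coformer present
    in several methods must carry the same outcome label everywhere.
    Each row reports its own denominator ``n``.
    """
    thresholds = thresholds or {}
    seen: dict[str, bool] = {}
    for method, data in datasets.items():
        for d in data:
            if d.coformer_id in seen and seen[d.coformer_id] != d.outcome:
                raise ValueError(
                    f"conflicting outcome labels for coformer {d.coformer_id!r}"
                )
            seen[d.coformer_id] = d.outcome

    rows: dict[str, dict] = {}
    for method, data in datasets.items():
        counts = confusion_counts(data, thresholds.get(method, 0.0))
        rep = metrics(counts)
        roc = roc_curve(data)
        rows[method] = {
            "n": len(data),
            "counts": counts,
            "metrics": rep,
            "auc": roc.auc,
            "roc_points": roc.points,
        }
    return rows
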