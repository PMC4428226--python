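"""Threshold classification of observed patterns as spurious vs real.

With the true distribution known (i.e. on simulated data), a per-pattern
statistic — the MLE ``theta_hat_i`` or the naive proportion ``y_i/N_read`` —
is thresholded at ``K``: pattern ``i`` is declared spurious when the
statistic is ``<= K``.  Counting against the truth (``theta_i = 0`` means
truly spurious) gives TP/FP/TN/FN and the rates TPR = TP/(TP+FN),
FPR = FP/(FP+TN), traced over a grid of thresholds.  Only patterns with
non-zero reads enter the classification.  This is a descriptive evaluation
device, not a hypothesis test: the threshold has no p-value interpretation
because patterns are not independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .error_model import PatternDistribution

__all__ = ["ClassificationOutcome", "classify_at_threshold", "tpr_fpr_curve"]


@dataclass(frozen=True)
class ClassificationOutcome:
    """Confusion counts and rates for one threshold K."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        """TP / (TP + FN); NaN when no truly spurious pattern exists."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else math.nan

    @property
    def fpr(self) -> float:
        """FP / (FP + TN); NaN when no truly real pattern exists."""
        neg = self.fp + self.tn
        return self.fp / neg if neg else math.nan


def classify_at_threshold(
    stat: Mapping[int, float],
    true_theta: PatternDistribution,
    K: float,
) -> ClassificationOutcome:
    """Classify each observed pattern as spurious (stat <= K) vs real.

    Parameters
    ----------
    stat
        Per-pattern statistic keyed by 1-based pattern index, defined on
        every pattern with non-zero reads (``theta_hat_i`` or ``y_i/N``).
    true_theta
        The known true distribution; ``theta_i = 0`` marks a truly spurious
        pattern.
    K
        Classification threshold in [0, 1]; ties (stat == K) are declared
        spurious.
    """
    if not 0 <= K <= 1:
        raise ValueError(f"threshold K must be in [0, 1], got {K}")
    tp = fp = tn = fn = 0
    for k, s in stat.items():
        truly_spurious = true_theta.prob(k) == 0
        called_spurious = s <= K
        if called_spurious and truly_spurious:
            tp += 1
        elif called_spurious:
            fp += 1
        elif truly_spurious:
            fn += 1
        else:
            tn += 1
    return ClassificationOutcome(K, tp, fp, tn, fn)


def tpr_fpr_curve(
    stat: Mapping[int, float],
    true_theta: PatternDistribution,
    K_grid=None,
) -> list[ClassificationOutcome]:
    """Confusion outcomes over a monotone grid of thresholds.

    By default the grid is 0, 1 and every distinct statistic value — the
    exact step positions of the curve.  TPR and FPR are non-decreasing in K.
    """
    if K_grid is None:
        K_grid = sorted({0.0, 1.0} | {float(v) for v in stat.values()})
    else:
        K_grid = [float(k) for k in K_grid]
        if not K_grid:
            raise ValueError("threshold grid must be non-empty")
        if any(b < a for a, b in zip(K_grid, K_grid[1:])):
            raise ValueError("threshold grid must be monotone increasing")
    return [classify_at_threshold(stat, true_theta, K) for K in K_grid]
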