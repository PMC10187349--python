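"""Outcome-evaluation statistics.

ROC/AUC (Mann-Whitney rank identity, midpoint tie convention),
Mann-Whitney U tests (exact enumeration for small tie-free inputs,
normal approximation with tie correction otherwise), Spearman
correlation of scores with lesion volumes (on a log10 pseudocount
scale, which leaves the ranks and hence rho unchanged), and Phoenix
biochemical-recurrence calling from post-treatment PSA series (first
rise of >= 2 ng/mL above the running nadir).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "BcrCall", "roc_auc", "mann_whitney", "spearman_volume", "call_bcr"]


@dataclass(frozen=True)
class RocResult:
    """ROC curve and area. ``fpr``/``tpr`` trace the curve from (0,0) to
    (1,1); ``auc`` is the probability a positive outranks a negative
    (ties counted one half)."""

    auc: float
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    positive_label: object


@dataclass(frozen=True)
class BcrCall:
    """Phoenix-rule call: outcome 'BCR' or 'NED', the month of the first
    qualifying rise (None for NED) and the running nadir in force at the
    call."""

    outcome: str
    time_months: float | None
    nadir: float


def roc_auc(scores: Sequence[float], labels: Sequence[object], positive_label=1) -> RocResult:
    """AUC via the Mann-Whitney rank identity plus the ROC polyline."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return RocResult(
        auc=float(auc),
        fpr=tuple(map(float, fpr)),
        tpr=tuple(map(float, tpr)),
        positive_label=positive_label,
    )


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, P).

    P is exact (full enumeration over rank assignments) when the pooled
    sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_volume(
    x: Sequence[float], volumes: Sequence[float], pseudocount: float = 0.1
) -> tuple[float, float]:
    """Spearman rho of x against log10(volume + pseudocount), with
    t-approximation P. The log transform is monotone, so rho equals the
    correlation on raw volumes; it is applied for consistency with the
    plotted scale."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if x.shape != v.shape:
        raise ValueError("x and volumes must have equal length")
    if (v < 0).any():
        raise ValueError("volumes must be non-negative")
    rho, p = stats.spearmanr(x, np.log10(v + pseudocount))
    return float(rho), float(p)


def call_bcr(times: Sequence[float], values: Sequence[float]) -> BcrCall:
    """Phoenix biochemical-recurrence call on a PSA series.

    The nadir is the running minimum of all values observed so far; BCR
    is called at the first time the PSA reaches nadir + 2.0 ng/mL
    (inclusive). Values after the first qualifying rise cannot change
    the call.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one post-treatment PSA value")
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    nadir = np.inf
    for t, v in zip(times, values):
        nadir = min(nadir, v)
        if v >= nadir + 2.0:
            return BcrCall(outcome="BCR", time_months=float(t), nadir=float(nadir))
    return BcrCall(outcome="NED", time_months=None, nadir=float(nadir))
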