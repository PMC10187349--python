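"""Derivation, scoring and locking of the prostate-cancer-specific
TGF-beta activation signature.

The signature is built from a six-condition epithelial/stromal
co-culture contrast: the TGF-beta-stimulated co-culture (no receptor
inhibitor) against the five remaining conditions, equally weighted.
Genes passing an FDR filter are ranked by log2 fold-change, scored per
sample with a rank-weighted running-sum enrichment statistic (ssGSEA,
weighting exponent tau), and the signature size N is chosen as the
smallest local maximum of the score's AUC against outcome, starting at
three genes. Once selected, the signature is locked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEResult
from .evaluate import roc_auc
from .synthdata import CONDITIONS

__all__ = [
    "SsgseaParams",
    "RankedCandidates",
    "GeneSignature",
    "EnrichmentScores",
    "coculture_contrast",
    "rank_candidates",
    "ssgsea",
    "select_signature",
]


@dataclass(frozen=True)
class SsgseaParams:
    """ssGSEA scoring parameters.

    tau is the exponent applied to the (average-tie) expression ranks of
    in-set genes in the weighted ECDF; 0.25 is the value this analysis
    uses throughout. With normalize_across_samples, raw scores are
    divided by the cohort-wide score range, so single-sample use should
    disable it (scores are then comparable only within one run).
    """

    tau: float = 0.25
    normalize_across_samples: bool = True
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class RankedCandidates:
    """FDR-filtered candidate genes ordered by descending log2FC
    (ties by gene ID)."""

    table: pd.DataFrame  # index gene; columns log2fc, p_adj
    fdr_threshold: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneSignature:
    """An ordered, locked gene signature.

    Immutable by construction (frozen dataclass, tuple genes); the
    provenance mapping records the contrast, thresholds and the full
    AUC-vs-N trace of the selection search.
    """

    genes: tuple[str, ...]
    n: int
    tau: float
    locked: bool = True
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n != len(self.genes):
            raise ValueError("n must equal the number of genes")
        if self.n < 3:
            raise ValueError("a signature has at least three genes")


@dataclass(frozen=True)
class EnrichmentScores:
    """Per-sample enrichment scores; ``normalized`` says whether the raw
    running-sum scores were rescaled by the cohort score range."""

    scores: pd.Series
    normalized: bool
    tau: float


def coculture_contrast(conditions: Sequence[str] = CONDITIONS) -> pd.Series:
    """Contrast weights: +1 on the TGF-beta-stimulated co-culture, -1/5
    on each of the five negative conditions."""
    missing = [c for c in CONDITIONS if c not in conditions]
    if missing:
        raise ValueError(f"design is missing condition(s): {missing}")
    weights = pd.Series(0.0, index=list(conditions))
    weights["cocult_tgfb"] = 1.0
    for cond in CONDITIONS:
        if cond != "cocult_tgfb":
            weights[cond] = -0.2
    return weights


def rank_candidates(de: DEResult, fdr_threshold: float = 0.1) -> RankedCandidates:
    """Keep genes with adjusted P below the FDR threshold, ordered by
    descending log2 fold-change (ties broken by gene ID)."""
    tab = de.table
    kept = tab.loc[tab["p_adj"] < fdr_threshold, ["log2fc", "p_adj"]].copy()
    kept = kept.iloc[np.lexsort((kept.index.to_numpy(), -kept["log2fc"].to_numpy()))]
    return RankedCandidates(table=kept, fdr_threshold=fdr_threshold)


def _ssgsea_sample(values: np.ndarray, gene_ids: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Running-sum enrichment score for one sample.

    Genes are ranked by expression (average ranks for ties; the largest
    value gets rank N) and walked in descending rank order (rank ties
    broken by gene ID). At each step the weighted in-set ECDF — weights
    r_g^tau — is compared with the unweighted out-of-set ECDF; the score
    is the sum of the differences over all steps.
    """
    n = values.size
    r = stats.rankdata(values)  # average ties, largest value -> rank n
    order = np.lexsort((gene_ids, -r))
    in_walk = in_set[order]
    w = np.where(in_walk, r[order] ** tau, 0.0)
    denom_in = w.sum()
    p_in = np.cumsum(w) / denom_in
    n_out = n - int(in_set.sum())
    p_out = np.cumsum(~in_walk) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    expr: pd.DataFrame,
    genes: Sequence[str],
    params: SsgseaParams = SsgseaParams(),
) -> EnrichmentScores:
    """Single-sample enrichment scores of a gene set across all samples."""
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        if not params.allow_missing:
            raise ValueError(
                f"signature genes absent from the expression matrix: {missing} "
                "(pass allow_missing to drop them)"
            )
        warnings.warn(f"dropping {len(missing)} signature gene(s) absent from matrix: {missing}")
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    if len(present) >= expr.shape[0]:
        raise ValueError("gene set must be a strict subset of the measured genes")

    gene_ids = expr.index.to_numpy(dtype=object)
    in_set = np.isin(gene_ids, present)
    values = expr.to_numpy(float)
    raw = np.array(
        [_ssgsea_sample(values[:, j], gene_ids, in_set, params.tau) for j in range(values.shape[1])]
    )
    normalized = False
    if params.normalize_across_samples:
        if raw.size < 2:
            warnings.warn("cohort normalization skipped: fewer than two samples")
        else:
            rng_ = raw.max() - raw.min()
            if rng_ > 0:
                raw = raw / rng_
                normalized = True
            else:
                warnings.warn("cohort normalization skipped: zero score range")
    else:
        warnings.warn(
            "scores are not cohort-normalized; they are scale-comparable only within this run"
        )
    return EnrichmentScores(
        scores=pd.Series(raw, index=expr.columns, name="enrichment_score"),
        normalized=normalized,
        tau=params.tau,
    )


def select_signature(
    candidates: RankedCandidates,
    expr: pd.DataFrame,
    labels: Sequence[object],
    n_start: int = 3,
    n_max: int | None = None,
    params: SsgseaParams = SsgseaParams(),
    positive_label: object = "BCR",
) -> GeneSignature:
    """Lock the signature size at the smallest local-max AUC.

    For N = n_start..n_max the top-N candidate genes are scored on the
    discovery cohort and the AUC of the scores against the outcome
    labels is computed; the returned signature uses the smallest N with
    AUC(N) >= AUC(N-1) (where defined) and AUC(N) >= AUC(N+1) (where
    defined). If the AUC still rises at n_max, n_max is returned with a
    warning. The result is locked; the full AUC trace is kept in the
    provenance.
    """
    if len(candidates) < n_start:
        raise ValueError(
            f"need at least n_start={n_start} candidates, have {len(candidates)}"
        )
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    if n_max is None:
        n_max = min(30, len(candidates))
    n_max = min(n_max, len(candidates))

    score_params = SsgseaParams(tau=params.tau, normalize_across_samples=False,
                                allow_missing=params.allow_missing)
    trace: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # raw-score mode warning per N
        for n in range(n_start, n_max + 1):
            scores = ssgsea(expr, candidates.genes[:n], score_params)
            trace[n] = roc_auc(scores.scores, labels, positive_label=positive_label).auc

    selected = None
    for n in range(n_start, n_max + 1):
        left_ok = (n == n_start) or (trace[n] >= trace[n - 1])
        right_ok = (n == n_max) or (trace[n] >= trace[n + 1])
        if left_ok and right_ok:
            if n == n_max and n > n_start and trace[n] > trace[n - 1]:
                warnings.warn(
                    f"AUC still increasing at n_max={n_max}; returning n_max"
                )
            selected = n
            break
    assert selected is not None  # a finite trace always has a local max

    return GeneSignature(
        genes=tuple(candidates.genes[:selected]),
        n=selected,
        tau=params.tau,
        locked=True,
        provenance={
            "fdr_threshold": candidates.fdr_threshold,
            "contrast": "cocult_tgfb vs five equally weighted negatives",
            "auc_trace": dict(trace),
            "n_start": n_start,
            "n_max": n_max,
            "discovery_auc": trace[selected],
        },
    )
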