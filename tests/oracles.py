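"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (double loops, explicit enumeration)
kept separate from the library paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def ssgsea_naive(values, gene_ids, gene_set, tau) -> float:
    """O(N * |G|) literal running-sum ssGSEA for one sample."""
    n = len(values)
    r = stats.rankdata(values)
    order = sorted(range(n), key=lambda i: (-r[i], gene_ids[i]))
    in_set = [gene_ids[i] in gene_set for i in order]
    denom = sum(r[order[j]] ** tau for j in range(n) if in_set[j])
    n_out = n - sum(in_set)
    es = 0.0
    for i in range(1, n + 1):
        p_in = sum(r[order[j]] ** tau for j in range(i) if in_set[j]) / denom
        p_out = sum(1 for j in range(i) if not in_set[j]) / n_out
        es += p_in - p_out
    return es


def bh_naive(p) -> list[float]:
    """BH adjusted P by the definitional minimum over candidate cutoffs."""
    m = len(p)
    out = []
    for pi in p:
        cands = [
            pj * m / sum(1 for pk in p if pk <= pj) for pj in p if pj >= pi
        ]
        out.append(min(1.0, min(cands)))
    return out


def auc_naive(scores, labels, positive) -> float:
    """Normalized concordant-pair count (ties worth one half)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


def mw_exact_naive(a, b) -> float:
    """Two-sided exact Mann-Whitney P by enumerating all assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = _u_stat(a, b)
    n_extreme = 0
    combos = list(itertools.combinations(range(len(pooled)), na))
    for idx in combos:
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = _u_stat(ga, gb)
        nb = len(gb)
        # two-sided: as or more extreme in either tail
        if min(u, na * nb - u) <= min(u_obs, na * len(b) - u_obs):
            n_extreme += 1
    return n_extreme / len(combos)


def _u_stat(a, b) -> float:
    return sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)


def mw_permutation_p(a, b, n_perm, seed) -> float:
    """Permutation estimate of the two-sided Mann-Whitney P."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na, nb = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    dev_obs = abs(u_obs - na * nb / 2)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        u = perm[:na].sum() - na * (na + 1) / 2
        if abs(u - na * nb / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / n_perm


def spearman_no_ties(x, y) -> float:
    """rho = 1 - 6 sum d^2 / (n (n^2 - 1)); valid without ties."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def allele_count_naive(pten_lost, pten_mut, tp53_lost, tp53_mut) -> int:
    """Literal per-gene min(2, lost + mutations) sum."""
    return min(2, pten_lost + pten_mut) + min(2, tp53_lost + tp53_mut)
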