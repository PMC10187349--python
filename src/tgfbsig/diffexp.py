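"""Gene-wise differential expression.

Two fitting routes are provided:

* ordinary least-squares linear contrasts with empirical-Bayes variance
  moderation (the classic moderated t: per-gene sample variances are
  shrunk toward a pooled inverse-chi-square prior whose degrees of
  freedom d0 and location s0^2 are estimated by moment matching on the
  log sample variances), for designs with one independent sample per
  unit, and
* a per-gene random-intercept linear mixed model (REML) for cohorts with
  repeated biopsies per patient, where the patient is the blocking
  factor and the outcome is a patient-level fixed effect.

Both routes report Benjamini-Hochberg adjusted P values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEResult",
    "LMMResult",
    "cell_means_design",
    "fit_linear_contrast",
    "moderate",
    "benjamini_hochberg",
    "fit_mixed_model",
    "filter_de",
]


@dataclass
class DEResult:
    """Per-gene differential expression table plus moderation prior.

    ``table`` is indexed by gene with columns log2fc, t, p, p_adj, df and
    s2 (residual sample variance). ``d0``/``s0_sq`` are the prior degrees
    of freedom and prior variance (None before moderation; d0 may be
    +inf when the sample variances carry no excess spread).
    ``contrast_variance`` is c' (X'X)^-1 c, the unit-variance factor of
    the contrast estimate.
    """

    table: pd.DataFrame
    contrast_variance: float
    moderated: bool = False
    d0: float | None = None
    s0_sq: float | None = None


@dataclass
class LMMResult:
    """Per-gene random-intercept mixed-model fits.

    Columns: beta (fixed outcome effect, log2 units), se, sigma_u2
    (patient variance), sigma_e2 (residual variance), wald_t, p, p_adj,
    method ('reml', or 'ols' when the patient variance hit the zero
    boundary or every patient contributed a single sample).
    """

    table: pd.DataFrame
    df: int


def cell_means_design(condition: pd.Series) -> pd.DataFrame:
    """One-indicator-per-condition design (cell means coding)."""
    levels = list(dict.fromkeys(condition))
    mat = np.column_stack([(condition == lv).to_numpy(float) for lv in levels])
    return pd.DataFrame(mat, index=condition.index, columns=levels)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the columns that add no rank given their predecessors
    bad, r = [], 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            bad.append(names[j])
        r = rj
    raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def fit_linear_contrast(
    expr: pd.DataFrame, design: pd.DataFrame, contrast: Sequence[float] | pd.Series
) -> DEResult:
    """Per-gene least squares of expr on design, tested along a contrast.

    The reported log2FC is c' beta_hat; the (unmoderated) t statistic
    uses the per-gene residual variance with df = n - rank(design).
    """
    if not design.index.equals(expr.columns):
        design = design.reindex(expr.columns)
        if design.isna().any().any():
            raise ValueError("design rows do not match expression columns")
    if isinstance(contrast, pd.Series):
        contrast = contrast.reindex(design.columns)
        if contrast.isna().any():
            raise ValueError("contrast names do not match design coefficients")
        c = contrast.to_numpy(float)
    else:
        c = np.asarray(contrast, dtype=float)
        if c.shape != (design.shape[1],):
            raise ValueError("contrast length must equal the number of coefficients")

    X = design.to_numpy(float)
    n, p = X.shape
    _check_full_rank(X, list(design.columns))
    d = n - p
    if d < 1:
        raise ValueError("no residual degrees of freedom (n <= rank of design)")

    Y = expr.to_numpy(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv  # genes x p
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / d
    cvar = float(c @ xtx_inv @ c)
    lfc = B @ c

    if cvar == 0.0:
        t = np.zeros_like(lfc)
        pvals = np.ones_like(lfc)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(s2 * cvar)
        t = np.where(np.isnan(t), 0.0, t)
        pvals = 2.0 * stats.t.sf(np.abs(t), d)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": pvals,
            "p_adj": benjamini_hochberg(pvals),
            "df": float(d),
            "s2": s2,
        },
        index=expr.index,
    )
    return DEResult(table=table, contrast_variance=cvar, moderated=False)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def moderate(fit: DEResult) -> DEResult:
    """Empirical-Bayes moderation of a linear-contrast fit.

    Moment matching on log s_g^2: with z_g = log s_g^2, the quantity
    e_g = z_g - digamma(d_g/2) + log(d_g/2) has mean log s0^2 +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2) beyond
    the sampling term trigamma(d_g/2); solving the two equations gives
    (d0, s0^2). Posterior variances s~_g^2 = (d0 s0^2 + d_g s_g^2) /
    (d0 + d_g) replace s_g^2 in the t statistic, tested on d0 + d_g df.
    When the sample variances show no excess spread the prior df is
    +inf and every posterior variance equals s0^2.
    """
    tab = fit.table
    d = tab["df"].to_numpy(float)
    s2 = tab["s2"].to_numpy(float)
    ok = (d > 0) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive df and variance")

    z = np.log(s2[ok])
    e = z - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d[ok] / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    cvar = fit.contrast_variance
    lfc = tab["log2fc"].to_numpy(float)
    if cvar == 0.0:
        t = np.zeros_like(lfc)
        pvals = np.ones_like(lfc)
    else:
        t = lfc / np.sqrt(s2_post * cvar)
        df_total = d0 + d
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)

    table = tab.assign(
        t=t, p=pvals, p_adj=benjamini_hochberg(pvals), s2_post=s2_post
    )
    return DEResult(
        table=table,
        contrast_variance=cvar,
        moderated=True,
        d0=float(d0),
        s0_sq=s0_sq,
    )


def benjamini_hochberg(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted P values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def fit_mixed_model(
    expr: pd.DataFrame,
    outcomes: Mapping[str, str] | pd.Series,
    patient_ids: Sequence[str],
    positive_label: str | None = None,
) -> LMMResult:
    """Per-gene random-intercept LMM: y = b0 + b1*outcome + u_patient + e.

    ``outcomes`` maps patients (or samples) to one of two labels;
    ``patient_ids`` aligns with expression columns. Fits REML per gene
    (statsmodels MixedLM); a fit whose patient variance collapses to the
    zero boundary, or a cohort with a single biopsy per patient, falls
    back to ordinary least squares. The Wald statistic for b1 is referred
    to a t distribution with n_patients - 2 degrees of freedom — the
    between-patient df appropriate for a patient-level covariate.
    """
    import statsmodels.api as sm

    patient_ids = list(patient_ids)
    if len(patient_ids) != expr.shape[1]:
        raise ValueError("patient_ids must align with expression columns")
    outcomes = dict(outcomes.items()) if isinstance(outcomes, pd.Series) else dict(outcomes)

    if set(outcomes) >= set(expr.columns):
        # per-sample labels: collapse to patient level, demanding consistency
        per_patient: dict[str, str] = {}
        for s, pid in zip(expr.columns, patient_ids):
            lab = outcomes[s]
            if per_patient.setdefault(pid, lab) != lab:
                raise ValueError(
                    f"patient {pid} has samples in both outcome groups; "
                    "the outcome is a patient-level label"
                )
        outcomes = per_patient
    missing = [pid for pid in patient_ids if pid not in outcomes]
    if missing:
        raise ValueError(f"no outcome for patients: {sorted(set(missing))}")

    labels = sorted({outcomes[pid] for pid in set(patient_ids)})
    if len(labels) != 2:
        raise ValueError(f"need exactly two outcome groups, got {labels}")
    if positive_label is None:
        positive_label = "BCR" if "BCR" in labels else labels[1]
    x = np.array([1.0 if outcomes[pid] == positive_label else 0.0 for pid in patient_ids])

    patients = sorted(set(patient_ids))
    n_pat = len(patients)
    per_group = pd.Series({p: outcomes[p] for p in patients}).value_counts()
    if per_group.min() < 2:
        raise ValueError("need at least two patients per outcome group")
    df_wald = n_pat - 2

    groups = np.asarray(patient_ids)
    exog = np.column_stack([np.ones_like(x), x])
    counts = pd.Series(patient_ids).value_counts()
    all_singletons = bool((counts == 1).all())

    rows = []
    for gene, y in expr.iterrows():
        y = y.to_numpy(float)
        beta = se = su2 = se2 = np.nan
        method = "ols"
        if not all_singletons:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
                su2 = float(np.asarray(res.cov_re)[0, 0])
                se2 = float(res.scale)
                beta = float(res.fe_params[1])
                se = float(res.bse_fe[1])
                if res.converged and su2 > 1e-8 and np.isfinite(se):
                    method = "reml"
            except (np.linalg.LinAlgError, ValueError):
                pass
        if method == "ols":
            ols = sm.OLS(y, exog).fit()
            beta = float(ols.params[1])
            se = float(ols.bse[1])
            su2 = 0.0
            se2 = float(ols.scale)
        t = beta / se if se > 0 else 0.0
        rows.append((gene, beta, se, su2, se2, t, 2.0 * stats.t.sf(abs(t), df_wald), method))

    table = pd.DataFrame(
        rows,
        columns=["gene", "beta", "se", "sigma_u2", "sigma_e2", "wald_t", "p", "method"],
    ).set_index("gene")
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    return LMMResult(table=table, df=df_wald)


def filter_de(
    result: DEResult | LMMResult,
    p_threshold: float = 0.05,
    fc_threshold_log2: float = 1.0,
    use_adjusted: bool = False,
) -> list[str]:
    """Genes with P (or P_adj) below and |log2FC| at or above threshold."""
    if p_threshold <= 0 or fc_threshold_log2 < 0:
        raise ValueError("thresholds must be positive")
    tab = result.table
    fc = tab["log2fc"] if "log2fc" in tab.columns else tab["beta"]
    pcol = tab["p_adj"] if use_adjusted else tab["p"]
    keep = (pcol < p_threshold) & (fc.abs() >= fc_threshold_log2)
    return list(tab.index[keep])
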