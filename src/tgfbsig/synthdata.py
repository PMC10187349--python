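"""Synthetic data generators emulating the structure of a radiogenomic
prostate-cancer study.

Four generators cover the inputs the analysis pipeline consumes:

* a six-condition epithelial/stromal co-culture experiment with a handful
  of planted TGF-beta-responsive genes (signature discovery substrate),
* a radiotherapy cohort with repeated biopsies per patient, patient-level
  random intercepts and a planted outcome-associated gene set,
* per-sample PTEN/TP53 allele-call tables with outcome-conditional
  enrichment of multi-allele loss,
* post-treatment PSA trajectories with a planted biochemical-recurrence
  crossing time for recurrent patients.

Every generator is deterministic given its config and seed: a single seed
is expanded into independent per-stream child seeds (baselines, planted
gene choice, noise, patient assignment, volumes, grades, alleles, PSA) so
adding a stream never perturbs draws from earlier streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CoCultureConfig",
    "CohortConfig",
    "AlleleConfig",
    "PsaConfig",
    "PlantedTruth",
    "simulate_coculture",
    "simulate_cohort",
    "simulate_allele_calls",
    "simulate_psa_series",
]

#: The six co-culture conditions. The contrast of interest compares the
#: TGF-beta-stimulated epithelial/stromal co-culture (no receptor
#: inhibitor) against the five remaining, equally weighted, conditions.
CONDITIONS = (
    "cocult_tgfb",
    "cocult_vehicle",
    "cocult_tgfb_sd208",
    "cocult_sd208",
    "stroma_tgfb",
    "stroma_vehicle",
)

#: Clinical follow-up grid in months: quarterly for two years, then
#: semi-annually to five years, then yearly.
PSA_SCHEDULE = (0, 3, 6, 9, 12, 15, 18, 21, 24, 30, 36, 42, 48, 54, 60, 72, 84, 96)


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


@dataclass
class PlantedTruth:
    """Ground-truth record of what a generator planted.

    ``patient_intercepts`` is recorded for planted signature genes only
    (gene -> patient -> intercept); other fields are filled by whichever
    generator produced the object.
    """

    gene_effects: dict[str, float] = field(default_factory=dict)
    patient_intercepts: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_outcomes: dict[str, str] = field(default_factory=dict)
    allele_counts: dict[str, int] = field(default_factory=dict)
    psa_crossing_months: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gene_effects": self.gene_effects,
            "patient_intercepts": self.patient_intercepts,
            "sample_outcomes": self.sample_outcomes,
            "allele_counts": self.allele_counts,
            "psa_crossing_months": self.psa_crossing_months,
        }


# --------------------------------------------------------------------------
# co-culture experiment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoCultureConfig:
    """Configuration of the six-condition co-culture simulation.

    Expression is on a log2 microarray-intensity scale: per-gene baselines
    are drawn once from Normal(baseline_mean, baseline_sd) and replicate
    noise from Normal(0, noise_sd). Planted genes gain ``planted_log2fc``
    only in the TGF-beta-stimulated co-culture condition.
    """

    n_genes: int = 200
    n_replicates_per_condition: int = 3
    n_planted: int = 6
    planted_log2fc: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"n_planted ({self.n_planted}) exceeds n_genes ({self.n_genes})"
            )
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")


def simulate_coculture(
    config: CoCultureConfig,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Simulate a genes x (6 * replicates) log2 expression matrix.

    Returns the matrix, a per-sample condition annotation, and the
    planted-truth record (gene -> planted log2 effect in ``cocult_tgfb``).
    """
    rng = _streams(config.seed, ["baselines", "planted", "noise"])
    genes = _gene_names(config.n_genes)
    reps = config.n_replicates_per_condition
    samples = [f"{cond}_r{j + 1}" for cond in CONDITIONS for j in range(reps)]
    condition = pd.Series(
        [cond for cond in CONDITIONS for _ in range(reps)],
        index=samples,
        name="condition",
    )

    mu = rng["baselines"].normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    planted_idx = np.sort(
        rng["planted"].choice(config.n_genes, size=config.n_planted, replace=False)
    )
    noise = rng["noise"].normal(0.0, config.noise_sd, (config.n_genes, len(samples)))

    expr = mu[:, None] + noise
    tgfb_cols = np.asarray(condition.to_numpy() == "cocult_tgfb")
    expr[np.ix_(planted_idx, np.flatnonzero(tgfb_cols))] += config.planted_log2fc

    matrix = pd.DataFrame(expr, index=genes, columns=samples)
    truth = PlantedTruth(
        gene_effects={genes[i]: float(config.planted_log2fc) for i in planted_idx}
    )
    return matrix, condition, truth


# --------------------------------------------------------------------------
# patient cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the repeated-biopsy radiotherapy cohort.

    The per-sample expression model is

        y_gij = mu_g + beta_g * BCR_i + u_gi + eps_gij

    with a patient-level random intercept u_gi ~ Normal(0, patient_sd^2)
    shared across patient i's biopsies and residual noise
    eps ~ Normal(0, residual_sd^2). beta_g equals ``signature_effect`` for
    the planted signature genes and 0 elsewhere. Outcome (BCR vs NED) is a
    patient-level label shared by all of a patient's biopsies; lesion
    volumes are drawn lognormal with outcome-specific (meanlog, sdlog).
    """

    n_patients: int = 29
    biopsies_min: int = 1
    biopsies_max: int = 4
    bcr_fraction: float = 0.17
    n_genes: int = 500
    signature_genes: tuple[str, ...] | None = None
    n_signature_genes: int = 6
    signature_effect: float = 1.0
    patient_sd: float = 0.5
    residual_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    volume_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"NED": (0.7, 0.8), "BCR": (1.8, 0.8)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bcr_fraction < 1:
            raise ValueError("bcr_fraction must be in (0, 1)")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not 1 <= self.biopsies_min <= self.biopsies_max:
            raise ValueError("need 1 <= biopsies_min <= biopsies_max")
        if self.signature_genes is not None:
            universe = set(_gene_names(self.n_genes))
            missing = [g for g in self.signature_genes if g not in universe]
            if missing:
                raise ValueError(
                    f"signature genes not in the {self.n_genes}-gene universe: {missing}"
                )

    @property
    def n_bcr(self) -> int:
        return int(round(self.n_patients * self.bcr_fraction))


# Gleason grade-group mix of an intermediate/high-risk cohort
# (grade groups 1..5).
_GRADE_PROBS = (0.0, 0.103, 0.103, 0.379, 0.415)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate expression + annotation for a repeated-biopsy cohort.

    Returns (expression genes x samples, annotation, truth). Annotation
    columns: patient_id, lesion_id, outcome, grade_group,
    pct_highest_grade, volume_baseline_cm3, volume_post_cm3; index is the
    sample (biopsy) ID.
    """
    if config.n_bcr < 1:
        raise ValueError(
            "bcr_fraction * n_patients rounds to zero BCR patients; "
            "increase n_patients (or bcr_fraction)"
        )
    rng = _streams(
        config.seed,
        ["baselines", "genes", "assign", "intercepts", "noise", "volumes", "grades"],
    )
    genes = _gene_names(config.n_genes)

    if config.signature_genes is None:
        sig_idx = np.sort(
            rng["genes"].choice(config.n_genes, config.n_signature_genes, replace=False)
        )
        signature_genes = [genes[i] for i in sig_idx]
    else:
        signature_genes = list(config.signature_genes)
        sig_idx = np.array([genes.index(g) for g in signature_genes])

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    outcome = np.array(["BCR"] * config.n_bcr + ["NED"] * (config.n_patients - config.n_bcr))
    rng["assign"].shuffle(outcome)
    n_biopsies = rng["assign"].integers(
        config.biopsies_min, config.biopsies_max + 1, config.n_patients
    )

    sample_ids: list[str] = []
    patient_of: list[str] = []
    lesion_of: list[str] = []
    for pid, nb in zip(patients, n_biopsies):
        for k in range(nb):
            sample_ids.append(f"{pid}_B{k + 1}")
            patient_of.append(pid)
            # at most three cores per lesion, mirroring targeted sampling
            lesion_of.append(f"{pid}_L{k // 3 + 1}")
    n_samples = len(sample_ids)
    pat_index = np.array([patients.index(p) for p in patient_of])
    is_bcr = np.array([outcome[i] == "BCR" for i in pat_index])

    mu = rng["baselines"].normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    beta = np.zeros(config.n_genes)
    beta[sig_idx] = config.signature_effect
    u = rng["intercepts"].normal(0.0, config.patient_sd, (config.n_genes, config.n_patients))
    eps = rng["noise"].normal(0.0, config.residual_sd, (config.n_genes, n_samples))

    expr = mu[:, None] + beta[:, None] * is_bcr[None, :] + u[:, pat_index] + eps
    matrix = pd.DataFrame(expr, index=genes, columns=sample_ids)

    # lesion volumes (cm^3): one baseline/post pair per lesion, shared by
    # that lesion's biopsies; post volume is baseline shrunk by RT
    vol_base: dict[str, float] = {}
    vol_post: dict[str, float] = {}
    for les, pid in sorted(set(zip(lesion_of, patient_of))):
        meanlog, sdlog = config.volume_params[outcome[patients.index(pid)]]
        b = float(rng["volumes"].lognormal(meanlog, sdlog))
        shrink = float(rng["volumes"].beta(1.5, 5.0))
        vol_base[les] = b
        vol_post[les] = b * shrink
    grade = rng["grades"].choice(np.arange(1, 6), size=n_samples, p=_GRADE_PROBS)
    pct = np.round(rng["grades"].uniform(10, 90, n_samples), 1)

    annotation = pd.DataFrame(
        {
            "patient_id": patient_of,
            "lesion_id": lesion_of,
            "outcome": [outcome[i] for i in pat_index],
            "grade_group": grade,
            "pct_highest_grade": pct,
            "volume_baseline_cm3": [vol_base[l] for l in lesion_of],
            "volume_post_cm3": [vol_post[l] for l in lesion_of],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = PlantedTruth(
        gene_effects={g: float(config.signature_effect) for g in signature_genes},
        patient_intercepts={
            g: {p: float(u[gi, pi]) for pi, p in enumerate(patients)}
            for g, gi in zip(signature_genes, sig_idx)
        },
        sample_outcomes={s: annotation.loc[s, "outcome"] for s in sample_ids},
    )
    return matrix, annotation, truth


# --------------------------------------------------------------------------
# allele calls
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleConfig:
    """Outcome-conditional PTEN/TP53 allele-alteration distributions.

    Per sample and gene, copies lost is categorical over {0, 1, 2} and the
    oncogenic mutation count is Binomial(2, mutation_prob), both keyed by
    the sample's outcome. Defaults enrich multi-allele loss in recurrent
    (BCR) samples; passing identical distributions for both outcomes turns
    the enrichment off.
    """

    loss_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"NED": (0.85, 0.13, 0.02), "BCR": (0.15, 0.45, 0.40)}
    )
    mutation_prob: Mapping[str, float] = field(
        default_factory=lambda: {"NED": 0.05, "BCR": 0.35}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for k, p in self.loss_probs.items():
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"loss_probs[{k!r}] must be a 3-simplex")
        for k, p in self.mutation_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"mutation_prob[{k!r}] must be in [0, 1]")


ALLELE_GENES = ("PTEN", "TP53")


def simulate_allele_calls(
    config: AlleleConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw per-sample PTEN/TP53 allele calls conditioned on outcome.

    Returns a long table with one row per (sample, gene) — columns
    sample_id, patient_id, gene, copies_lost, oncogenic_mutation_count —
    and a truth record with the intended altered-allele count A per
    sample (per-gene contribution capped at two alleles).
    """
    rng = _streams(config.seed, ["alleles"])["alleles"]
    rows = []
    counts: dict[str, int] = {}
    for sample, row in annotation.iterrows():
        grp = row["outcome"]
        a = 0
        for gene in ALLELE_GENES:
            lost = int(rng.choice(3, p=config.loss_probs[grp]))
            muts = int(rng.binomial(2, config.mutation_prob[grp]))
            a += min(2, lost + muts)
            rows.append(
                {
                    "sample_id": sample,
                    "patient_id": row["patient_id"],
                    "gene": gene,
                    "copies_lost": lost,
                    "oncogenic_mutation_count": muts,
                }
            )
        counts[str(sample)] = a
    table = pd.DataFrame(rows)
    truth = PlantedTruth(
        allele_counts=counts,
        sample_outcomes={s: annotation.loc[s, "outcome"] for s in annotation.index},
    )
    return table, truth


# --------------------------------------------------------------------------
# PSA trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaConfig:
    """Post-treatment PSA trajectory parameters (ng/mL, months).

    All patients decline exponentially from a lognormal pretreatment
    baseline to ``nadir`` at ``decline_months``. NED patients then stay at
    the nadir with small positive noise never reaching nadir + 2. BCR
    patients rise linearly so that PSA first reaches nadir + 2 ng/mL
    exactly at a planted follow-up visit (the Phoenix definition of
    biochemical recurrence); with nonzero noise the pre-crossing values
    are kept strictly below threshold so the planted crossing is the
    first qualifying time.
    """

    baseline_median: float = 13.5
    baseline_sdlog: float = 0.5
    nadir: float = 0.5
    decline_months: int = 12
    rise_months: int = 18
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nadir <= 0 or self.baseline_median <= self.nadir:
            raise ValueError("need 0 < nadir < baseline_median")


def simulate_psa_series(
    annotation: pd.DataFrame, config: PsaConfig
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate per-patient PSA follow-up series on the visit schedule.

    Returns a long table (patient_id, time_months, psa_ng_ml) and a truth
    record mapping patient -> planted crossing month (None for NED).
    """
    rng = _streams(config.seed, ["psa"])["psa"]
    outcome_by_patient = (
        annotation.groupby("patient_id")["outcome"].first().to_dict()
        if "patient_id" in annotation.columns
        else annotation["outcome"].to_dict()
    )
    times = np.asarray(PSA_SCHEDULE, dtype=float)
    decline_k = math.log(1000.0) / config.decline_months
    eligible_crossings = [
        t for t in PSA_SCHEDULE if config.decline_months + config.rise_months <= t <= 72
    ]

    rows = []
    crossings: dict[str, float | None] = {}
    for pid in sorted(outcome_by_patient):
        grp = outcome_by_patient[pid]
        baseline = float(rng.lognormal(math.log(config.baseline_median), config.baseline_sdlog))
        t_cross = float(rng.choice(eligible_crossings)) if grp == "BCR" else None
        values = np.empty_like(times)
        for i, t in enumerate(times):
            if t < config.decline_months:
                v = config.nadir + (baseline - config.nadir) * math.exp(-decline_k * t)
                v += abs(rng.normal(0.0, config.noise_sd))
            elif t == config.decline_months:
                v = config.nadir  # anchor the running nadir exactly
            elif grp == "NED" or t < t_cross - config.rise_months:
                v = config.nadir + min(
                    abs(rng.normal(0.0, config.noise_sd)), 1.5
                )
            else:
                frac = (t - (t_cross - config.rise_months)) / config.rise_months
                v = config.nadir + 2.0 * frac + rng.normal(0.0, config.noise_sd)
                if t < t_cross:
                    v = min(v, config.nadir + 1.9)
                    v = max(v, config.nadir)
                elif t == t_cross:
                    v = max(v, config.nadir + 2.0)
                else:
                    v = max(v, config.nadir + 2.0 + 2.0 * (t - t_cross) / config.rise_months)
            values[i] = v
        crossings[pid] = t_cross
        rows.extend(
            {"patient_id": pid, "time_months": float(t), "psa_ng_ml": float(v)}
            for t, v in zip(times, values)
        )
    return pd.DataFrame(rows), PlantedTruth(psa_crossing_months=crossings)
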