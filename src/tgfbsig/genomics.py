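"""PTEN/TP53 allele-dosage genomics.

A tumor suppressor contributes up to two altered alleles per gene: the
number of copies lost plus the number of oncogenic mutations, capped at
two (a mutation on an already-deleted allele cannot disable a third
allele). The allele-dosage count A sums the two genes' contributions
(0-4); A >= 3 — e.g. hemizygous PTEN loss plus a TP53 mutation plus
loss of the remaining TP53 copy — defines the high-risk genomic class.
Two mutations in a gene without copy loss count as two altered alleles
(compound heterozygosity is assumed; phasing is out of scope).

Cohort classification is at the patient level, on one designated sample
per patient; the representative biopsy is the core with the highest
Gleason grade group, ties broken by the greatest percentage of tumor at
the highest-grade pattern, then by lexicographic biopsy ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "GENES",
    "BiopsyRecord",
    "AlleleDoseResult",
    "CohortClassification",
    "count_altered_alleles",
    "classify_cohort",
    "select_representative_biopsy",
]

GENES = ("PTEN", "TP53")


@dataclass(frozen=True)
class AlleleDoseResult:
    """Altered-allele count A (0-4) for one sample and its class at the
    given threshold (default: A >= 3 is positive)."""

    altered_alleles: int
    positive: bool
    threshold: int
    per_gene: Mapping[str, int]


@dataclass(frozen=True)
class BiopsyRecord:
    biopsy_id: str
    grade_group: int
    pct_highest_grade: float

    def __post_init__(self) -> None:
        if not 1 <= self.grade_group <= 5:
            raise ValueError("Gleason grade group must be in 1..5")
        if not 0 <= self.pct_highest_grade <= 100:
            raise ValueError("percent highest-grade pattern must be in 0..100")


@dataclass(frozen=True)
class CohortClassification:
    """Patient-level classification and its confusion against outcome."""

    table: pd.DataFrame  # index patient; altered_alleles, positive, outcome
    threshold: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def count_altered_alleles(
    calls: Mapping[str, tuple[int, int]] | pd.DataFrame, threshold: int = 3
) -> AlleleDoseResult:
    """Allele-dosage count for one sample.

    ``calls`` maps gene -> (copies_lost, oncogenic_mutation_count), or is
    a DataFrame with columns gene, copies_lost, oncogenic_mutation_count
    holding one sample's rows. A gene absent from the input is treated
    as unaltered, with a warning.
    """
    if isinstance(calls, pd.DataFrame):
        if calls["gene"].duplicated().any():
            raise ValueError("one row per (sample, gene) expected")
        calls = {
            r["gene"]: (int(r["copies_lost"]), int(r["oncogenic_mutation_count"]))
            for _, r in calls.iterrows()
        }
    per_gene: dict[str, int] = {}
    for gene in GENES:
        if gene not in calls:
            warnings.warn(f"no allele call for {gene}; treating it as unaltered")
            per_gene[gene] = 0
            continue
        lost, muts = calls[gene]
        if not 0 <= lost <= 2:
            raise ValueError(f"{gene}: copies_lost must be in 0..2, got {lost}")
        if muts < 0:
            raise ValueError(f"{gene}: mutation count must be >= 0, got {muts}")
        per_gene[gene] = min(2, lost + muts)
    a = sum(per_gene.values())
    return AlleleDoseResult(
        altered_alleles=a, positive=a >= threshold, threshold=threshold, per_gene=per_gene
    )


def classify_cohort(
    table: pd.DataFrame,
    outcomes: Mapping[str, str],
    representative: Mapping[str, str],
    threshold: int = 3,
) -> CohortClassification:
    """Patient-level allele-dosage classification vs outcome.

    ``table`` is the long allele-call table (sample_id, patient_id,
    gene, copies_lost, oncogenic_mutation_count); ``representative``
    designates the one sample per patient to classify. Specificity is
    TN/(TN+FP) among NED patients; BCR is the positive outcome.
    """
    by_sample = {s: g for s, g in table.groupby("sample_id")}
    rows = []
    for patient, outcome in sorted(outcomes.items()):
        if patient not in representative:
            raise ValueError(f"no designated representative sample for patient {patient}")
        sample = representative[patient]
        if sample not in by_sample:
            raise ValueError(f"designated sample {sample} has no allele calls")
        res = count_altered_alleles(
            by_sample[sample][["gene", "copies_lost", "oncogenic_mutation_count"]],
            threshold=threshold,
        )
        rows.append((patient, sample, res.altered_alleles, res.positive, outcome))
    tab = pd.DataFrame(
        rows, columns=["patient_id", "sample_id", "altered_alleles", "positive", "outcome"]
    ).set_index("patient_id")
    is_bcr = tab["outcome"] == "BCR"
    pos = tab["positive"]
    return CohortClassification(
        table=tab,
        threshold=threshold,
        tp=int((pos & is_bcr).sum()),
        fp=int((pos & ~is_bcr).sum()),
        tn=int((~pos & ~is_bcr).sum()),
        fn=int((~pos & is_bcr).sum()),
    )


def select_representative_biopsy(biopsies: Sequence[BiopsyRecord]) -> str:
    """The core used for per-patient analyses: highest Gleason grade
    group, tie broken by greatest percent of tumor at the highest-grade
    pattern, residual tie by lexicographically smallest biopsy ID."""
    if not biopsies:
        raise ValueError("at least one biopsy with tumor is required")
    best = min(biopsies, key=lambda b: (-b.grade_group, -b.pct_highest_grade, b.biopsy_id))
    return best.biopsy_id
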