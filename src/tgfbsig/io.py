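"""File formats and run configuration.

Expression matrices are read/written as plain TSV (gene IDs in the
first column, sample IDs in the header) or GCT v1.2; gene sets as GMT;
allele calls are assembled from a MAF-subset mutation TSV plus a
gene-level copy-number TSV. Gene identifiers are upper-cased on read
(mixed-source symbol tables). RunConfig gathers the pipeline constants
(FDR 0.1, P 0.05, two-fold change, three-allele threshold, tau 0.25,
selection start at three genes) and round-trips through JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics import GENES
from .signature import GeneSignature

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_allele_calls",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and flags; defaults are the analysis' stated
    constants."""

    seed: int = 0
    fdr_threshold: float = 0.1
    p_threshold: float = 0.05
    fold_change: float = 2.0
    allele_threshold: int = 3
    tau: float = 0.25
    n_start: int = 3
    normalize_scores: bool = True
    allow_missing_genes: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _validate_matrix(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    df.index = df.index.astype(str).str.upper()
    df.index.name = None
    df.columns.name = None
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene identifiers: {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = bad.isna() & df[col].notna()
        if nonnum.any():
            row = df.index[nonnum.argmax()]
            raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        df[col] = bad
    if df.isna().any().any() or not np.isfinite(df.to_numpy(float)).all():
        raise ValueError(f"{path}: expression values must be finite")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV or GCT v1.2."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2"):
        with path.open() as fh:
            fh.readline()
            dims = fh.readline().split("\t")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in df.columns if c.lower() == "description"])
        if df.shape != (n_rows, n_cols):
            raise ValueError(
                f"{path}: GCT declares {n_rows}x{n_cols} but contains "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_matrix(df, path)


def write_expression(matrix: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets (name, description, tab-separated genes),
    preserving gene order."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has no genes")
        name, genes = fields[0], [g.upper() for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]] | GeneSignature, path: str | Path,
    description: str = "tgfbsig",
) -> None:
    if isinstance(sets, GeneSignature):
        sets = {"TGFB_PROSTATE": list(sets.genes)}
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_allele_calls(
    mutation_path: str | Path,
    copy_path: str | Path,
    samples: Sequence[str] | None = None,
    patient_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join a MAF-subset mutation TSV with a gene-level copy-number TSV.

    The mutation table needs columns Tumor_Sample_Barcode, Hugo_Symbol
    and oncogenic (only rows flagged 'Oncogenic'/'Likely Oncogenic' are
    counted); the copy table needs sample_id, gene, copies_lost. Rows
    for genes other than PTEN/TP53 are dropped with a warning; a
    (sample, gene) pair absent from both tables is unaltered. ``samples``
    extends the sample universe (e.g. samples with no alterations at
    all); ``patient_of`` supplies patient IDs (defaults to the sample ID).
    """
    mut = pd.read_csv(mutation_path, sep="\t")
    cn = pd.read_csv(copy_path, sep="\t")

    universe = set(samples or [])
    rows: dict[tuple[str, str], dict[str, int]] = {}

    if len(mut):
        mut["Hugo_Symbol"] = mut["Hugo_Symbol"].astype(str).str.upper()
        unknown = sorted(set(mut["Hugo_Symbol"]) - set(GENES))
        if unknown:
            warnings.warn(f"dropping mutation rows for genes outside {GENES}: {unknown}")
            mut = mut[mut["Hugo_Symbol"].isin(GENES)]
        onco = mut["oncogenic"].astype(str).str.strip().str.lower().isin(
            {"oncogenic", "likely oncogenic", "true", "1", "yes"}
        )
        for (s, g), cnt in (
            mut[onco].groupby(["Tumor_Sample_Barcode", "Hugo_Symbol"]).size().items()
        ):
            rows.setdefault((str(s), g), {})["oncogenic_mutation_count"] = int(cnt)
        universe |= set(map(str, mut["Tumor_Sample_Barcode"]))

    if len(cn):
        cn["gene"] = cn["gene"].astype(str).str.upper()
        unknown = sorted(set(cn["gene"]) - set(GENES))
        if unknown:
            warnings.warn(f"dropping copy-number rows for genes outside {GENES}: {unknown}")
            cn = cn[cn["gene"].isin(GENES)]
        if cn.duplicated(subset=["sample_id", "gene"]).any():
            dup = cn[cn.duplicated(subset=["sample_id", "gene"])]
            raise ValueError(
                f"duplicate (sample, gene) copy-number rows: "
                f"{list(dup[['sample_id', 'gene']].itertuples(index=False, name=None))}"
            )
        for _, r in cn.iterrows():
            rows.setdefault((str(r["sample_id"]), r["gene"]), {})["copies_lost"] = int(
                r["copies_lost"]
            )
        universe |= set(map(str, cn["sample_id"]))

    out = []
    for sample in sorted(universe):
        for gene in GENES:
            rec = rows.get((sample, gene), {})
            out.append(
                {
                    "sample_id": sample,
                    "patient_id": (patient_of or {}).get(sample, sample),
                    "gene": gene,
                    "copies_lost": rec.get("copies_lost", 0),
                    "oncogenic_mutation_count": rec.get("oncogenic_mutation_count", 0),
                }
            )
    return pd.DataFrame(out, columns=[
        "sample_id", "patient_id", "gene", "copies_lost", "oncogenic_mutation_count"
    ])
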