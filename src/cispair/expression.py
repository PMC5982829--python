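"""Count-matrix ingestion, CPM normalization, expression filtering, profiles.

A cohort is a set of per-cancer-type raw count matrices (genes x samples).
Normalization is plain counts-per-million against the raw library size
(column sum); no compositional correction (TMM etc.) is applied.  The
expression filter retains, per cancer type, genes with >= ``min_cpm`` in at
least ``min_samples`` samples; mean profiles for the specificity score are
computed over all samples regardless of that filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix for one cancer type, in raw counts or CPM."""

    cancer_type: str
    data: pd.DataFrame  # index: gene_id, columns: sample_id
    unit: str = "raw_counts"  # {raw_counts, cpm}

    def __post_init__(self) -> None:
        if self.unit not in ("raw_counts", "cpm"):
            raise ExpressionError(f"bad unit {self.unit!r}")
        if (self.data.to_numpy() < 0).any():
            raise ExpressionError(f"{self.cancer_type}: negative entries")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)


@dataclass
class MeanProfile:
    """Per-cancer-type mean CPM of one gene, ordered by cancer type."""

    gene_id: str
    values: pd.Series = field(repr=False)  # index: cancer_type

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ExpressionError(f"{self.gene_id}: negative profile entry")


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: each column scaled by its raw sum x 1e6.

    All-zero library columns are passed through as zeros with a warning.
    """
    if counts.unit != "raw_counts":
        raise ExpressionError("cpm_normalize expects raw counts")
    libsize = counts.data.sum(axis=0)
    zero_cols = libsize == 0
    if zero_cols.any():
        warnings.warn(
            f"{counts.cancer_type}: {int(zero_cols.sum())} all-zero library column(s)"
        )
    safe = libsize.replace(0, 1)
    cpm = counts.data.div(safe, axis=1) * 1e6
    return ExpressionMatrix(cancer_type=counts.cancer_type, data=cpm, unit="cpm")


def filter_expressed(
    cpm: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> List[str]:
    """Gene ids with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if cpm.unit != "cpm":
        raise ExpressionError("filter_expressed expects a cpm matrix")
    n_ok = (cpm.data >= min_cpm).sum(axis=1)
    return list(cpm.data.index[n_ok >= min_samples])


def mean_profile(
    cpms: Mapping[str, ExpressionMatrix], gene_id: str
) -> MeanProfile:
    """Arithmetic mean CPM per cancer type for one gene.

    Cancer types whose matrix lacks the gene contribute 0 (a gene absent
    from a filtered matrix has no measured counts there); a gene absent from
    every matrix is an error.
    """
    entries = {}
    present = False
    for cancer_type, mat in cpms.items():
        if mat.unit != "cpm":
            raise ExpressionError("mean_profile expects cpm matrices")
        if gene_id in mat.data.index:
            entries[cancer_type] = float(mat.data.loc[gene_id].mean())
            present = True
        else:
            entries[cancer_type] = 0.0
    if not present:
        raise ExpressionError(f"{gene_id}: absent from every cancer type")
    return MeanProfile(gene_id=gene_id, values=pd.Series(entries))


def mean_profiles(cpms: Mapping[str, ExpressionMatrix]) -> pd.DataFrame:
    """Genes x cancer-types matrix of mean CPM (union of genes, absent -> 0)."""
    cols = {}
    for cancer_type, mat in cpms.items():
        if mat.unit != "cpm":
            raise ExpressionError("mean_profiles expects cpm matrices")
        cols[cancer_type] = mat.data.mean(axis=1)
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path, cancer_type: str) -> ExpressionMatrix:
    """TSV with gene_id first column, sample ids in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(cancer_type=cancer_type, data=df, unit="raw_counts")


def write_counts_tsv(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="gene_id")


def read_cohort_index(path: str | Path) -> Dict[str, Path]:
    """Two-column TSV (cancer_type, path); paths resolve relative to the index."""
    base = Path(path).parent
    out: Dict[str, Path] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cancer_type, rel = line.rstrip("\n").split("\t")
            p = Path(rel)
            out[cancer_type] = p if p.is_absolute() else base / p
    return out


def load_cohort(index_path: str | Path) -> Dict[str, ExpressionMatrix]:
    """Read every cancer type's raw count matrix named in a cohort index."""
    return {
        ct: read_counts_tsv(p, ct) for ct, p in read_cohort_index(index_path).items()
    }


def load_cohort_cpm(index_path: str | Path) -> Dict[str, ExpressionMatrix]:
    return {ct: cpm_normalize(m) for ct, m in load_cohort(index_path).items()}
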