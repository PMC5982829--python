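"""Downstream characterization of the screened pair sets.

Covers the four follow-up metrics used to prioritize candidate regulatory
lncRNAs: Tau expression specificity across cancer types, mean exonic
sequence conservation (lncRNA exons masked by coding exons), subcellular
localization via the cytoplasmic/nuclear relative concentration index (RCI),
and coupling between lncRNA expression and methylation at the paired coding
gene's TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import (
    GeneRecord,
    Interval,
    interval_length,
    merge_exons,
    merge_intervals,
    subtract_intervals,
)
from .expression import ExpressionMatrix, MeanProfile
from .screen import P_FLOOR, ConstantInputError, bh_adjust, fisher_exact_2x2, spearman

log = logging.getLogger(__name__)

TSS_REGIONS = ("TSS200", "TSS1500")


@dataclass
class TauScore:
    gene_id: str
    tau: float
    n_groups: int


@dataclass
class ConservationResult:
    gene_id: str
    mean_score: float  # nan when n_bases == 0
    n_bases: int


# ---------------------------------------------------------------------------
# Tau specificity
# ---------------------------------------------------------------------------

def tau(profile: MeanProfile, log_transform: bool = True) -> TauScore:
    """Tau expression-specificity index over cancer-type mean expression.

    tau = sum_i (1 - x_i / max(x)) / (n - 1), computed on log2(x + 1) by
    default.  0 for a uniform nonzero profile (ubiquitous expression), 1
    when exactly one group is expressed (fully restricted).
    """
    x = profile.values.to_numpy(dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"{profile.gene_id}: tau needs >= 2 groups")
    if log_transform:
        x = np.log2(x + 1.0)
    m = x.max()
    if m <= 0:
        raise ValueError(f"{profile.gene_id}: tau undefined for all-zero profile")
    value = float((1.0 - x / m).sum() / (n - 1))
    return TauScore(gene_id=profile.gene_id, tau=value, n_groups=n)


def tau_table(profiles: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """Tau per row of a genes x cancer-types mean-expression matrix.

    All-zero rows yield NaN rather than an error.
    """
    x = profiles.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    m = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (1.0 - x / m[:, None]).sum(axis=1) / (n - 1)
    vals = np.where(m > 0, vals, np.nan)
    return pd.Series(vals, index=profiles.index, name="tau")


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Per-base score track backed by disjoint scored intervals per chromosome.

    Bases not covered by any interval score 0, matching the convention of
    averaging a conservation signal over every exonic base.
    """

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int, float]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._values: Dict[str, np.ndarray] = {}
        for chrom, rows in intervals.items():
            rows = sorted(rows)
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping track intervals")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in rows], dtype=float)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ScoreTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        return cls(
            {
                chrom: list(zip(g["start"], g["end"], g["value"]))
                for chrom, g in df.groupby("chrom")
            }
        )

    @classmethod
    def from_bigwig(cls, path: str | Path) -> "ScoreTrack":
        import pyBigWig  # optional reader

        bw = pyBigWig.open(str(path))
        data = {}
        for chrom in bw.chroms():
            data[chrom] = [
                (s, e, v) for s, e, v in (bw.intervals(chrom) or []) if v is not None
            ]
        bw.close()
        return cls(data)

    def sum_over(self, chrom: str, intervals: Sequence[Interval]) -> float:
        """Sum of per-base scores over half-open intervals (uncovered = 0)."""
        if chrom not in self._starts:
            return 0.0
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        total = 0.0
        for s, e in intervals:
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            if hi <= lo:
                continue
            ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
            total += float((ov * values[lo:hi]).sum())
        return total


def exonic_conservation(
    gene: GeneRecord,
    track: ScoreTrack,
    mask: Sequence[Interval] = (),
) -> ConservationResult:
    """Base-weighted mean track score over the gene's merged exons minus mask.

    For lncRNAs the mask is the union of all coding exons on the same
    chromosome, so only non-coding exonic sequence contributes.  An empty
    support yields n_bases = 0 and an undefined (NaN) mean.
    """
    support = subtract_intervals(merge_exons(gene), merge_intervals(list(mask)))
    n_bases = interval_length(support)
    if n_bases == 0:
        log.info("%s: empty conservation support after masking", gene.gene_id)
        return ConservationResult(gene_id=gene.gene_id, mean_score=float("nan"), n_bases=0)
    total = track.sum_over(gene.chrom, support)
    return ConservationResult(
        gene_id=gene.gene_id, mean_score=total / n_bases, n_bases=n_bases
    )


def conservation_table(
    genes: Sequence[GeneRecord], track: ScoreTrack
) -> pd.DataFrame:
    """Mean exonic conservation for every gene; coding exons mask lncRNAs."""
    coding_exons: Dict[str, List[Interval]] = {}
    for g in genes:
        if g.biotype == "coding":
            coding_exons.setdefault(g.chrom, []).extend(g.exons)
    coding_exons = {c: merge_intervals(v) for c, v in coding_exons.items()}
    rows = []
    for g in genes:
        mask = coding_exons.get(g.chrom, []) if g.biotype == "lncRNA" else []
        res = exonic_conservation(g, track, mask)
        rows.append((g.gene_id, g.biotype, res.mean_score, res.n_bases))
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "mean_score", "n_bases"])


# ---------------------------------------------------------------------------
# gene-category enrichment
# ---------------------------------------------------------------------------

def category_enrichment(
    summaries: pd.DataFrame,
    category: Iterable[str],
    category_name: str = "category",
    background: str = "other_sets",
) -> pd.DataFrame:
    """Per set (LCN/LCP/CCN/CCP): fraction of unique coding genes in a category.

    Fisher's exact test compares each set's coding genes against either the
    union of the other three sets (default) or all coding genes present in
    the summaries.
    """
    if background not in ("other_sets", "all_genes"):
        raise ValueError(f"bad background {background!r}")
    category = set(category)
    sets = {
        lbl: set(summaries.loc[summaries["set_label"] == lbl, "anchor_id"])
        for lbl in ("LCN", "LCP", "CCN", "CCP")
    }
    all_coding = set(summaries["anchor_id"])
    rows = []
    for lbl, members in sets.items():
        if not members:
            log.info("%s: empty set, enrichment undefined", lbl)
            rows.append(
                dict(set_label=lbl, category=category_name, n_genes=0,
                     n_in_category=0, fraction=np.nan, fisher_p=np.nan)
            )
            continue
        other = (
            set().union(*(v for k, v in sets.items() if k != lbl))
            if background == "other_sets"
            else all_coding
        ) - members
        a = len(members & category)
        b = len(members) - a
        c = len(other & category)
        d = len(other) - c
        p = fisher_exact_2x2(a, b, c, d) if other else np.nan
        rows.append(
            dict(set_label=lbl, category=category_name, n_genes=len(members),
                 n_in_category=a, fraction=a / len(members), fisher_p=p)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation coupling
# ---------------------------------------------------------------------------

def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """450K-style manifest TSV: probe_id, gene_id, region (TSS200/TSS1500/Body)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def assign_probe_to_tss(
    manifest: pd.DataFrame, betas: pd.DataFrame, gene_id: str
) -> str | None:
    """Representative TSS probe for a gene in one cancer type's beta matrix.

    Among TSS-region probes present in the matrix, picks the one with the
    highest mean beta across samples; ties break to the lexicographically
    smallest probe id.  Returns None when the gene has no usable TSS probe.
    """
    probes = manifest.loc[
        (manifest["gene_id"] == gene_id) & (manifest["region"].isin(TSS_REGIONS)),
        "probe_id",
    ]
    probes = sorted(set(probes) & set(betas.index))
    if not probes:
        log.info("%s: no TSS probe in methylation matrix", gene_id)
        return None
    means = betas.loc[probes].mean(axis=1)
    best = means.max()
    return min(p for p in probes if means[p] == best)


def methylation_coupling(
    pairs: pd.DataFrame,
    cpms: Mapping[str, ExpressionMatrix],
    betas: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    alpha_meth: float = 0.05,
    min_samples_for_test: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate lncRNA expression with coding-TSS methylation per cancer type.

    ``pairs`` needs columns anchor_id (coding) and partner_id (lncRNA).  For
    each (pair, cancer type) with enough matched samples, Spearman rho
    between the lncRNA's CPM and the coding gene's representative TSS-probe
    beta is computed; P values are BH-adjusted within each cancer type.

    Returns (records, flags): per-test records, and one row per pair with
    ``positively_coupled`` set when rho > 0 in a strict majority of its
    testable cancer types.
    """
    rows = []
    for cancer_type, beta in betas.items():
        if cancer_type not in cpms:
            continue
        cpm = cpms[cancer_type].data
        matched = sorted(set(cpm.columns) & set(beta.columns))
        if len(matched) < min_samples_for_test:
            log.info("%s: only %d matched samples, skipped", cancer_type, len(matched))
            continue
        for anchor_id, partner_id in pairs[["anchor_id", "partner_id"]].itertuples(index=False):
            if partner_id not in cpm.index:
                continue
            probe = assign_probe_to_tss(manifest, beta, anchor_id)
            if probe is None:
                continue
            x = cpm.loc[partner_id, matched].to_numpy(dtype=float)
            y = beta.loc[probe, matched].to_numpy(dtype=float)
            try:
                rho, p = spearman(x, y)
            except ConstantInputError:
                log.info("%s/%s in %s: constant input", anchor_id, partner_id, cancer_type)
                continue
            rows.append(
                dict(anchor_id=anchor_id, partner_id=partner_id,
                     cancer_type=cancer_type, probe_id=probe,
                     n=len(matched), rho_meth=rho, p_raw=p)
            )
    records = pd.DataFrame(
        rows, columns=["anchor_id", "partner_id", "cancer_type", "probe_id",
                       "n", "rho_meth", "p_raw"],
    )
    if not records.empty:
        records["p_adj"] = records.groupby("cancer_type", group_keys=False)[
            "p_raw"
        ].transform(lambda s: bh_adjust(s.to_numpy()))
        records["significant"] = records["p_adj"] < alpha_meth
    else:
        records["p_adj"] = []
        records["significant"] = []
    if records.empty:
        flags = pd.DataFrame(
            columns=["anchor_id", "partner_id", "n_testable", "n_pos", "n_sig",
                     "positively_coupled"]
        )
    else:
        grouped = records.assign(
            pos=records["rho_meth"] > 0
        ).groupby(["anchor_id", "partner_id"], as_index=False)
        flags = grouped.agg(
            n_testable=("cancer_type", "size"),
            n_pos=("pos", "sum"),
            n_sig=("significant", "sum"),
        )
        flags["positively_coupled"] = flags["n_pos"] > flags["n_testable"] / 2
    return records, flags


def load_beta_matrices(index_path: str | Path) -> Dict[str, pd.DataFrame]:
    """Methylation cohort index TSV (cancer_type, path) -> beta DataFrames."""
    base = Path(index_path).parent
    out: Dict[str, pd.DataFrame] = {}
    with open(index_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cancer_type, rel = line.rstrip("\n").split("\t")
            p = Path(rel)
            out[cancer_type] = pd.read_csv(
                p if p.is_absolute() else base / p, sep="\t", index_col=0
            )
    return out


# ---------------------------------------------------------------------------
# localization (RCI)
# ---------------------------------------------------------------------------

def t_test_two_sample(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> Tuple[float, float]:
    """Two-sample t-test; pooled-variance Student by default, Welch optional.

    Degenerate zero-variance groups: equal means give (0, 1); unequal means
    give an infinite statistic with P at the numeric floor.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"bad variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), P_FLOOR
    t, p = scipy.stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), max(float(p), P_FLOOR)


def read_rci(path: str | Path) -> pd.DataFrame:
    """RCI TSV: gene_id, cell_line, rci (log2 cytoplasmic/nuclear)."""
    df = pd.read_csv(path, sep="\t")
    if not np.isfinite(df["rci"]).all():
        raise ValueError(f"{path}: non-finite RCI values")
    return df


def localization_compare(
    rci: pd.DataFrame,
    lcn_ids: Iterable[str],
    lcp_ids: Iterable[str],
    background_ids: Iterable[str],
    min_group: int = 2,
) -> pd.DataFrame:
    """Per cell line: LCN median RCI and t-tests vs background and vs LCP.

    Negative RCI means nuclear enrichment, the compartment where a
    cis-acting regulator must reside.  Cell lines with fewer than
    ``min_group`` genes in a compared group are skipped for that test.
    """
    lcn_ids, lcp_ids, bg_ids = set(lcn_ids), set(lcp_ids), set(background_ids)
    rows = []
    for cell_line, g in rci.groupby("cell_line"):
        vals = g.set_index("gene_id")["rci"]
        lcn = vals[vals.index.isin(lcn_ids)].to_numpy()
        lcp = vals[vals.index.isin(lcp_ids)].to_numpy()
        bg = vals[vals.index.isin(bg_ids)].to_numpy()
        if len(lcn) < min_group:
            log.info("%s: LCN group too small, skipped", cell_line)
            continue
        row = dict(
            cell_line=cell_line,
            n_lcn=len(lcn),
            median_lcn=float(np.median(lcn)),
            median_background=float(np.median(bg)) if len(bg) else np.nan,
            median_lcp=float(np.median(lcp)) if len(lcp) else np.nan,
        )
        if len(bg) >= min_group:
            t, p = t_test_two_sample(lcn, bg)
            row.update(t_vs_background=t, p_vs_background=p)
        else:
            row.update(t_vs_background=np.nan, p_vs_background=np.nan)
        if len(lcp) >= min_group:
            t, p = t_test_two_sample(lcn, lcp)
            row.update(t_vs_lcp=t, p_vs_lcp=p)
        else:
            row.update(t_vs_lcp=np.nan, p_vs_lcp=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
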