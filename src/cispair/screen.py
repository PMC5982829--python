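"""Per-cancer Spearman screening, BH correction and cross-cancer set labels.

Each proximal pair is tested in every cancer type where both genes pass the
expression filter.  Significance uses the Benjamini-Hochberg step-up within
a (cancer type x partner class x window) family at a stringent threshold
(default corrected P < 1e-5); no cut is applied to rho itself, so weakly but
consistently correlated pairs survive.  Pairs are then aggregated across
cancer types into the four canonical sets:

* LCN / LCP - lncRNA/coding pairs negatively / positively correlated in the
  majority of testable cancer types, significant in at least one;
* CCN / CCP - the analogous coding/coding sets.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, filter_expressed
from .pairing import GenePair

log = logging.getLogger(__name__)

P_FLOOR = np.finfo(float).tiny


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho with a two-sided t-approximation P value.

    rho is the Pearson correlation of midranks.  P comes from
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom; at
    |rho| = 1 the P value is reported at the numeric floor rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise ConstantInputError("constant input vector")
    rho = float(np.clip((rxc * ryc).sum() / denom, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, P_FLOOR
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * scipy.stats.t.sf(abs(t), df=n - 2))
    return rho, max(p, P_FLOOR)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(mat, axis=1)


def screen_pairs(
    pairs: Sequence[GenePair],
    cpms: Mapping[str, ExpressionMatrix],
    alpha: float = 1e-5,
    min_cpm: float = 1.0,
    min_samples_filter: int = 3,
    min_samples_for_test: int = 10,
    bh_family: str = "per_cancer",
) -> pd.DataFrame:
    """Spearman-test every pair in every cancer type where both genes pass.

    Returns one row per (pair, cancer type): anchor_id, partner_id,
    partner_class, window_bp, cancer_type, n, rho, p_raw, p_adj.
    ``bh_family`` is ``per_cancer`` (adjust within each cancer type x
    partner class x window family) or ``global`` (one family).
    """
    if bh_family not in ("per_cancer", "global"):
        raise ValueError(f"bad bh_family {bh_family!r}")
    chunks: List[pd.DataFrame] = []
    for cancer_type, mat in cpms.items():
        if mat.data.shape[1] < min_samples_for_test:
            log.info("%s: fewer than %d samples, skipped", cancer_type, min_samples_for_test)
            continue
        retained = set(filter_expressed(mat, min_cpm=min_cpm, min_samples=min_samples_filter))
        testable = [
            p for p in pairs if p.anchor_id in retained and p.partner_id in retained
        ]
        if not testable:
            log.info("%s: no testable pairs", cancer_type)
            continue
        gene_ids = sorted({p.anchor_id for p in testable} | {p.partner_id for p in testable})
        sub = mat.data.loc[gene_ids].to_numpy(dtype=float)
        ranks = _rank_rows(sub)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks**2).sum(axis=1))
        idx = {g: i for i, g in enumerate(gene_ids)}
        ai = np.array([idx[p.anchor_id] for p in testable])
        pi = np.array([idx[p.partner_id] for p in testable])
        denom = norms[ai] * norms[pi]
        ok = denom > 0
        n_const = int((~ok).sum())
        if n_const:
            log.info("%s: %d pair(s) skipped (constant expression)", cancer_type, n_const)
        rho = np.full(len(testable), np.nan)
        rho[ok] = (ranks[ai[ok]] * ranks[pi[ok]]).sum(axis=1) / denom[ok]
        rho = np.clip(rho, -1.0, 1.0)
        n = sub.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p_raw = 2 * scipy.stats.t.sf(np.abs(t), df=n - 2)
        p_raw = np.where(np.abs(rho) == 1.0, P_FLOOR, p_raw)
        p_raw = np.maximum(p_raw, P_FLOOR)
        chunk = pd.DataFrame(
            {
                "anchor_id": [p.anchor_id for p in testable],
                "partner_id": [p.partner_id for p in testable],
                "partner_class": [p.partner_class for p in testable],
                "window_bp": [p.window_bp for p in testable],
                "cancer_type": cancer_type,
                "n": n,
                "rho": rho,
                "p_raw": p_raw,
            }
        )
        chunks.append(chunk[ok])
    if not chunks:
        return pd.DataFrame(
            columns=[
                "anchor_id", "partner_id", "partner_class", "window_bp",
                "cancer_type", "n", "rho", "p_raw", "p_adj",
            ]
        )
    records = pd.concat(chunks, ignore_index=True)
    if bh_family == "per_cancer":
        keys = ["cancer_type", "partner_class", "window_bp"]
    else:
        keys = ["partner_class", "window_bp"]
    records["p_adj"] = (
        records.groupby(keys, group_keys=False)["p_raw"].transform(lambda s: bh_adjust(s.to_numpy()))
    )
    return records


def summarize_and_label(
    records: pd.DataFrame,
    alpha: float = 1e-5,
    window_bp: int | None = None,
    majority: str = "testable",
    n_cancer_types: int | None = None,
) -> pd.DataFrame:
    """Aggregate per-cancer records into per-pair summaries with set labels.

    A pair is labelled LCN (lncRNA partner) or CCN (coding partner) when its
    rho is negative in a strict majority of cancer types and at least one
    negative correlation is significant (adjusted P < alpha); LCP / CCP are
    the positive mirror.  Significant correlations of the opposite sign do
    not veto membership.  ``majority='testable'`` takes the majority over
    cancer types where the pair was testable; ``'all'`` over all cancer
    types in the cohort (``n_cancer_types`` required).
    """
    if majority not in ("testable", "all"):
        raise ValueError(f"bad majority mode {majority!r}")
    if majority == "all" and n_cancer_types is None:
        raise ValueError("majority='all' requires n_cancer_types")
    if records.empty:
        return pd.DataFrame(
            columns=[
                "anchor_id", "partner_id", "partner_class", "n_testable",
                "n_neg_rho", "n_pos_rho", "n_sig_neg", "n_sig_pos", "set_label",
            ]
        )
    recs = records
    if window_bp is None:
        window_bp = int(recs["window_bp"].max())
    recs = recs[recs["window_bp"] == window_bp]
    sig = recs["p_adj"] < alpha
    grouped = recs.assign(
        neg=(recs["rho"] < 0),
        pos=(recs["rho"] > 0),
        sig_neg=((recs["rho"] < 0) & sig),
        sig_pos=((recs["rho"] > 0) & sig),
    ).groupby(["anchor_id", "partner_id", "partner_class"], as_index=False)
    out = grouped.agg(
        n_testable=("cancer_type", "size"),
        n_neg_rho=("neg", "sum"),
        n_pos_rho=("pos", "sum"),
        n_sig_neg=("sig_neg", "sum"),
        n_sig_pos=("sig_pos", "sum"),
    )
    denom = out["n_testable"] if majority == "testable" else n_cancer_types
    neg_major = out["n_neg_rho"] > denom / 2
    pos_major = out["n_pos_rho"] > denom / 2
    is_lnc = out["partner_class"] == "lncRNA"
    label = np.full(len(out), "none", dtype=object)
    label[neg_major & (out["n_sig_neg"] >= 1) & is_lnc] = "LCN"
    label[neg_major & (out["n_sig_neg"] >= 1) & ~is_lnc] = "CCN"
    label[pos_major & (out["n_sig_pos"] >= 1) & is_lnc] = "LCP"
    label[pos_major & (out["n_sig_pos"] >= 1) & ~is_lnc] = "CCP"
    out["set_label"] = label
    return out.sort_values(["anchor_id", "partner_id"]).reset_index(drop=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def pair_class_enrichment(
    lc_records: pd.DataFrame,
    cc_records: pd.DataFrame,
    alpha: float = 1e-5,
    enrich_p: float = 0.01,
) -> pd.DataFrame:
    """Per (cancer type, window): significant fractions of LC vs CC pairs.

    The enriched flag is set when the lncRNA/coding significant fraction
    exceeds the coding/coding one with two-sided Fisher P < ``enrich_p``.
    """
    strata = sorted(
        set(map(tuple, lc_records[["cancer_type", "window_bp"]].drop_duplicates().to_numpy()))
        | set(map(tuple, cc_records[["cancer_type", "window_bp"]].drop_duplicates().to_numpy()))
    )
    rows = []
    for cancer_type, window_bp in strata:
        lc = lc_records[
            (lc_records["cancer_type"] == cancer_type) & (lc_records["window_bp"] == window_bp)
        ]
        cc = cc_records[
            (cc_records["cancer_type"] == cancer_type) & (cc_records["window_bp"] == window_bp)
        ]
        lc_sig = int((lc["p_adj"] < alpha).sum())
        cc_sig = int((cc["p_adj"] < alpha).sum())
        lc_frac = lc_sig / len(lc) if len(lc) else np.nan
        cc_frac = cc_sig / len(cc) if len(cc) else np.nan
        if len(lc) and len(cc):
            p = fisher_exact_2x2(lc_sig, len(lc) - lc_sig, cc_sig, len(cc) - cc_sig)
        else:
            p = np.nan
        enriched = bool(
            len(lc) and len(cc) and p < enrich_p and lc_frac > cc_frac
        )
        rows.append(
            dict(
                cancer_type=cancer_type,
                window_bp=window_bp,
                n_lc=len(lc),
                lc_sig=lc_sig,
                lc_frac=lc_frac,
                n_cc=len(cc),
                cc_sig=cc_sig,
                cc_frac=cc_frac,
                fisher_p=p,
                enriched=enriched,
            )
        )
    return pd.DataFrame(rows)
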