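"""End-to-end orchestration: annotate -> pair -> screen -> characterize -> report.

``run_all`` drives the full screen from a single :class:`PipelineConfig` and
writes plain-TSV/JSON outputs only, so reruns with an identical config (and
seed) are byte-identical and trivially diffable.  ``evaluate_recovery``
compares a result set against a synthetic truth manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GeneRecord, read_chrom_sizes, read_gtf
from .characterize import (
    ScoreTrack,
    category_enrichment,
    conservation_table,
    load_beta_matrices,
    localization_compare,
    methylation_coupling,
    read_probe_manifest,
    read_rci,
    tau_table,
)
from .expression import cpm_normalize, load_cohort, mean_profiles
from .pairing import (
    build_window_pairs,
    colocation_fraction,
    flag_apa_candidates,
    pairs_to_frame,
    shuffle_within_chromosome,
)
from .screen import pair_class_enrichment, screen_pairs, summarize_and_label
from .simulate import TruthManifest

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full screen run."""

    gtf: str
    chrom_sizes: str
    cohort_index: str
    conservation: Optional[str] = None
    meth_index: Optional[str] = None
    probe_manifest: Optional[str] = None
    rci: Optional[str] = None
    categories: Dict[str, str] = field(default_factory=dict)
    windows: List[int] = field(default_factory=lambda: [25_000, 50_000, 100_000])
    apa_gap: int = 5000
    apa_side: str = "both"
    alpha: float = 1e-5
    enrich_p: float = 0.01
    alpha_meth: float = 0.05
    majority: str = "testable"
    tau_log: bool = True
    min_cpm: float = 1.0
    min_samples_filter: int = 3
    min_samples_for_test: int = 10
    bh_family: str = "per_cancer"
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.windows) != sorted(set(self.windows)):
            raise ValueError("windows must be strictly increasing")
        for name in ("alpha", "enrich_p", "alpha_meth"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _check_inputs(config: PipelineConfig) -> None:
    required = [config.gtf, config.chrom_sizes, config.cohort_index]
    optional = [config.conservation, config.meth_index, config.probe_manifest, config.rci]
    optional += list(config.categories.values())
    for p in required + [p for p in optional if p]:
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")


def run_all(config: PipelineConfig, outdir: str | Path) -> Dict[str, Path]:
    """Run every stage and write all result tables under ``outdir``.

    Stage completion markers are written to ``<outdir>/.stages/`` so a
    partially written result directory is always identifiable.
    """
    _check_inputs(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = out / ".stages"
    stages.mkdir(exist_ok=True)
    for old in stages.glob("*.done"):
        old.unlink()
    paths: Dict[str, Path] = {}
    counts_log: Dict[str, int] = {}

    def mark(stage: str) -> None:
        (stages / f"{stage}.done").write_text("ok\n")
        log.info("stage %s done", stage)

    # --- annotation
    genes = read_gtf(config.gtf)
    sizes = read_chrom_sizes(config.chrom_sizes)
    sizes.validate_genes(genes)
    coding = [g for g in genes if g.biotype == "coding"]
    lncs = [g for g in genes if g.biotype == "lncRNA"]
    counts_log["genes_coding"] = len(coding)
    counts_log["genes_lncRNA"] = len(lncs)
    mark("annotation")

    # --- APA filter
    flags = flag_apa_candidates(coding, lncs, apa_gap=config.apa_gap, side=config.apa_side)
    flagged = {f.lnc_id for f in flags}
    lncs_kept = [g for g in lncs if g.gene_id not in flagged]
    counts_log["apa_flagged"] = len(flags)
    counts_log["lncRNA_kept"] = len(lncs_kept)
    paths["apa_flags"] = out / "apa_flags.tsv"
    _write_tsv(
        pd.DataFrame(
            [(f.lnc_id, f.coding_id, f.gap_bp) for f in flags],
            columns=["lnc_id", "coding_id", "gap_bp"],
        ).sort_values("lnc_id"),
        paths["apa_flags"],
    )
    mark("apa_filter")

    # --- pairing
    lc_pairs, cc_pairs = [], []
    for w in config.windows:
        lc_pairs.extend(build_window_pairs(coding, lncs_kept, w, partner_class="lncRNA"))
        cc_pairs.extend(
            build_window_pairs(coding, coding, w, partner_class="coding",
                               dedupe_unordered=True)
        )
    counts_log["lc_pairs"] = len(lc_pairs)
    counts_log["cc_pairs"] = len(cc_pairs)
    paths["pairs"] = out / "pairs.tsv"
    _write_tsv(
        pd.concat([pairs_to_frame(lc_pairs), pairs_to_frame(cc_pairs)], ignore_index=True)
        .sort_values(["partner_class", "window_bp", "anchor_id", "partner_id"]),
        paths["pairs"],
    )
    mark("pairing")

    # --- shuffle null (proximity only)
    if config.shuffle:
        shuffled = shuffle_within_chromosome(coding + lncs_kept, sizes, config.seed)
        sh_coding = [g for g in shuffled if g.biotype == "coding"]
        sh_lncs = [g for g in shuffled if g.biotype == "lncRNA"]
        rows = []
        for w in config.windows:
            rows.append(
                dict(
                    window_bp=w,
                    real_fraction=colocation_fraction(lncs_kept, coding, w),
                    shuffled_fraction=colocation_fraction(sh_lncs, sh_coding, w),
                )
            )
        paths["shuffle_colocation"] = out / "shuffle_colocation.tsv"
        _write_tsv(pd.DataFrame(rows), paths["shuffle_colocation"])
    mark("shuffle_null")

    # --- expression
    cpms = {ct: cpm_normalize(m) for ct, m in load_cohort(config.cohort_index).items()}
    counts_log["cancer_types"] = len(cpms)
    mark("expression")

    # --- correlation screen
    screen_kw = dict(
        alpha=config.alpha,
        min_cpm=config.min_cpm,
        min_samples_filter=config.min_samples_filter,
        min_samples_for_test=config.min_samples_for_test,
        bh_family=config.bh_family,
    )
    lc_records = screen_pairs(lc_pairs, cpms, **screen_kw)
    cc_records = screen_pairs(cc_pairs, cpms, **screen_kw)
    counts_log["lc_records"] = len(lc_records)
    counts_log["cc_records"] = len(cc_records)
    paths["records_lc"] = out / "records_lc.tsv"
    paths["records_cc"] = out / "records_cc.tsv"
    sort_cols = ["cancer_type", "window_bp", "anchor_id", "partner_id"]
    _write_tsv(lc_records.sort_values(sort_cols), paths["records_lc"])
    _write_tsv(cc_records.sort_values(sort_cols), paths["records_cc"])
    mark("screen")

    # --- set labels
    n_types = len(cpms)
    summaries = pd.concat(
        [
            summarize_and_label(lc_records, alpha=config.alpha,
                                majority=config.majority, n_cancer_types=n_types),
            summarize_and_label(cc_records, alpha=config.alpha,
                                majority=config.majority, n_cancer_types=n_types),
        ],
        ignore_index=True,
    )
    for lbl in ("LCN", "LCP", "CCN", "CCP"):
        counts_log[f"set_{lbl}"] = int((summaries["set_label"] == lbl).sum())
    mark("labels")

    # --- per-stratum LC-vs-CC enrichment
    enrichment = pair_class_enrichment(
        lc_records, cc_records, alpha=config.alpha, enrich_p=config.enrich_p
    )
    paths["enrichment"] = out / "enrichment.tsv"
    _write_tsv(enrichment, paths["enrichment"])
    mark("enrichment")

    # --- tau specificity
    profiles = mean_profiles(cpms)
    taus = tau_table(profiles, log_transform=config.tau_log)
    paths["tau"] = out / "tau.tsv"
    _write_tsv(
        taus.rename_axis("gene_id").reset_index().sort_values("gene_id"), paths["tau"]
    )
    summaries["TauC"] = summaries["anchor_id"].map(taus)
    summaries["TauL"] = summaries["partner_id"].map(taus)
    mark("tau")

    # --- conservation
    if config.conservation:
        track = (
            ScoreTrack.from_bigwig(config.conservation)
            if str(config.conservation).endswith((".bw", ".bigwig"))
            else ScoreTrack.from_bedgraph(config.conservation)
        )
        cons = conservation_table(genes, track)
        paths["conservation"] = out / "conservation.tsv"
        _write_tsv(cons.sort_values("gene_id"), paths["conservation"])
        cons_by_gene = cons.set_index("gene_id")["mean_score"]
        summaries["PhastconC"] = summaries["anchor_id"].map(cons_by_gene)
        summaries["PhastconL"] = summaries["partner_id"].map(cons_by_gene)
    mark("conservation")

    # --- gene-category enrichment
    if config.categories:
        cat_tables = []
        for name, path in sorted(config.categories.items()):
            members = [
                line.strip() for line in Path(path).read_text().splitlines() if line.strip()
            ]
            cat_tables.append(
                category_enrichment(summaries, members, category_name=name)
            )
        paths["category_enrichment"] = out / "category_enrichment.tsv"
        _write_tsv(pd.concat(cat_tables, ignore_index=True), paths["category_enrichment"])
    mark("categories")

    # --- localization
    if config.rci:
        rci = read_rci(config.rci)
        lcn_ids = set(summaries.loc[summaries["set_label"] == "LCN", "partner_id"])
        lcp_ids = set(summaries.loc[summaries["set_label"] == "LCP", "partner_id"])
        background = {g.gene_id for g in lncs_kept}
        loc = localization_compare(rci, lcn_ids, lcp_ids, background)
        paths["localization"] = out / "localization.tsv"
        _write_tsv(loc, paths["localization"])
    mark("localization")

    # --- methylation coupling on the LCN set
    if config.meth_index and config.probe_manifest:
        betas = load_beta_matrices(config.meth_index)
        manifest = read_probe_manifest(config.probe_manifest)
        lcn_pairs = summaries.loc[
            summaries["set_label"] == "LCN", ["anchor_id", "partner_id"]
        ]
        meth_records, meth_flags = methylation_coupling(
            lcn_pairs, cpms, betas, manifest,
            alpha_meth=config.alpha_meth,
            min_samples_for_test=config.min_samples_for_test,
        )
        paths["methylation_records"] = out / "methylation_records.tsv"
        paths["methylation_flags"] = out / "methylation_flags.tsv"
        _write_tsv(meth_records, paths["methylation_records"])
        _write_tsv(meth_flags, paths["methylation_flags"])
        if not meth_flags.empty:
            coupled = meth_flags.set_index(["anchor_id", "partner_id"])["positively_coupled"]
            summaries["positively_coupled"] = [
                bool(coupled.get((a, p), False))
                for a, p in summaries[["anchor_id", "partner_id"]].itertuples(index=False)
            ]
    mark("methylation")

    paths["summaries"] = out / "summaries.tsv"
    _write_tsv(summaries, paths["summaries"])

    manifest_payload = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "counts": counts_log,
    }
    paths["run_manifest"] = out / "run_manifest.json"
    with open(paths["run_manifest"], "w") as fh:
        json.dump(manifest_payload, fh, indent=1, sort_keys=True)
    mark("report")
    return paths


# ---------------------------------------------------------------------------
# recovery evaluation against a truth manifest
# ---------------------------------------------------------------------------

def evaluate_recovery(
    summaries: pd.DataFrame,
    truth: TruthManifest,
    meth_flags: Optional[pd.DataFrame] = None,
) -> Dict:
    """Sensitivity / false-discovery proportion of the LCN call set.

    Sensitivity counts planted (mediated) repressor pairs labelled LCN among
    those testable (present in the summaries); FDP is the fraction of LCN
    pairs that were not planted repressors (None when LCN is empty).  A
    per-class confusion table maps each planted class to its label counts.
    Planted pairs whose genes never appear in the summaries at all raise an
    error listing the unmatched ids.
    """
    known = set(summaries["anchor_id"]) | set(summaries["partner_id"])
    truth_genes = {g for p in truth.pairs for g in (p.anchor_id, p.partner_id)}
    unmatched = sorted(g for g in truth_genes if g not in known)
    # genes can legitimately be absent when a pair was never testable; only a
    # fully disjoint truth indicates an id mismatch
    if truth.pairs and len(unmatched) == len(truth_genes):
        raise ValueError(f"truth/result id mismatch, e.g. {unmatched[:5]}")

    labels = summaries.set_index(["anchor_id", "partner_id"])["set_label"]
    confusion: Dict[str, Dict[str, int]] = {}
    for p in truth.pairs:
        lbl = labels.get((p.anchor_id, p.partner_id), "untested")
        confusion.setdefault(p.pair_class, {}).setdefault(lbl, 0)
        confusion[p.pair_class][lbl] += 1

    repressors = truth.pairs_of_class("repressor", "mediated_repressor")
    testable = [
        p for p in repressors if (p.anchor_id, p.partner_id) in labels.index
    ]
    n_hit = sum(
        1 for p in testable if labels.get((p.anchor_id, p.partner_id)) == "LCN"
    )
    sensitivity = n_hit / len(testable) if testable else float("nan")

    lcn = summaries.loc[summaries["set_label"] == "LCN", ["anchor_id", "partner_id"]]
    planted_keys = {(p.anchor_id, p.partner_id) for p in repressors}
    n_lcn = len(lcn)
    n_false = sum(
        1 for a, p in lcn.itertuples(index=False) if (a, p) not in planted_keys
    )
    fdp = n_false / n_lcn if n_lcn else None

    result = {
        "n_planted_repressors": len(repressors),
        "n_testable_repressors": len(testable),
        "n_lcn": n_lcn,
        "sensitivity": sensitivity,
        "fdp": fdp,
        "confusion": confusion,
    }
    if meth_flags is not None and not meth_flags.empty:
        mediated = {
            (p.anchor_id, p.partner_id)
            for p in truth.pairs_of_class("mediated_repressor")
        }
        flags = meth_flags.set_index(["anchor_id", "partner_id"])["positively_coupled"]
        tested = [k for k in mediated if k in flags.index]
        result["n_mediated_tested"] = len(tested)
        result["meth_sensitivity"] = (
            sum(bool(flags[k]) for k in tested) / len(tested) if tested else float("nan")
        )
    return result
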