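"""Synthetic miniature cohort with planted cis-regulatory structure.

Generates every input the pipeline consumes — annotation, chromosome sizes,
per-cancer-type count matrices, methylation beta matrices with a probe
manifest, a conservation track, an RCI table and gene-category lists —
together with a ground-truth manifest of the planted pair classes:

* ``shared_domain_positive`` — both genes driven by a common per-sample
  latent factor, emulating co-activation within a chromatin domain;
* ``repressor`` — a lncRNA whose latent activity up-regulates itself and
  down-regulates the paired coding gene (negative rank correlation);
* ``mediated_repressor`` — a repressor whose latent activity additionally
  raises methylation at the coding gene's TSS probe;
* ``independent`` — a proximal pair with no coupling (negative control).

Counts are negative-binomial with log-normal library sizes; methylation
betas are logistic-transformed Gaussians, so all values lie strictly in
(0, 1).  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    ChromSizes,
    GeneRecord,
    Interval,
    merge_intervals,
    write_chrom_sizes,
    write_gtf,
)
from .characterize import ScoreTrack
from .expression import ExpressionMatrix

PAIR_CLASSES = ("shared_domain_positive", "repressor", "mediated_repressor", "independent")

#: Log-scale latent gain producing a population Spearman of about -0.5
#: between the repressor lncRNA and its coding target at the default
#: negative-binomial dispersion (see the calibration fixture in the tests).
DEFAULT_REPRESSOR_GAMMA = 0.53


@dataclass
class SimConfig:
    """Desk-scale cohort defaults: 3 x 10 Mb chromosomes, 300 + 300 genes,
    4 cancer types x 200 samples."""

    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    n_coding: int = 300
    n_lnc: int = 300
    n_cancer_types: int = 4
    samples_per_type: int = 200
    nb_dispersion: float = 0.2
    lib_log_mean: float = float(np.log(1e6))
    lib_log_sd: float = 0.3
    n_repressor: int = 40
    frac_mediated: float = 0.5
    n_shared: int = 60
    n_independent: int = 60
    n_apa_decoys: int = 20
    repressor_gamma: float = DEFAULT_REPRESSOR_GAMMA
    shared_strength: float = 0.5
    meth_delta: float = 1.0
    meth_noise_sd: float = 0.5
    n_single_cancer: int = 30
    single_cancer_boost: float = 6.5
    rci_shift: float = -1.2
    rci_sd: float = 1.0
    n_cell_lines: int = 15
    cons_high_mean: float = 0.8
    cons_low_mean: float = 0.05
    cons_background: float = 0.02
    frac_high_cons_repressor_lnc: float = 0.2
    apa_gap: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_coding", "n_lnc",
            "n_cancer_types", "samples_per_type",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_planted = self.n_repressor + self.n_shared + self.n_independent
        if n_planted + self.n_apa_decoys > self.n_lnc:
            raise ValueError("more planted lncRNAs than n_lnc")
        if n_planted > self.n_coding:
            raise ValueError("more planted anchors than coding genes")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PlantedPair:
    anchor_id: str
    partner_id: str
    pair_class: str
    effect: float  # target population Spearman (sign carries direction)
    meth_coupling: float  # methylation coupling strength (0 = none)
    orientation: str
    distance_bp: int


@dataclass
class GeneTruth:
    specificity: str = "ubiquitous"  # or "single_cancer"
    specific_type: Optional[str] = None
    conservation: str = "low"  # or "high"
    localization_shift: float = 0.0


@dataclass
class TruthManifest:
    """Planted structure of a synthetic cohort, for downstream evaluation."""

    pairs: List[PlantedPair] = field(default_factory=list)
    genes: Dict[str, GeneTruth] = field(default_factory=dict)
    apa_decoys: List[str] = field(default_factory=list)
    cancer_types: List[str] = field(default_factory=list)

    def pairs_of_class(self, *classes: str) -> List[PlantedPair]:
        return [p for p in self.pairs if p.pair_class in classes]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [dataclasses.asdict(p) for p in self.pairs],
            "genes": {g: dataclasses.asdict(t) for g, t in sorted(self.genes.items())},
            "apa_decoys": self.apa_decoys,
            "cancer_types": self.cancer_types,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pairs=[PlantedPair(**p) for p in payload["pairs"]],
            genes={g: GeneTruth(**t) for g, t in payload["genes"].items()},
            apa_decoys=payload["apa_decoys"],
            cancer_types=payload["cancer_types"],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _make_exons(start: int, end: int, n_exons: int, rng: np.random.Generator) -> List[Interval]:
    """Partition [start, end) into n_exons exons anchored at both gene ends."""
    length = end - start
    if n_exons == 1 or length < 4 * n_exons:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = [0, *cuts.tolist(), length]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = bounds[i], bounds[i + 1]
        if e > s:
            exons.append((start + s, start + e))
    return exons or [(start, end)]


def _same_strand_clear(
    span: Tuple[int, int], strand: str, chrom: str,
    coding: Sequence[GeneRecord], min_gap: int,
) -> bool:
    """True when no same-strand coding gene lies within min_gap of the span."""
    s, e = span
    for g in coding:
        if g.chrom != chrom or g.strand != strand:
            continue
        gap = 0 if (g.start < e and s < g.end) else (s - g.end if s >= g.end else g.start - e)
        if gap <= min_gap:
            return False
    return True


def _place_partner(
    anchor: GeneRecord,
    orientation: str,
    gap: int,
    length: int,
    chrom_len: int,
) -> Optional[Tuple[int, int, str]]:
    """(start, end, strand) of a partner at a given orientation/gap, or None."""
    opp = "-" if anchor.strand == "+" else "+"
    if orientation == "antisense_overlap":
        start = anchor.start + (anchor.length - length) // 2
        start = max(0, min(start, chrom_len - length))
        return (start, start + length, opp)
    left_of_anchor = {
        "divergent": anchor.strand == "+",
        "convergent": anchor.strand == "-",
        "sense_upstream": anchor.strand == "+",
        "sense_downstream": anchor.strand == "-",
    }[orientation]
    strand = anchor.strand if orientation.startswith("sense") else opp
    if left_of_anchor:
        end = anchor.start - gap
        start = end - length
    else:
        start = anchor.end + gap
        end = start + length
    if start < 0 or end > chrom_len:
        return None
    return (start, end, strand)


_PLANT_ORIENTATIONS = (
    "antisense_overlap", "divergent", "convergent", "sense_upstream", "sense_downstream",
)
_PLANT_WEIGHTS = (0.3, 0.2, 0.15, 0.15, 0.2)


def _draw_gap(orientation: str, stratum: str, rng: np.random.Generator) -> int:
    """Boundary gap consistent with the orientation class and window stratum."""
    if orientation == "antisense_overlap":
        return 0
    lo_by_stratum = {"w25": 0, "w50": 25_001, "w100": 50_001, "far": 101_000}
    hi_by_stratum = {"w25": 24_000, "w50": 49_000, "w100": 99_000, "far": 110_000}
    lo, hi = lo_by_stratum[stratum], hi_by_stratum[stratum]
    if orientation == "divergent" and stratum == "w25":
        return int(rng.integers(200, 1000))  # promoters head-to-head
    if orientation.startswith("sense"):
        lo = max(lo, 6000)  # clear of the APA gap
    else:
        lo = max(lo, 1000)
    return int(rng.integers(lo, max(hi, lo + 1)))


def generate_genome(config: SimConfig) -> Tuple[List[GeneRecord], ChromSizes, TruthManifest]:
    """Place coding genes on a slot grid and plant lncRNA partners around them.

    Coding genes never overlap each other.  Planted partners are drawn over
    the orientation classes with distances spread across the window strata
    (mostly < 25 kb); independent-class partners include a tranche just
    outside 100 kb as out-of-window negative controls.  Same-strand
    placements keep a clear margin beyond the APA gap; a configured number
    of APA decoys is placed inside it on purpose.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = ChromSizes({c: config.chrom_length for c in chroms})

    # --- coding genes on a slot grid (non-overlapping by construction)
    coding: List[GeneRecord] = []
    per_chrom = int(np.ceil(config.n_coding / config.n_chromosomes))
    slot = config.chrom_length // per_chrom
    idx = 0
    for chrom in chroms:
        for k in range(per_chrom):
            if idx >= config.n_coding:
                break
            length = int(rng.integers(2000, min(20001, slot // 4)))
            offset = int(rng.integers(5000, slot - length - 5000))
            start = min(k * slot + offset, config.chrom_length - length)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"CG{idx:04d}"
            exons = _make_exons(start, start + length, int(rng.integers(1, 6)), rng)
            coding.append(
                GeneRecord(gene_id, chrom, start, start + length, strand, "coding", exons)
            )
            idx += 1
    truth = TruthManifest(
        cancer_types=[f"CT{i + 1}" for i in range(config.n_cancer_types)]
    )
    for g in coding:
        truth.genes[g.gene_id] = GeneTruth(conservation="high")

    # --- planted pairs
    n_mediated = int(round(config.n_repressor * config.frac_mediated))
    classes = (
        ["mediated_repressor"] * n_mediated
        + ["repressor"] * (config.n_repressor - n_mediated)
        + ["shared_domain_positive"] * config.n_shared
        + ["independent"] * config.n_independent
    )
    anchor_order = rng.permutation(len(coding))
    lncs: List[GeneRecord] = []
    lnc_idx = 0
    n_far = min(10, config.n_independent)  # independent controls beyond 100 kb
    far_left = n_far
    for pos, pair_class in enumerate(classes):
        anchor = coding[int(anchor_order[pos])]
        placed = None
        for _attempt in range(200):
            orientation = str(rng.choice(_PLANT_ORIENTATIONS, p=_PLANT_WEIGHTS))
            if pair_class == "independent" and far_left > 0:
                stratum = "far"
                if orientation == "antisense_overlap":
                    continue
            else:
                stratum = str(rng.choice(["w25", "w50", "w100"], p=[0.7, 0.2, 0.1]))
            gap = _draw_gap(orientation, stratum, rng)
            length = int(rng.integers(500, 5001))
            spot = _place_partner(anchor, orientation, gap, length, config.chrom_length)
            if spot is None:
                continue
            start, end, strand = spot
            # keep the placement out of APA range of every coding gene, and
            # off other coding spans for same-strand partners
            if not _same_strand_clear((start, end), strand, anchor.chrom, coding,
                                      config.apa_gap + 500):
                continue
            placed = (start, end, strand, orientation, gap, stratum)
            break
        if placed is None:
            raise RuntimeError(f"could not place partner for {anchor.gene_id}")
        start, end, strand, orientation, gap, stratum = placed
        if stratum == "far":
            far_left -= 1
        gene_id = f"LNC{lnc_idx:04d}"
        lnc_idx += 1
        exons = _make_exons(start, end, int(rng.integers(1, 4)), rng)
        lncs.append(GeneRecord(gene_id, anchor.chrom, start, end, strand, "lncRNA", exons))
        effect = 0.0
        meth = 0.0
        if pair_class in ("repressor", "mediated_repressor"):
            effect = -0.5
            if pair_class == "mediated_repressor":
                meth = config.meth_delta
        elif pair_class == "shared_domain_positive":
            effect = 0.5
        truth.pairs.append(
            PlantedPair(anchor.gene_id, gene_id, pair_class, effect, meth,
                        orientation, 0 if orientation == "antisense_overlap" else gap)
        )
        high_cons = (
            pair_class in ("repressor", "mediated_repressor")
            and rng.random() < config.frac_high_cons_repressor_lnc
        )
        shift = config.rci_shift if pair_class in ("repressor", "mediated_repressor") else 0.0
        truth.genes[gene_id] = GeneTruth(
            conservation="high" if high_cons else "low", localization_shift=shift
        )

    # --- APA decoys: same-strand lncRNAs right past a coding gene's 3' end
    decoy_hosts = rng.permutation(len(coding))[: config.n_apa_decoys]
    for host_i in decoy_hosts:
        host = coding[int(host_i)]
        for _attempt in range(100):
            gap = int(rng.integers(0, 4500))
            length = int(rng.integers(500, 3001))
            spot = _place_partner(host, "sense_downstream", gap, length, config.chrom_length)
            if spot is None:
                continue
            start, end, strand = spot
            if start < 0 or end > config.chrom_length:
                continue
            break
        else:
            raise RuntimeError(f"could not place APA decoy near {host.gene_id}")
        gene_id = f"LNC{lnc_idx:04d}"
        lnc_idx += 1
        lncs.append(
            GeneRecord(gene_id, host.chrom, start, end, strand, "lncRNA",
                       _make_exons(start, end, 1, rng))
        )
        truth.apa_decoys.append(gene_id)
        truth.genes[gene_id] = GeneTruth()

    # --- background lncRNAs anywhere APA-safe
    while lnc_idx < config.n_lnc:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(500, 5001))
        start = int(rng.integers(0, config.chrom_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        if not _same_strand_clear((start, start + length), strand, chrom, coding,
                                  config.apa_gap + 500):
            continue
        gene_id = f"LNC{lnc_idx:04d}"
        lnc_idx += 1
        lncs.append(
            GeneRecord(gene_id, chrom, start, start + length, strand, "lncRNA",
                       _make_exons(start, start + length, int(rng.integers(1, 4)), rng))
        )
        truth.genes[gene_id] = GeneTruth()

    # --- single-cancer-specific genes among unplanted genes
    planted_ids = {p.anchor_id for p in truth.pairs} | {p.partner_id for p in truth.pairs}
    free = [g.gene_id for g in coding + lncs
            if g.gene_id not in planted_ids and g.gene_id not in truth.apa_decoys]
    chosen = rng.permutation(len(free))[: config.n_single_cancer]
    for i in chosen:
        gid = free[int(i)]
        truth.genes[gid].specificity = "single_cancer"
        truth.genes[gid].specific_type = truth.cancer_types[
            int(rng.integers(0, config.n_cancer_types))
        ]

    genes = coding + lncs
    sizes.validate_genes(genes)
    return genes, sizes, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression(
    genes: Sequence[GeneRecord],
    truth: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[Dict[str, ExpressionMatrix], Dict[str, Dict[str, np.ndarray]]]:
    """Per-cancer raw count matrices plus the per-pair latent activities.

    The returned latents map cancer_type -> {pair_key: z-vector}; the same
    z drives methylation for mediated pairs, so callers pass them on to
    :func:`generate_methylation`.
    """
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    gi = {g: i for i, g in enumerate(gene_ids)}

    base_cpm = np.empty(n_genes)
    for i, g in enumerate(genes):
        scale = 80.0 if g.biotype == "coding" else 15.0
        base_cpm[i] = scale * float(np.exp(rng.normal(0.0, 0.8)))
    planted_ids = {p.anchor_id for p in truth.pairs if p.pair_class != "independent"}
    planted_ids |= {p.partner_id for p in truth.pairs if p.pair_class != "independent"}
    for g in planted_ids:
        base_cpm[gi[g]] = max(base_cpm[gi[g]], 8.0)  # planted genes pass the cpm filter

    counts: Dict[str, ExpressionMatrix] = {}
    latents: Dict[str, Dict[str, np.ndarray]] = {}
    for ct in truth.cancer_types:
        n = config.samples_per_type
        samples = [f"{ct}-S{j:04d}" for j in range(n)]
        lib = np.exp(rng.normal(config.lib_log_mean, config.lib_log_sd, size=n))
        log_rate = np.tile(np.log(base_cpm)[:, None], (1, n))
        for gid, gt in truth.genes.items():
            if gt.specificity == "single_cancer" and gid in gi:
                if gt.specific_type == ct:
                    log_rate[gi[gid]] += config.single_cancer_boost
                else:
                    log_rate[gi[gid]] = np.log(0.1)
        ct_latents: Dict[str, np.ndarray] = {}
        for p in truth.pairs:
            key = f"{p.anchor_id}:{p.partner_id}"
            z = rng.normal(0.0, 1.0, size=n)
            ct_latents[key] = z
            if p.pair_class in ("repressor", "mediated_repressor"):
                g = config.repressor_gamma
                log_rate[gi[p.anchor_id]] -= g * z
                log_rate[gi[p.partner_id]] += g * z
            elif p.pair_class == "shared_domain_positive":
                a = config.shared_strength
                log_rate[gi[p.anchor_id]] += a * z
                log_rate[gi[p.partner_id]] += a * z
        mu = np.exp(log_rate) * (lib / 1e6)[None, :]
        mat = _nb_draw(rng, mu, config.nb_dispersion)
        counts[ct] = ExpressionMatrix(
            cancer_type=ct,
            data=pd.DataFrame(mat, index=gene_ids, columns=samples),
            unit="raw_counts",
        )
        latents[ct] = ct_latents
    return counts, latents


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_methylation(
    genes: Sequence[GeneRecord],
    truth: TruthManifest,
    config: SimConfig,
    latents: Dict[str, Dict[str, np.ndarray]],
    counts: Dict[str, ExpressionMatrix],
    rng: np.random.Generator,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Beta matrices per cancer type plus a probe manifest.

    Every coding gene gets 1-3 TSS probes and one gene-body probe.  For
    mediated_repressor pairs the coding TSS probes track the pair's latent
    activity (beta rises with lncRNA expression); all other probes are
    logistic noise around a probe-specific baseline.  A random ~10% of
    samples per cancer type lack methylation, exercising sample matching.
    """
    mediated = {p.anchor_id: p for p in truth.pairs if p.pair_class == "mediated_repressor"}
    manifest_rows = []
    probe_info: List[Tuple[str, str, bool]] = []  # probe_id, gene_id, is_tss
    pid = 0
    for g in genes:
        if g.biotype != "coding":
            continue
        n_tss = int(rng.integers(1, 4))
        for k in range(n_tss):
            probe = f"cg{pid:07d}"
            pid += 1
            region = "TSS200" if k == 0 else "TSS1500"
            manifest_rows.append((probe, g.gene_id, region))
            probe_info.append((probe, g.gene_id, True))
        probe = f"cg{pid:07d}"
        pid += 1
        manifest_rows.append((probe, g.gene_id, "Body"))
        probe_info.append((probe, g.gene_id, False))
    manifest = pd.DataFrame(manifest_rows, columns=["probe_id", "gene_id", "region"])
    baselines = rng.normal(-1.0, 0.5, size=len(probe_info))

    betas: Dict[str, pd.DataFrame] = {}
    for ct in truth.cancer_types:
        samples = counts[ct].sample_ids
        n = len(samples)
        keep = np.sort(rng.choice(n, size=max(int(0.9 * n), 2), replace=False))
        kept_samples = [samples[i] for i in keep]
        mat = np.empty((len(probe_info), len(keep)))
        for row, (probe, gene_id, is_tss) in enumerate(probe_info):
            eps = rng.normal(0.0, config.meth_noise_sd, size=len(keep))
            x = baselines[row] + eps
            if is_tss and gene_id in mediated:
                p = mediated[gene_id]
                z = latents[ct][f"{p.anchor_id}:{p.partner_id}"][keep]
                x = x + p.meth_coupling * z
            mat[row] = _logistic(x)
        betas[ct] = pd.DataFrame(
            mat, index=[p for p, _, _ in probe_info], columns=kept_samples
        )
    return betas, manifest


# ---------------------------------------------------------------------------
# conservation track
# ---------------------------------------------------------------------------

def generate_conservation_track(
    genes: Sequence[GeneRecord],
    sizes: ChromSizes,
    truth: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator,
) -> Dict[str, List[Tuple[int, int, float]]]:
    """Disjoint scored intervals per chromosome (bedGraph-ready).

    Exons of high-conservation genes score around ``cons_high_mean``, low
    around ``cons_low_mean``, everything else ``cons_background``; where
    exons of several genes overlap, coding exons take precedence.  Values
    are clipped to [0, 1].
    """
    painted: Dict[str, List[Tuple[int, int, float, int]]] = {c: [] for c in sizes}
    for g in genes:
        cls = truth.genes[g.gene_id].conservation
        mean = config.cons_high_mean if cls == "high" else config.cons_low_mean
        priority = 1 if g.biotype == "coding" else 0
        for s, e in merge_intervals(g.exons):
            value = float(np.clip(rng.normal(mean, 0.05), 0.0, 1.0))
            painted[g.chrom].append((s, e, value, priority))

    track: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, segs in painted.items():
        chrom_len = sizes[chrom]
        points = sorted({0, chrom_len} | {s for s, *_ in segs} | {e for _, e, *_ in segs})
        # sweep over atomic intervals; highest (priority, value) wins
        events = sorted(segs)
        out: List[Tuple[int, int, float]] = []
        for a, b in zip(points[:-1], points[1:]):
            covering = [
                (pr, v) for s, e, v, pr in events if s <= a and e >= b
            ]
            value = max(covering)[1] if covering else config.cons_background
            if out and out[-1][2] == value and out[-1][1] == a:
                out[-1] = (out[-1][0], b, value)
            else:
                out.append((a, b, value))
        track[chrom] = out
    return track


def write_bedgraph(
    track: Dict[str, List[Tuple[int, int, float]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for s, e, v in track[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")


# ---------------------------------------------------------------------------
# RCI and categories
# ---------------------------------------------------------------------------

def generate_rci(
    genes: Sequence[GeneRecord],
    truth: TruthManifest,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """RCI values for every lncRNA across cell lines.

    Planted repressor lncRNAs draw from a nuclear-shifted normal
    (mean = ``rci_shift`` < 0); everything else centres at 0.
    """
    cell_lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    rows = []
    for g in genes:
        if g.biotype != "lncRNA":
            continue
        shift = truth.genes[g.gene_id].localization_shift
        vals = rng.normal(shift, config.rci_sd, size=len(cell_lines))
        rows.extend(
            (g.gene_id, cl, float(v)) for cl, v in zip(cell_lines, vals)
        )
    return pd.DataFrame(rows, columns=["gene_id", "cell_line", "rci"])


def generate_categories(
    genes: Sequence[GeneRecord],
    truth: TruthManifest,
    rng: np.random.Generator,
) -> Dict[str, List[str]]:
    """Gene-category lists: one enriched among repressor anchors, one not.

    ``driver_like`` contains half of the repressor anchors plus a 5%
    background of other coding genes (emulating a cancer-gene catalogue);
    ``housekeeping_like`` is a uniform 10% draw of coding genes.
    """
    repressor_anchors = sorted(
        {p.anchor_id for p in truth.pairs_of_class("repressor", "mediated_repressor")}
    )
    coding_ids = sorted(g.gene_id for g in genes if g.biotype == "coding")
    other = [g for g in coding_ids if g not in set(repressor_anchors)]
    driver = sorted(
        [g for g in repressor_anchors if rng.random() < 0.5]
        + [g for g in other if rng.random() < 0.05]
    )
    housekeeping = sorted(g for g in coding_ids if rng.random() < 0.1)
    return {"driver_like": driver, "housekeeping_like": housekeeping}


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimConfig
    genes: List[GeneRecord]
    sizes: ChromSizes
    truth: TruthManifest
    counts: Dict[str, ExpressionMatrix]
    betas: Dict[str, pd.DataFrame]
    probe_manifest: pd.DataFrame
    track: Dict[str, List[Tuple[int, int, float]]]
    rci: pd.DataFrame
    categories: Dict[str, List[str]]

    def score_track(self) -> ScoreTrack:
        return ScoreTrack(self.track)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the complete synthetic cohort deterministically from the seed."""
    genes, sizes, truth = generate_genome(config)
    rng = np.random.default_rng(config.seed + 1)  # genome used its own stream
    counts, latents = generate_expression(genes, truth, config, rng)
    betas, manifest = generate_methylation(genes, truth, config, latents, counts, rng)
    track = generate_conservation_track(genes, sizes, truth, config, rng)
    rci = generate_rci(genes, truth, config, rng)
    categories = generate_categories(genes, truth, rng)
    return SyntheticCohort(
        config=config, genes=genes, sizes=sizes, truth=truth, counts=counts,
        betas=betas, probe_manifest=manifest, track=track, rci=rci,
        categories=categories,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Dict[str, Path]:
    """Write the cohort in exactly the formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "counts").mkdir(exist_ok=True)
    (out / "methylation").mkdir(exist_ok=True)
    (out / "categories").mkdir(exist_ok=True)

    paths: Dict[str, Path] = {}
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(cohort.genes, paths["gtf"])
    paths["chrom_sizes"] = out / "chrom.sizes"
    write_chrom_sizes(cohort.sizes, paths["chrom_sizes"])

    index_rows = []
    for ct in sorted(cohort.counts):
        p = out / "counts" / f"{ct}.tsv"
        cohort.counts[ct].data.to_csv(p, sep="\t", index_label="gene_id")
        index_rows.append(f"{ct}\tcounts/{ct}.tsv")
    paths["cohort_index"] = out / "cohort_index.tsv"
    paths["cohort_index"].write_text("\n".join(index_rows) + "\n")

    meth_rows = []
    for ct in sorted(cohort.betas):
        p = out / "methylation" / f"{ct}.tsv"
        cohort.betas[ct].to_csv(p, sep="\t", index_label="probe_id", float_format="%.5f")
        meth_rows.append(f"{ct}\tmethylation/{ct}.tsv")
    paths["meth_index"] = out / "meth_index.tsv"
    paths["meth_index"].write_text("\n".join(meth_rows) + "\n")
    paths["probe_manifest"] = out / "probe_manifest.tsv"
    cohort.probe_manifest.to_csv(paths["probe_manifest"], sep="\t", index=False)

    paths["conservation"] = out / "conservation.bedgraph"
    write_bedgraph(cohort.track, paths["conservation"])
    paths["rci"] = out / "rci.tsv"
    cohort.rci.to_csv(paths["rci"], sep="\t", index=False, float_format="%.4f")
    for name, members in sorted(cohort.categories.items()):
        p = out / "categories" / f"{name}.txt"
        p.write_text("\n".join(members) + "\n")
        paths[f"category_{name}"] = p
    paths["truth"] = out / "truth.json"
    cohort.truth.to_json(paths["truth"])
    return paths
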