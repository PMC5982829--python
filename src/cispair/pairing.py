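"""Proximal gene-pair construction, orientation classes and the shuffle null.

Pairing reproduces BEDTools ``windowBed`` semantics on gene spans: a partner
is paired with a coding anchor when its span overlaps, completely or
partially, the anchor span extended by the window on both sides.  Same-strand
lncRNAs overlapping or within a short gap of a coding gene are flagged as
potential alternative-polyadenylation (APA) read-through artifacts and
removed before pairing.  The shuffle null relocates genes uniformly within
their own chromosome (``shuffleBed -chrom`` semantics, overlaps allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .annotation import ChromSizes, GeneRecord

ORIENTATIONS = (
    "antisense_overlap",
    "sense_overlap",
    "divergent",
    "convergent",
    "sense_upstream",
    "sense_downstream",
)


@dataclass(frozen=True)
class GenePair:
    """A coding anchor with a proximal partner at a given window threshold."""

    anchor_id: str
    partner_id: str
    partner_class: str  # {lncRNA, coding}
    distance_bp: int
    orientation: str
    window_bp: int

    def __post_init__(self) -> None:
        if self.anchor_id == self.partner_id:
            raise ValueError("self-pair")
        if not (0 <= self.distance_bp <= self.window_bp):
            raise ValueError(
                f"{self.anchor_id}/{self.partner_id}: distance {self.distance_bp} "
                f"outside [0, {self.window_bp}]"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class APAFlag:
    """A same-strand lncRNA close enough to a coding gene to be a 3' artifact."""

    lnc_id: str
    coding_id: str
    gap_bp: int


def span_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Gap between nearest span boundaries; 0 when spans overlap."""
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def classify_orientation(anchor: GeneRecord, partner: GeneRecord) -> str:
    """Orientation of a partner relative to a coding anchor.

    Overlapping spans are antisense_overlap / sense_overlap by strand.
    Non-overlapping partners on the opposite strand are divergent when they
    sit on the anchor's 5' side (promoters head-to-head) and convergent on
    the 3' side (tails facing); same-strand partners are sense_upstream /
    sense_downstream of the anchor's 5' end.
    """
    if anchor.chrom != partner.chrom:
        raise ValueError(
            f"{anchor.gene_id} on {anchor.chrom} vs {partner.gene_id} on {partner.chrom}"
        )
    overlap = anchor.start < partner.end and partner.start < anchor.end
    same_strand = anchor.strand == partner.strand
    if overlap:
        return "sense_overlap" if same_strand else "antisense_overlap"
    # which flank of the anchor does the partner occupy, in anchor 5'->3' sense
    partner_left = partner.end <= anchor.start
    on_five_prime = partner_left if anchor.strand == "+" else not partner_left
    if same_strand:
        return "sense_upstream" if on_five_prime else "sense_downstream"
    return "divergent" if on_five_prime else "convergent"


def flag_apa_candidates(
    coding: Sequence[GeneRecord],
    lncs: Sequence[GeneRecord],
    apa_gap: int = 5000,
    side: str = "both",
) -> List[APAFlag]:
    """Flag same-strand lncRNAs overlapping or within ``apa_gap`` of a coding gene.

    ``side='both'`` applies the gap on either side of the coding gene;
    ``side='three_prime'`` restricts non-overlapping flags to lncRNAs lying
    past the coding gene's 3' end (the read-through geometry proper).
    Each lncRNA is flagged at most once, against the closest qualifying
    coding gene.
    """
    if side not in ("both", "three_prime"):
        raise ValueError(f"bad side {side!r}")
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    flags: List[APAFlag] = []
    for lnc in lncs:
        best: Tuple[int, str] | None = None
        for cg in by_chrom.get(lnc.chrom, []):
            if cg.strand != lnc.strand:
                continue
            gap = span_distance(cg, lnc)
            if gap > apa_gap:
                continue
            if side == "three_prime" and gap > 0:
                downstream = lnc.start >= cg.end if cg.strand == "+" else lnc.end <= cg.start
                if not downstream:
                    continue
            if best is None or gap < best[0] or (gap == best[0] and cg.gene_id < best[1]):
                best = (gap, cg.gene_id)
        if best is not None:
            flags.append(APAFlag(lnc_id=lnc.gene_id, coding_id=best[1], gap_bp=best[0]))
    return flags


def build_window_pairs(
    anchors: Sequence[GeneRecord],
    partners: Sequence[GeneRecord],
    window_bp: int,
    partner_class: str = "lncRNA",
    dedupe_unordered: bool = False,
) -> List[GenePair]:
    """All (anchor, partner) pairs whose spans fall within ``window_bp``.

    A pair is emitted when the partner span intersects
    ``[anchor.start - window_bp, anchor.end + window_bp)``, i.e. the nearest
    boundary gap is at most the window (0 when overlapping).  With
    ``dedupe_unordered`` (coding/coding controls) each unordered pair is kept
    once, with the lexicographically smaller gene_id as anchor.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for p in partners:
        by_chrom.setdefault(p.chrom, []).append(p)
    starts: Dict[str, np.ndarray] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda g: g.start)
        starts[chrom] = np.array([g.start for g in plist])

    pairs: List[GenePair] = []
    seen = set()
    for anchor in anchors:
        plist = by_chrom.get(anchor.chrom)
        if not plist:
            continue
        lo = anchor.start - window_bp
        hi = anchor.end + window_bp
        # partners sorted by start; any partner with start < hi may qualify,
        # and partners are variable-length so scan left of the cut for ends > lo
        cut = int(np.searchsorted(starts[anchor.chrom], hi, side="left"))
        for partner in plist[:cut]:
            if partner.end <= lo or partner.gene_id == anchor.gene_id:
                continue
            a_id, p_id = anchor.gene_id, partner.gene_id
            if dedupe_unordered and p_id < a_id:
                a_id, p_id = p_id, a_id
            key = (a_id, p_id)
            if key in seen:
                continue
            seen.add(key)
            if dedupe_unordered and a_id != anchor.gene_id:
                anc, part = partner, anchor
            else:
                anc, part = anchor, partner
            pairs.append(
                GenePair(
                    anchor_id=anc.gene_id,
                    partner_id=part.gene_id,
                    partner_class=partner_class,
                    distance_bp=span_distance(anc, part),
                    orientation=classify_orientation(anc, part),
                    window_bp=window_bp,
                )
            )
    return pairs


def shuffle_within_chromosome(
    genes: Sequence[GeneRecord],
    sizes: ChromSizes,
    seed: int | np.random.Generator,
    no_overlap: bool = False,
    max_tries: int = 1000,
) -> List[GeneRecord]:
    """Relocate each gene uniformly within its own chromosome.

    Gene id, chromosome, strand, length and exon structure (shifted) are
    preserved.  Overlaps among the shuffled genes are permitted by default;
    ``no_overlap`` enables rejection sampling against previously placed
    genes.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    placed: Dict[str, List[Tuple[int, int]]] = {}
    out: List[GeneRecord] = []
    for g in genes:
        chrom_len = sizes[g.chrom]
        if g.length > chrom_len:
            raise ValueError(f"{g.gene_id}: longer than chromosome {g.chrom}")
        hi = chrom_len - g.length
        for _ in range(max_tries):
            new_start = int(rng.integers(0, hi + 1))
            if not no_overlap:
                break
            span = (new_start, new_start + g.length)
            if all(
                span[1] <= s or span[0] >= e for s, e in placed.get(g.chrom, [])
            ):
                break
        else:
            raise RuntimeError(f"{g.gene_id}: could not place without overlap")
        placed.setdefault(g.chrom, []).append((new_start, new_start + g.length))
        out.append(g.shifted(new_start))
    return out


def colocation_fraction(
    lncs: Sequence[GeneRecord],
    coding: Sequence[GeneRecord],
    window_bp: int,
) -> float:
    """Fraction of lncRNAs with at least one coding gene within ``window_bp``."""
    if not lncs:
        return float("nan")
    pairs = build_window_pairs(coding, lncs, window_bp)
    hit = {p.partner_id for p in pairs}
    return len(hit & {g.gene_id for g in lncs}) / len(lncs)


def pairs_to_frame(pairs: Iterable[GenePair]):
    """Pairs as a DataFrame in the canonical TSV column order."""
    import pandas as pd

    rows = [
        (p.anchor_id, p.partner_id, p.partner_class, p.orientation, p.distance_bp, p.window_bp)
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "anchor_id",
            "partner_id",
            "partner_class",
            "orientation",
            "distance_bp",
            "window_bp",
        ],
    )
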