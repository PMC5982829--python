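"""Gene-model types, annotation I/O and exon-interval utilities.

All coordinates are internally 0-based half-open (BED convention).  GTF input
(1-based inclusive) is converted on read.  A gene is modelled at gene level
only: exons from all transcripts are pooled and may overlap; interval
utilities (:func:`merge_exons`, :func:`subtract_intervals`) operate on the
pooled set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

Interval = Tuple[int, int]

#: Default mapping from GENCODE biotype strings to the two classes the
#: screen distinguishes.  Anything absent from the mapping is ignored.
DEFAULT_BIOTYPE_MAP: Dict[str, str] = {
    "protein_coding": "coding",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "3prime_overlapping_ncrna": "lncRNA",
}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class GeneRecord:
    """A stranded, gene-level model on 0-based half-open coordinates.

    ``exons`` is the pool of exon intervals across all transcripts of the
    gene; duplicates and overlaps are permitted and resolved by
    :func:`merge_exons` when a disjoint support is needed.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in ("coding", "lncRNA"):
            raise AnnotationError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene without exons")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(
                    f"{self.gene_id}: exon ({s}, {e}) outside gene span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (5' end) as a single base position."""
        return self.start if self.strand == "+" else self.end - 1

    def shifted(self, new_start: int) -> "GeneRecord":
        """A copy translated so that the span starts at ``new_start``."""
        delta = new_start - self.start
        return replace(
            self,
            start=new_start,
            end=self.end + delta,
            exons=[(s + delta, e + delta) for s, e in self.exons],
        )


class ChromSizes(dict):
    """Chromosome name -> length (bases).  Plain dict with validation."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise AnnotationError(f"chromosome {name}: non-positive length")
        super().__init__(sizes)

    def validate_genes(self, genes: Iterable[GeneRecord]) -> None:
        for g in genes:
            if g.chrom not in self:
                raise AnnotationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self[g.chrom]:
                raise AnnotationError(
                    f"{g.gene_id}: end {g.end} beyond {g.chrom} length {self[g.chrom]}"
                )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of half-open intervals: sorted, pairwise disjoint.

    Adjacent intervals (end == next start) merge, so the result is the
    minimal disjoint representation of the covered bases.
    """
    if not intervals:
        return []
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_exons(gene: GeneRecord) -> List[Interval]:
    """Disjoint union of a gene's pooled exon intervals."""
    return merge_intervals(gene.exons)


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Bases of ``a`` not covered by ``b`` (both half-open), sorted disjoint."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def interval_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    biotype_map: Mapping[str, str] | None = None,
) -> List[GeneRecord]:
    """Read a GENCODE-dialect GTF into gene-level records.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons of all transcripts are pooled per gene (duplicates kept; merging is
    deferred to :func:`merge_exons`).  Genes whose biotype maps to ``ignore``
    (or is absent from the map) are dropped, together with their exons.

    The gene line's coordinates are authoritative for the span; if pooled
    exons extend beyond it a warning is issued and the exons are clipped.
    """
    biotype_map = dict(biotype_map or DEFAULT_BIOTYPE_MAP)
    genes: Dict[str, dict] = {}
    exons: Dict[str, List[Interval]] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}: line {lineno}: missing gene_id")
            if feature == "gene":
                raw_bt = attrs.get("gene_type", attrs.get("gene_biotype", ""))
                genes[gene_id] = dict(
                    chrom=chrom, start=start, end=end, strand=strand, raw_biotype=raw_bt
                )
                order.append(gene_id)
            else:
                exons.setdefault(gene_id, []).append((start, end))

    orphans = sorted(set(exons) - set(genes))
    if orphans:
        raise AnnotationError(
            f"{path}: exon feature(s) without a gene line: {', '.join(orphans[:5])}"
        )

    records: List[GeneRecord] = []
    for gene_id in order:
        info = genes[gene_id]
        biotype = biotype_map.get(info["raw_biotype"], "ignore")
        if biotype == "ignore":
            continue
        gene_exons = exons.get(gene_id) or [(info["start"], info["end"])]
        lo = min(s for s, _ in gene_exons)
        hi = max(e for _, e in gene_exons)
        if lo < info["start"] or hi > info["end"]:
            warnings.warn(
                f"{gene_id}: exon extremes [{lo}, {hi}) disagree with gene line "
                f"[{info['start']}, {info['end']}); gene line kept, exons clipped"
            )
            gene_exons = [
                (max(s, info["start"]), min(e, info["end"]))
                for s, e in gene_exons
                if max(s, info["start"]) < min(e, info["end"])
            ] or [(info["start"], info["end"])]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=info["chrom"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                biotype=biotype,
                exons=gene_exons,
            )
        )
    return records


_GTF_BIOTYPE = {"coding": "protein_coding", "lncRNA": "lincRNA"}


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene + exon features in GENCODE-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{_GTF_BIOTYPE[g.biotype]}"; '
                f'gene_name "{g.gene_id}";'
            )
            fh.write(
                f"{g.chrom}\tcispair\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tcispair\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed6(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}|{g.biotype}\t0\t{g.strand}\n"
            )


def write_bed12(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Gene spans with merged exon blocks.  name = ``gene_id|biotype``."""
    with open(path, "w") as fh:
        for g in genes:
            blocks = merge_exons(g)
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            starts = ",".join(str(s - g.start) for s, _ in blocks) + ","
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        f"{g.gene_id}|{g.biotype}",
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> List[GeneRecord]:
    records: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}: line {lineno}: not BED12")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            gene_id, _, biotype = name.partition("|")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotype or "coding",
                    exons=exons,
                )
            )
    return records


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Two-column TSV: chromosome name, length."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AnnotationError(f"{path}: line {lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")
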