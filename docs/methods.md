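# Methods

This note records the models, conventions and numerical choices behind
`cispair`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and gene models

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read.  Genes are modelled at gene level:
exons from all transcripts are pooled, and interval utilities
(`merge_intervals`, `subtract_intervals`) produce the disjoint supports used
for conservation averaging.  The gene line's span is authoritative when it
disagrees with exon extremes (a warning is issued and exons are clipped)
because downstream pairing distances are defined on gene spans.  Biotype
assignment to {coding, lncRNA} is configuration: a shipped GENCODE-style
default maps `protein_coding` to coding and the common long-non-coding
biotypes (`lincRNA`, `antisense`, `processed_transcript`, `sense_intronic`,
`sense_overlapping`, `3prime_overlapping_ncrna`) to lncRNA; everything else
is dropped.  Annotation releases disagree about which biotypes are "lncRNA",
so this is deliberately not hard-coded.

## Pairing

`build_window_pairs` reproduces BEDTools `windowBed` semantics: a partner is
paired with a coding anchor when its span intersects the anchor span
extended by the window on both sides, with the intersection taken on
half-open intervals.  `distance_bp` is the gap between nearest span
boundaries (0 for any overlap) — span distance, not TSS distance, matching
window semantics on gene BED records.  Coding/coding control pairs use the
identical operation with self-pairs removed and each unordered pair kept
once (lexicographically smaller id as anchor).  Pair sets are nested across
windows by construction, which the tests assert.

The APA filter removes same-strand lncRNAs that overlap a coding gene or lie
within `apa_gap` (default 5000 bp) of either boundary.  The read-through
geometry proper is only the 3' side; the default is symmetric because an
intersect+closest implementation is side-agnostic, and a `side='three_prime'`
switch restricts it.  Each lncRNA is flagged at most once, against the
closest qualifying coding gene.

The shuffle null (`shuffle_within_chromosome`) redraws each gene's start
uniformly within its own chromosome, preserving id, strand, length and exon
structure, allowing overlaps (as `shuffleBed -chrom` does without
`-noOverlapping`; a rejection-sampling no-overlap mode exists but is off by
default).  Shuffling perturbs proximity only; expression stays attached to
gene ids, so shuffled-pair correlations use real expression values.

## Correlation screen

Normalization is plain CPM against the raw column sum — deliberately not
TMM or any compositional correction, since the screen is rank-based within
gene pairs.  The expression filter (≥ 1 CPM in ≥ 3 samples, per cancer
type) gates which pairs are testable in which cancer type; mean profiles
for Tau are computed over all samples regardless, so a gene weakly
expressed in some cancer types still contributes honest (near-zero) means.

Spearman ρ is the Pearson correlation of midranks.  The two-sided *P* uses
the *t* approximation t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of freedom,
adequate for cohort-scale n; |ρ| = 1 reports *P* at the double-precision
floor rather than zero so that downstream −log transforms stay finite.
Constant vectors raise an explicit error and the pair is skipped with a
logged reason.  Pairs are tested only in cancer types with at least
`min_samples_for_test` (default 10) samples, below which rank-test *P*
values are unstable.

BH adjustment is applied within each (cancer type × partner class × window)
family by default.  The family choice is not dictated by the statistic;
per-cancer families match the per-cancer presentation of the results and
keep LC and CC screens comparable at each window.  A `global` family mode is
available.  Significance is adjusted *P* < 10⁻⁵ with no ρ threshold: large
cohorts make small correlations significant, and pairs with modest but
consistent negative ρ are exactly the interesting ones.

Set labels aggregate per pair across cancer types at a single window
(default: the largest).  "Majority of cancers" means a strict majority of
*testable* cancer types — a cancer type where either gene fails the filter
cannot vote; a mode using the full cohort count exists.  Significant
correlations of the opposite sign do not veto membership (a pair can be LCN
with some positively-significant types); strict majorities of opposite signs
are mutually exclusive, so every pair gets exactly one of
{LCN, LCP, CCN, CCP, none}.

LC-vs-CC enrichment per (cancer type, window) uses the two-sided Fisher
exact test on the 2×2 table of significant/non-significant counts; a
stratum is flagged enriched when *P* < 0.01 and the LC fraction exceeds the
CC fraction.

## Characterization

**Tau** is computed on log2(mean CPM + 1) by default (log expression keeps a
single dominant cancer type from saturating the index); a raw-CPM mode
exists.  Both modes give τ = 0 for uniform nonzero profiles and τ = 1 for
single-type expression.  All-zero profiles are undefined (error in the
scalar API, NaN in the table API).

**Conservation** is the base-weighted mean of a per-base score over the
gene's merged exons; for lncRNAs the union of all coding exons on the same
chromosome is subtracted first, so shared antisense sequence cannot inflate
lncRNA conservation.  Uncovered bases score 0 — averaging is over all
exonic bases, not only covered ones.  Tracks are read from bedGraph
(4-column, 0-based half-open); bigWig is accepted when pyBigWig is
importable.  Empty post-mask support yields n_bases = 0 and an undefined
mean.

**Probe assignment**: among TSS-region probes (TSS200 ∪ TSS1500) present in
the beta matrix, the probe with the maximum mean beta within the cancer type
represents the TSS, ties broken to the lexicographically smallest probe id.
"Maximum value" is ambiguous (max mean, max variance, per-sample max); max
mean is the only reading that yields one deterministic probe per cancer
type.  **Coupling** correlates lncRNA CPM with that probe's beta over the
matched-sample intersection, BH-adjusted per cancer type at 0.05; a pair is
"positively coupled" when ρ > 0 in a strict majority of its testable cancer
types.  Note this flag deliberately carries no significance requirement —
it mirrors a fraction-of-set statistic, and under independence it behaves
like a fair coin per cancer type, which the null test accounts for.

**Localization** compares LCN lncRNA RCI values per cell line against the
lncRNA background and against LCP, using the pooled-variance Student t-test
(Welch available).  Zero-variance degenerate groups return *P* = 1 for equal
means and the numeric floor otherwise.

**Category enrichment** compares each set's unique coding genes against the
union of the other three sets by default (the quoted comparison of interest:
is the negative lncRNA set special *among* the screened sets); an all-genes
background mode exists.

## Synthetic cohort

The generator emulates the real inputs at desk scale with planted, labelled
structure; defaults are 3 × 10 Mb chromosomes, 300 coding + 300 lncRNA
genes, 4 cancer types × 200 samples, 40 repressor pairs (half
methylation-mediated), 60 shared-domain pairs, 60 independent proximal
pairs (10 of them just beyond 100 kb as out-of-window controls) and 20 APA
decoys.

* **Geometry.** Coding genes sit non-overlapping on a slot grid; planted
  partners are drawn over the orientation classes (antisense overlap,
  divergent < 1 kb, convergent, sense up/downstream ≥ 6 kb to stay clear of
  the APA rule) with distances spread 70/20/10% across the three window
  strata.  All same-strand placements are rejection-sampled to keep more
  than 5.5 kb from every coding gene, so exactly the configured decoys are
  APA-flagged.
* **Counts.** Negative binomial with gene-level dispersion 0.2 (TCGA-like
  overdispersion; Poisson counts would make the *P* values dishonestly
  sharp), log-normal library sizes (σ = 0.3 around 10⁶).  Latent per-sample
  activities z ~ N(0,1), shared within a pair, enter the log-mean with gain
  +γ for the lncRNA and −γ for the repressed coding gene; shared-domain
  pairs get a common +0.5·z.  γ = 0.53 was calibrated once by brute-force
  simulation to a population Spearman of ≈ −0.5 at typical planted base
  expression (lncRNA 15 CPM, coding 80 CPM); the γ→ρ map is frozen in
  `tests/data/gamma_calibration.json` and spot-checked by a test.  Planted
  genes have base expression clamped to ≥ 8 CPM so they are testable.
  Single-cancer genes use a 0.1-CPM off-type baseline with a 6.5 log-unit
  boost in one cancer type, which realizes τ > 0.9.
* **Methylation.** Betas are logistic(N(−1, 0.5) + noise), strictly inside
  (0,1); mediated pairs add +1.0·z at the coding TSS probes so beta rises
  with lncRNA expression.  1–3 TSS probes plus a body probe per coding gene
  exercise probe selection; ~10% of samples lack methylation to exercise
  sample matching.
* **Track / RCI / categories.** Exons of high-conservation genes (all
  coding; 20% of repressor lncRNAs) score ≈ 0.8, low ≈ 0.05, background
  0.02, clipped to [0,1], coding exons winning where exons overlap.
  Repressor lncRNAs draw RCI from N(−1.2, 1) across 15 cell lines, others
  from N(0, 1).  A "driver_like" category contains half the repressor
  anchors plus 5% background coding genes.

What the generator does **not** emulate: batch structure, tumor purity,
copy-number or mutational covariates, genome-scale gene density, realistic
exon size distributions, or correlated methylation beyond the planted TSS
probes.  Passing recovery tests therefore shows the statistical machinery is
correct and calibrated under the stated noise model — not that the screen's
biological error rates on real tumor data match these numbers.

## Problem sizes, determinism, degenerate inputs

The test suite runs the full pipeline on the default cohort once (seed 1)
and asserts ≥ 80% repressor sensitivity with ≤ 10% false-discovery
proportion and ≥ 80% mediated-coupling sensitivity; null calibration uses 20
seeds of a reduced all-independent cohort (60 + 60 genes, 4 × 100 samples —
the null property does not depend on cohort size) and requires an empty LCN
set in ≥ 95% of seeds with no enriched stratum.  All randomness flows from
explicit seeds through `numpy.random.default_rng`; outputs are plain TSV and
JSON written with fixed float formatting and sorted ordering, so identical
configs reproduce byte-identical files (asserted by test).  Degenerate
inputs have defined behaviour throughout: all-zero library columns pass
through as zeros with a warning, constant expression vectors skip the pair
with a logged reason, empty conservation support reports n_bases = 0,
empty enrichment strata emit unflagged rows, and single-cancer-type cohorts
degenerate the majority rule to that type's sign.

## Known limitations

* The Spearman *P* uses the *t* approximation everywhere; an exact
  permutation *P* is not implemented (cohorts below 10 samples are excluded
  instead).
* The screen is marginal: no partial correlation or adjustment for copy
  number, mutation or purity, by design — negative correlation is treated as
  a hypothesis generator, not a causal claim.
* The methylation analysis tests only the paired coding TSS, not a
  genome-wide scan, and the coupling flag is a sign-majority statistic with
  the null behaviour noted above.
* lncRNA/lncRNA pairs are out of scope; anchors are always coding genes.
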