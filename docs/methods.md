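# Methods

## Problem and model

A transposon mutant pool is a mixture of clones, each disrupted at one
genomic position.  Sequencing by inverse PCR from the inserted element
produces junction reads: `[PCR remnant] + transposon terminus + flanking
genome`.  The analysis reduces these reads to a table of unique insertion
positions with read depth, then to per-gene statistics, then (for a
selection experiment) to per-site enrichment scores between two pools.

## Junction-read extraction

Reads are scanned for the user-declared terminal motif and for its reverse
complement, derived automatically — a read may present either strand of the
junction.  Matching is exact: no mismatch allowance is given, because the
motif is a primer-defined constant region and exact matching keeps the
motif-match count interpretable; `N` never matches.  Tie-breaks are
deterministic and logged: the forward orientation wins over the reverse
complement when both occur (pathological, e.g. palindromic motifs), and
within an orientation the leftmost occurrence wins.

The emitted fragment is the sequence on the genomic side of the junction,
re-oriented to transposon orientation (bases upstream of a
reverse-complement match are reverse-complemented, qualities reversed), so
base 1 of every fragment is the junction-adjacent genomic base and one
aligner convention serves both orientations.  Length bounds default to
20–50 bp: shorter fragments map unreliably, and a short maximum avoids
re-entering the transposon when the PCR template was a small circle.
Truncation keeps the junction-proximal bases, since those define the
insertion site.  When both mates of a pair survive trimming they describe
the same junction, so mate 2 is discarded (mate 1 kept by convention; the
choice is arbitrary and affects nothing downstream).  A motif flush with
the read end yields a zero-length fragment and is rejected as `too_short`.

Conservation is asserted, not assumed: every input read is accounted for as
emitted, no-motif, too-short, or discarded mate 2, and the counts go in the
run log.

## Alignment

Alignment is external and pluggable (`bwa mem -t 2` default, `bowtie2
--end-to-end --very-sensitive` supported; unknown programs need an explicit
opt-in flag).  Downstream filtering needs MD and AS tags; a missing MD tag
is repaired from the reference via `samtools calmd` rather than read as
zero mismatches, which would silently disable the mismatch filter.
Secondary and supplementary records are ignored — only the primary
alignment of a read is counted, the conservative reading of "confidently
mapped".

The package also ships an exact-match oracle aligner (exhaustive substring
search, accelerated by a 16-mer index): a fragment occurring exactly once
in the reference, over both strands, is placed with full-match tags
(`MD=L`, `AS=L`); anything ambiguous or absent is unmapped.  It exists as
an independent reference implementation for tests and simulations, where
its requirements hold by construction; it is not a general-purpose aligner.

## Insertion calling

Per record, substitutions are counted from the MD tag; letters inside
`^`-deletion runs are deleted reference bases, not substitutions, and
insertions are invisible to MD, so indels are never counted — only true
substitutions.  A fractional mismatch threshold `m ∈ (0,1)` means
`floor(m × read length)`, reading "fraction of bases allowed" as an upper
bound.  The score filter is `AS ≥ threshold` on the aligner's own scale
(negative thresholds are meaningful for bowtie2); a record with no AS tag
fails and is counted separately.

The insertion site is the junction-adjacent base: the leftmost reference
position on `+`, and `pos + reference span − 1` on `-` (reference span from
CIGAR M/D/N/=/X; soft clips consume no reference).

Elements that copy a target site on insertion (8 bp for pGhost9::ISS1)
place the two junctions of one insertion exactly that distance apart, so
sites exactly `d` bp apart are merged into the lower position with depths
summed.  The merge is a single left-to-right pass without re-chaining: a
duplication produces exactly one partner site, so chains of merges are
artifacts, not signal.  Summing (rather than averaging) depth preserves
read conservation.  The coverage filter (`depth ≥ k`, recommended k=2)
runs at the counts stage, after collapsing — the pipeline order is fixed.

## Per-gene statistics

GFF3 and GFF2 dialects are accepted (parsed with gffutils); CDS features
are preferred over `gene`, and the identifier is the first of `ID`,
`locus_tag`, `gene_id`.  A site belongs to a gene when `start ≤ pos ≤ end`
(annotated span, not codon-truncated); sites in overlapping genes count in
each, flagged in the log — silently dropping them would bias both genes.

NRM and NIM normalise reads (resp. unique insertions) per kb of gene per
million pool-wide reads (resp. insertions), making genes comparable across
lengths and experiments; both are invariant under rescaling all counts and
totals together.  The NIM denominator uses genome-wide unique insertions
(not genic-only).  Genes with zero insertions stay in the table with
NIM = 0 and absent centiles — they are the essential candidates; the call
is strict (`NIM < 2`).

Centiles place each insertion within its gene 5′→3′ in coding orientation
(`100 × (offset+1) / length`; offset measured from `end` on `-` strand), so
base 1 of a gene scores `100/L` and the last coding base 100.  The NIindex
assigns each site `observed − expected` with one pool-wide expectation
(total reads / unique sites); the profile sums to zero by construction and
is emitted raw alongside a centred 201-site running-mean curve (cosmetics
only).

## Two-pool comparison

Shared sites are scored by the log proportion ratio, with each site's share
computed against its pool's **total mapped reads** (the plainest reading of
"share of reads"; a switch recomputes shares against shared-position totals
instead, and the choice is logged).  The Z-score standardises against the
shared population's own mean and sample (n−1) standard deviation, so the
Z population has mean 0 and sd 1 by construction — an identity the tests
hold to 1e-9.  Degenerate inputs (no shared sites, or sd = 0) short-circuit
with a warning rather than dividing by zero.

Flag bands are fixed two-sided normal quantiles: 1.960 (p≈0.05), 2.579
(p≈0.01), 3.291 (p≈0.001), lower edges inclusive.  The middle edge is
2.579 by convention of this flagging scheme — the textbook 0.995 quantile
is 2.576; the band between them is vanishingly thin.  The flags are an
approximation of importance, not multiplicity-corrected inference;
replicate-aware dispersion modelling is deliberately out of scope.

## Simulator

The generator emulates the library construction end to end: uniform random
genome; non-overlapping single-exon genes on alternating strands (one per
~1.1 kb, covering ~75% of the genome, as in a dense bacterial annotation);
insertions at unique positions; per-insertion read counts geometric
(mean 5, so singleton sites exist and the coverage filter has work to do);
reads split between the two junction orientations; and the target-site
duplication emulated by displacing the reverse junction exactly `tsd` bp.
Defaults — 500 kb genome, 450 genes, 5,000 insertions, tsd 8, 50 bp reads,
error rate 0 — describe a desk-scale screen with the per-kb insertion
density of a saturating library.

Three deliberate guarantees make truth recovery exact rather than
approximate, and each is a documented departure from full realism:

- **Minimum spacing 2·tsd+1** between planted insertions, so no two
  junctions from different insertions sit exactly `tsd` apart and collapse
  merges only true duplication partners.  Real libraries can violate this
  (~50 expected violations at 5,000 insertions on 500 kb); such collisions
  are unresolvable in principle by any distance-based collapse.
- **Errors never touch the motif**, so motif recovery is exact; motif-error
  robustness is explicitly not modelled.
- **Read self-check**: after assembly each read is verified to yield the
  intended junction under the same motif-search rules the pipeline uses
  (a random filler or error can otherwise spawn a spurious earlier match);
  failing reads are re-drawn, deterministically under the seed.

An insertion whose reads all come from the reverse junction leaves evidence
only at `p + tsd`; the truth-derived expectation accounts for this, because
no pipeline can infer a site for which no read exists.

The paired-pool null generator draws independent log-normal depths
(μ=2, σ=0.8 on the log scale, rounded, min 1) for one shared position set:
per-site read shares in real pools are heavy-tailed and roughly log-normal,
which is precisely the empirical premise that makes the log-ratio Z-score
approximately standard normal and the ~5% null flag rate meaningful.  What
passing tests on these simulations do **not** show: robustness to PCR
duplicates, insertion hot-spot sequence preference, realistic Illumina
error profiles, or multi-replicate dispersion — none of which the
generator models.

## Numerical and size choices

Exact identities (truth recovery, NIindex zero-sum at 1e-6, Z
self-normalisation at 1e-9) are asserted at machine-precision-scale
tolerances; distributional properties use binomial-width bands (base
composition ±5% at n=1000; null flag rate 5% ± 2% at n=2000).  Test and
verification runs use 500 kb / 5,000 insertions for the full round trip
(seconds on one CPU) and 100 kb / 1,000 insertions for the error-bearing
sweep; these sizes already saturate the properties being checked, and every
quantity scales per-million so larger runs change nothing but duration.

## Known limitations

No BAM/CRAM input (SAM only); no fuzzy motif matching; no operon-aware
polar-effect modelling; flags are not corrected for multiple testing;
GFF features spanning the origin of a circular chromosome are not handled
specially.
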