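# Methods

This note documents the models and procedures implemented in `linrep`, the
assumptions behind them, the parameters that matter, and what the synthetic
data does and does not emulate.

## Coordinates and data model

Internally every algorithm works on 0-based half-open intervals; everything
reported or serialized is 1-based inclusive, the convention of GenBank
records and of the coordinates people quote when describing bacterial
genomes. A `Replicon` carries an explicit `linear`/`circular` topology flag
that is never inferred: the systems this package targets are dominated by
linear replicons, so FASTA input (which has no topology field) defaults to
linear with a warning, and GenBank topology is read from the record.

CDS products are binned into functional categories by an ordered,
case-insensitive keyword table — `transposase` ← "transposase";
`transcriptional_regulator` ← "transcriptional regulator", then the broader
"regulator"; `hypothetical` ← "hypothetical protein"; anything else
`other` — with first-match-wins semantics. Annotation tables rarely state
the counting rule behind their transposase or regulator columns; this table
is one explicit operationalization, user-overridable, and counts derived
from it should be compared with published counts with that caveat in mind.
N bases are allowed in sequences, excluded from both numerator and
denominator of GC content, and never match a restriction site.

## Virtual digestion and gel matching

Site scanning is IUPAC-aware on the top strand, with the bottom strand
scanned for non-palindromic sites and the cut mapped back to top-strand
coordinates (the four shipped enzymes — DraI, AseI, BfrI, XbaI — are all
palindromic; the bottom-strand path exists for user-supplied sites).
Overlapping occurrences each yield a cut; duplicate cut positions collapse.
Circular replicons are scanned across the origin, and a single cut in a
circle linearizes it. Fragment lengths always sum exactly to the replicon
length — this conservation law is enforced by tests for every enzyme and
topology.

The gel model has two parts. Visibility: fragments below `min_visible_bp`
(default 30,000, reflecting pulsed-field running conditions tuned for large
fragments) are dropped from matching and their count reported. Migration:
the standard log-size law `position = a − b·log10(size)` within a
resolvable range; sizes outside it are flagged as compressed at the gel
limit.

Band matching is a maximum-cardinality one-to-one assignment between
visible predicted fragments and observed bands under a relative-error cap
(default 5%, in line with the sizing uncertainty of pulsed-field ladders,
which is worst for bands above ~500 kb), with ties broken by minimum total
relative error; it is solved exactly as a rectangular assignment problem.
Because distinct fragments of nearly equal size co-migrate as one band,
unmatched predicted fragments within tolerance of a matched fragment and
its band are attached to that band as a co-migration group rather than
reported missing.

## Collapsed inverted repeats from read depth

The model: a linear plasmid whose two ends are long inverted repeats
(lengths R) flanking a unique central region (length C) assembles into a
single `arm + central` contig because the assembler cannot separate the two
repeat copies; mapped-read depth is then ~2× over the arm and 1× over the
central region, and the true plasmid length is 2R + C.

Detection is in three steps:

1. **Smoothing.** A centered rolling median over `smooth_window_bp`
   (default 1,000, forced odd so that a clean step edge is preserved
   exactly).
2. **Change points.** Recursive binary segmentation on the smoothed track
   with within-segment squared-deviation cost; a split is accepted when its
   cost reduction exceeds a BIC-style penalty `10·σ²·log n`, with σ
   estimated robustly from the median absolute deviation of raw first
   differences (a floor of 1e-9 makes noiseless steps split exactly and
   constant tracks stay whole). Segments shorter than `min_segment_bp`
   (default 5,000) merge into the neighbor with the closer mean. The
   procedure is deterministic given the track.
3. **Calling.** Every end-anchored run of segments is a candidate arm; the
   call requires the length-weighted mean depth of the arm over that of the
   remainder to fall in `ratio_band` (default [1.6, 2.4], a tolerant
   reading of "twice the coverage"); the maximal qualifying run wins, and
   an arm covering the whole contig is a no-call. The baseline depth is the
   central-region mean, not the global mean: the arm dominates the contig
   length and would bias a global baseline.

Reconstruction returns `2·(contig − C) + C`, and sequence expansion emits
`arm + central + revcomp(arm)` (mirrored for a right-anchored arm), whose
first R bases provably equal the reverse complement of its last R bases.
Only one collapsed repeat per contig is resolved, and the arm must touch a
contig end — interior duplications are out of model. Telomere sequence
reconstruction is out of scope.

## Plasmid comparison

**Anchors.** All k-mers (default k = 21) unique in both sequences — with
uniqueness counted across both strands — matched forward and
reverse-complement and merged into maximal exact matches. At k = 21 a
~300-kb plasmid is effectively anchor-dense everywhere outside repeated
elements; transposase cassettes and other repeats contribute no anchors and
surface as gaps. k is configurable.

**Chaining.** Same-orientation collinear anchors are chained by
longest-total-length dynamic programming, extracted greedily. Three link
rules keep blocks honest:

* gaps on either sequence at most `max_gap` (default 5,000) and gap-length
  difference at most the indel/event boundary (50 bp), so any indel at or
  above the boundary splits the chain and surfaces as an event;
* no link may jump over another substantial anchor (≥ 50 bp) sitting inside
  its gap on either sequence — otherwise a chain can bridge an inverted
  segment whose divergence is diluted by identical flanking sequence;
* an anchor-free gap longer than 20 bp on both sides must actually align
  (edlib divergence ≤ 30%; unrelated 70%-GC sequence aligns at ~48%,
  genuine substitution clusters at a few percent).

Per-block identity comes from edlib alignment of the inter-anchor gaps.
Blocks shorter than `min_block` (default 500 bp) are dropped.

**Events.** The collinear backbone is the maximum-weight (by reference
span) chain of blocks with near-disjoint increasing intervals on both
sequences. Off-backbone blocks are translocations, or duplications when
their reference interval is already covered by a backbone block. Reverse
backbone blocks are inversions. Walking backbone adjacencies
(sentinel-bounded, with up to 50 bp of boundary slop), a gap present only
on the derived sequence is an insertion — reclassified as a duplication
when the inserted sequence (≥ 50 bp) aligns to the reference at ≤ 10%
divergence, which captures donor-copied material — and a gap only on the
reference is a deletion. Gap material explained by a translocated block is
not double-reported. When unaligned residue flanks an indel (an event
within one k-mer of a sequence end), the gap pair is aligned and the
longest indel run localizes the event at base resolution. Insertion
positions are reported, alongside the reference locus, as the 1-based
coordinate of the first inserted base on the derived sequence — the frame
in which such positions are usually quoted.

A translocation whose displacement is smaller than its own length is
inherently ambiguous — moving segment X left by d < |X| is
indistinguishable from moving the intervening segment right — and the
classifier resolves it by parsimony (the smaller displaced weight moves).
The synthetic generator samples translocations only in the unambiguous
regime (displacement greater than the segment length).

**SNPs.** Forward blocks with identity ≥ 0.9 are globally aligned and the
columns walked: mismatches become substitution calls; indel runs shorter
than 50 bp become indel calls, left-aligned to their canonical position in
repeat context (runs ≥ 50 bp belong to event classification). Reverse
blocks are not scanned for SNPs: in the near-identity regime this tool
targets, point mutations sit in the collinear backbone; mutations inside an
inverted segment are a documented blind spot. Coding effects use
translation table 11, strand-aware, from the annotated frame start (with a
warning when the CDS length is not a multiple of 3; a substitution in an
incomplete terminal codon is conservatively reported as missense).

## Mobile-element statistics

Density is simply `count / (length / 1e6)`, reported unrounded (rounding
only in display). The breakpoint-proximity statistic is the mean distance
from each breakpoint to the nearest feature edge (0 inside a feature),
computed on merged intervals. The null distribution redraws the same number
of positions uniformly on [1, L] `n_perm` times (default 10,000), seeded
and bit-for-bit reproducible; the one-sided p-value carries a +1
pseudo-count so it is never exactly zero. A permutation null was chosen
over an analytic one because feature intervals are irregular; its empirical
size is verified against the nominal α in the test suite. Breakpoints may
come from rearrangement events or from contig-junction coordinates — both
are plain position lists to this module. The median CDS length in
summaries uses the lower-middle convention for even counts (published
tables rarely disclose their tie rule; this one is fixed and stated).

## Synthetic data

The generator is a pure function of its inputs and seed (bit-identical
reruns) and emulates: i.i.d. base composition at a target GC (default
0.72); non-overlapping CDS cassettes whose product strings are drawn from
category-typical templates so keyword classification recovers the planted
category exactly; derived plasmids built by applying non-overlapping
insertions (random, explicit, or copied from a donor interval — the
donor-copy path emulates chromosomal transfer into a plasmid and exercises
duplication detection), deletions, inversions, translocations and
substitutions, with exact post-hoc coordinates recorded in the conventions
the mapper reports (deletion loci left-aligned to canonical position);
terminally inverted-duplicated plasmids with their collapsed `arm +
central` form; coverage tracks with expected depth 2d over the arm and d
elsewhere, perturbed by per-base multiplicative uniform noise (default
±15% around a 40× baseline); and gel observations with multiplicative
Gaussian sizing error (default 2%), a small-fragment visibility cutoff
(default 30 kb) and optional co-migration merging.

What it does **not** emulate — and hence what passing tests do not show
about real data: codon/dinucleotide structure, read-level long-read error
profiles and coverage waviness (GC bias, mappability), assembler-specific
collapse artifacts beyond the clean arm+central model, nested or
overlapping rearrangements, and telomeric ends. Event sets are sampled
well-separated (≥ 2 kb apart, ≥ 2 kb from ends) so each event is flanked by
anchorable sequence.

## Problem sizes and numerical choices

The default verification battery runs on scaled-down but structurally
faithful instances chosen to keep the full suite fast on one CPU:
2.3-Mb simulated genomes for digestion/gel statistics, 60–240-kb coverage
tracks across 100 seeded collapsed-repeat simulations (R ∈ [50, 200] kb,
C ∈ [10, 40] kb), 30-kb references across 100 seeded rearrangement sets,
one 300-kb SNP-recovery instance, and 200 replicates × 500 permutations
for null calibration. Tolerances asserted by the suite: collapsed-repeat R
and 2R + C within ±2% in ≥ 95/100 runs; rearrangement loci within ±k;
planted SNPs exact; permutation-test size within 3 binomial standard
errors of α = 0.05; ≥ 95% of visible bands matched at tolerance 3× the
sizing error.

Checks against the published ATCC 10970 accessions (fragment counts 14/17,
chromosome GC 72.0%, plasmid transposase counts, the 6.7-kb plasmid
insertion and the R6-500 central region) require downloading the deposited
records and are packaged as optional integration tests that activate when
the files are placed under `data/external/`.
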