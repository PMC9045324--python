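# linrep

Structural analysis of linear bacterial replicons — the linear chromosomes
and giant linear plasmids (GLPs) of high-GC actinomycetes such as
*Streptomyces*.

Finishing one of these genomes leaves a set of questions that sit between
assembly and biology, and this package turns each into a reproducible
computation:

* **Is the assembly the right shape?** Digest it in silico with a
  rare-cutter (DraI `TTT^AAA`, AseI `AT^TAAT`, …) and match the predicted
  fragment multiset against the bands observed on a pulsed-field gel
  (PFGE), modelling the visibility cutoff below which small fragments
  vanish under long-switch running conditions.
* **Is a linear plasmid half its true size?** Long terminal inverted
  repeats — one plasmid end equal to the reverse complement of the other —
  collapse into a single contig during assembly, halving the apparent
  length and doubling read depth over the repeat. From a coverage track,
  `linrep` segments the depth profile, calls the end-anchored ~2× arm, and
  reconstructs the full length as **2R + C** (arm length R, unique central
  region C), optionally emitting the full `arm + central + revcomp(arm)`
  sequence.
* **What changed between two plasmids?** Unique *k*-mer anchors are chained
  into synteny blocks; block gaps and order changes are classified into
  insertions, deletions, inversions, translocations and duplications;
  within-block alignment columns become SNP and short-indel calls with a
  strand-aware coding-effect classification (synonymous / missense /
  nonsense / frameshift / in-frame indel).
* **Are the breakpoints where the transposases are?** Per-replicon
  transposase densities (counts per Mbp from CDS product keywords) and a
  seeded Monte-Carlo permutation test of whether breakpoints or contig
  junctions sit closer to transposase features than uniformly random
  positions, `p = (1 + #{null ≤ observed}) / (n_perm + 1)`.

A seeded synthetic-data module generates the whole study system — ~70% GC
linear replicons, planted CDS cassettes, derived plasmids with known
rearrangements, collapsed-repeat coverage tracks, noisy gel observations —
with exact ground truth, so every analysis is testable offline.

## Worked example

Generate a fixture set and run the pipeline end to end:

```sh
linrep simulate --seed 7 --outdir fixtures
linrep digest fixtures/reference.fasta --enzyme DraI -o fragments.tsv
linrep gelmatch --predicted fragments.tsv --observed fixtures/bands.tsv --tol 0.06 -o report.tsv
linrep repeatfind --coverage fixtures/coverage.bedgraph -o call.tsv
linrep compare fixtures/reference.fasta fixtures/derived.fasta -o events.bed --snps snps.tsv
```

which prints

```
3 fragments (3 visible >= 30000 bp, 0 below cutoff); total 300000 bp
3 matched, 0 predicted unmatched, 0 observed unmatched, 0 co-migration group(s)
arm (0, 100000) central (100000, 125000) ratio 2.00 reconstructed 225000 bp
7 blocks, 2 events
8 SNP/short-indel calls
```

Reading this: DraI cuts the 300-kb simulated reference into 3 fragments,
all large enough to appear on the gel, and all 3 match an observed band
within tolerance — the assembly's digest profile is consistent with the
gel. The collapsed contig's coverage shows a 100-kb end-anchored arm at
2.00× the 25-kb central region, so the real plasmid is
2·100,000 + 25,000 = 225,000 bp. Comparing the derived plasmid to the
reference finds 2 rearrangement events and 8 point mutations; for this
seed the simulator's `truth.json` records exactly those two translocations
(positions 189,634 and 199,820) and all eight substitutions, each recovered
at the planted coordinate.

The same operations are available as a library
(`linrep.digest`, `linrep.repeats`, `linrep.compare`, `linrep.mobile`,
`linrep.simulate`), with the CLI a thin wrapper over them.

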