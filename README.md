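# seqbias

Profiling of short-read sequencing error modes and coverage biases from
mapped reads.

Short-read platforms differ in systematic, context-dependent ways that
aggregate quality metrics hide: optical versus strand-of-origin duplicate
structure, per-cycle substitution error, elevated read-2 error on short
fragments with a characteristic substitution spectrum, error bursts after
homopolymers and tandem repeats, strand-specific soft-clipping and quality
loss around G-quadruplex (G4) motifs, and coverage bias across genome
stratifications.  `seqbias` implements the full set of analyses needed to
characterize these behaviours from coordinate-sorted alignments, plus the
machinery to build high-confidence benchmarking regions for variant-call
comparison.  It is written for bioinformaticians evaluating sequencing
platforms or debugging error modes in WGS data.

A truth-annotated synthetic read simulator is a first-class part of the
package: it plants repeat/GC/G4 features into a random reference, emits
aligned paired-end reads exhibiting each phenomenon at configurable
strength, and records every injected event, so every analysis stage is
validated by parameter recovery without external data.

## The statistics it computes

* **Duplicate taxonomy.** For read pairs in a duplicate set, the Euclidean
  distance between flowcell coordinates (tile, x, y parsed from read
  names) and the relative read1/read2 order classify each comparison into
  {proximal, distal} x {complementary, non-complementary}.  Pairs within
  100 dimensionless pixel units on the same tile are proximal
  (optical-like); pairs with swapped mate roles are complementary
  ("sister" duplicates from the opposing strand of the same fragment).

* **Reference-based error.** For aligned, non-clipped columns of reads
  with MAPQ >= 60, the substitution rate per sequencing cycle
  (reverse-strand reads flipped so cycle 1 is the first sequenced base),
  per 50 bp insert-size bin, and per substitution type (12 types in read
  orientation, collapsed to 6 complement pairs), smoothed with a 5 bp
  rolling mean; the mid-read summary is the median rate over cycles
  50%-60% into the read.

* **Overlap-based error.** For proper pairs with |TLEN| < 2L the mates
  resequence the same molecule; a disagreement within the overlap charges
  one error to the lower-quality mate (ties split 0.5/0.5).  This measure
  is blind to true variants and pre-sequencing damage, so the gap between
  reference-based and overlap-based rates estimates variant density.

* **Context-dependent error change.** Reads overlapping a region set are
  stacked on an offset axis in sequencing direction; the change statistic
  is the mean rate over the 50 flank bases downstream of the region
  divided by the same window upstream, calibrated against random 30 bp
  control regions.

* **G4 soft-clip discovery and pileup.** Spans of reads with >= 10 total
  soft-clipped bases are slopped by 10 bp, merged with read counts,
  filtered (>= 2 reads, shared across run replicates and >= 2 subjects),
  purged of dual-strand loci and control-platform loci, and related to
  predicted G4 motifs by strand.  Around isolated motifs (> 300 bp apart,
  <= 50 bp long), base-quality and mismatch pileups are taken per strand
  for reads covering the motif by >= 5 bp on each side.

* **Stratified coverage.** Pair-consistent downsampling, MAPQ >= 60 depth,
  mean coverage per stratification (>= 10 kb span), relative difference
  (strat/autosomal - 1), and selection of the top-variance stratifications
  across datasets.

* **High-confidence regions and F1.** 100 bp windows with >= 10x and <= 2x
  median coverage in every dataset, intersected across technologies, minus
  clustered-variant (>= 2 within 10 bp, slop 50), SV (> 50 bp, slop 50),
  CNV (slop 1000) and configured BED exclusions, with partially covered
  repeats removed whole.  Benchmarking uses
  `F1 = (TP_truth + TP_query) / (TP_truth + TP_query + FP + FN)`.

## Worked example

```python
from seqbias import (SimulationConfig, ErrorModel, FeaturePlan, PostRepeatBurst,
                     build_reference, simulate_reads)
from seqbias.errors import (reference_error_by_cycle, overlap_error_by_cycle,
                            midread_median_rate)
from seqbias.duplicates import tally_duplicates
from seqbias.context import stack_by_interval, pooled_error_change

config = SimulationConfig(
    genome_length=100_000,
    depth=30,
    seed=1,
    feature_plan=[FeaturePlan("homopolymer", count=40, base="G", length=15)],
    duplicate_rates={"optical": 0.05, "complementary": 0.10},
    error_model=ErrorModel(
        base_rate_r1=0.001,
        base_rate_r2=0.004,
        post_repeat_burst=PostRepeatBurst(("homopolymer",), 3.0, 20),
    ),
)
reference, features = build_reference(config)
reads, truth = simulate_reads(config, reference, features)
refmap = {config.chrom: reference}

cycle = reference_error_by_cycle(reads, refmap)
med = midread_median_rate(cycle)
print(f"mid-read error rate  read1 {med[1]:.2%}  read2 {med[2]:.2%}")

overlap = overlap_error_by_cycle(reads)
print(f"overlap-based total error rate {overlap.total_rate():.2%} "
      f"({overlap.column_pairs} overlapping columns)")

tally = tally_duplicates(reads, mode="vs_primary")
n = len(truth.fragments)
print(f"duplicates per fragment: optical "
      f"{tally.counts['proximal_noncomplementary'] / n:.1%}, sister "
      f"{(tally.counts['distal_complementary'] + tally.counts['proximal_complementary']) / n:.1%}")

profile = stack_by_interval(reads, refmap, features, flank=150)
change = pooled_error_change(profile, window=50)
print(f"error-rate change after G homopolymers: x{change.ratio:.2f} "
      f"(upstream {change.upstream_rate:.2%}, downstream {change.downstream_rate:.2%})")
```

prints

```
mid-read error rate  read1 0.10%  read2 0.44%
overlap-based total error rate 0.58% (12387 overlapping columns)
duplicates per fragment: optical 5.1%, sister 9.7%
error-rate change after G homopolymers: x3.22 (upstream 0.24%, downstream 0.78%)
```

The mid-read rates recover the configured per-mate error rates (the
read-2 estimate sits slightly above its 0.40% base rate because the
post-homopolymer burst also elevates read-2 columns).  The overlap-based
total approximates the sum of the two per-mate rates plus the burst
contribution.  The injected duplicate fractions are recovered from
flowcell geometry and mate orientation alone, and the change statistic
recovers the planted x3 burst.

A `seqbias` command-line interface wraps the same functions for file-based
work (`seqbias simulate`, `duplicates`, `errors`, `context`, `g4-profile`,
`coverage`, `f1`); run `seqbias --help` for details.

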