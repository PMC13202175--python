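# Methods

This note documents the models behind `seqbias`: what the synthetic-read
generator simulates and what it deliberately does not, the conventions
every analysis stage follows, and the choices made where the design was
genuinely open.  Nothing here states an empirical result; all numbers the
package produces come from the test suite and `scripts/acceptance.py`.

## The synthetic-read generator

`simulate.build_reference` draws a uniform-random A/C/G/T background of
the configured length and plants features — homopolymers, tandem repeats,
GC-rich blocks, and canonical G4 motifs (on either strand; a minus-strand
motif is planted as its reverse complement, i.e. C-runs on the forward
sequence) — into equal slots with seeded jitter.  The slot layout
guarantees at least `feature_spacing` bases (default 500) between any two
features, which keeps every planted G4 motif "isolated" in the sense the
pileup analysis requires (> 300 bp from its neighbours) and keeps repeat
flank windows disjoint.  Packing that cannot honour the spacing raises an
error rather than silently overlapping features.

`simulate.simulate_reads` emits already-aligned records: the generator
knows each fragment's true origin, so no external aligner is involved and
soft-clips are written directly into CIGARs.  This keeps the test loop
closed and desk-scale; it also means alignment artefacts (mismapping,
clipping heuristics) are out of scope by construction.

Fragments: the fragment count is `depth x genome_length / (2 x
read_length)`, so non-duplicate reads alone realize the configured mean
depth; duplicates are emitted on top.  Insert sizes are normal
(default mean 400 bp, sd 60 bp — the ~400 bp WGS library regime with a
spread wide enough to populate both the overlapping-pair regime
(< 300 bp) and the 400 bp+ bins), rounded and truncated to
[read_length, genome_length].  Each fragment's read1 occupies the left or
right end with probability 1/2; reads are 150 bp (2 x 150 layout).

Error processes, applied per read in read space (sequencing order):

* base substitution at `base_rate_r1` / `base_rate_r2` per base, alternate
  base uniform among the other three;
* an optional linear end-of-read ramp over the final k cycles;
* **short-insert read-2 boost**: for read 2 of fragments below the
  threshold (default 300 bp), the rate is multiplied (default x4) and
  substitutions are drawn from a 12-type weight table.  The per-base rate
  is made proportional to the weight mass of the base's reference
  nucleotide (`rate_b = base x multiplier x 4 x W_b`), so the realized
  joint (ref, alt) distribution among boosted errors equals the
  normalized weights exactly on a uniform-composition genome.  The
  default acceptance scenario puts 0.6 of the mass on C>T/G>A and 0.2 on
  C>A/G>T, the deamination/oxidation-like signature;
* **post-repeat burst**: after a read traverses an affected feature
  (homopolymer by default), its error rate is multiplied (x3 in the
  acceptance scenario) for a plateau of `post_repeat_plateau` bases
  (default 50) past the feature exit, then relaxes exponentially with
  scale `decay` (default 20 bp).  The burst is applied in sequencing
  direction — the mechanism is a perturbation of synthesis, which travels
  with the polymerase, not with the reference.  The plateau-then-decay
  shape encodes the assumption that the perturbed state persists over
  tens of cycles before relaxing; a pure exponential with a ~20 bp scale
  would decay within the measurement window and make the 50 bp change
  statistic systematically underestimate the planted multiplier, which is
  not how the phenomenon presents (the elevation is sustained across the
  near-downstream flank);
* **G4 effect**: for reads sequencing the strand complementary to a
  planted motif and entering it from outside, base qualities drop by the
  configured Phred amount (default scenario: 10) from motif entry onward;
  with probability `softclip_prob` the remainder of the read is replaced
  by a C-biased random run and recorded as soft-clipped (the aligned span
  ends at the motif boundary); otherwise each within-motif base is forced
  to a C call with probability `c_excess`, producing C-dominated
  mismatches at loop positions.  The quality-drop magnitude and clip
  probability are free parameters chosen for a clear recoverable signal,
  not measured quantities;
* **planted variants**: homozygous SNVs at `variant_rate` are substituted
  into the sampled genome before reads are drawn, so reference-based
  error measures count them while overlap-based measures do not — the
  gap between the two estimates the planted density.

Duplicates are injected per fragment, independently per category:
*optical* copies share the tile and sit at a distance drawn uniform in
(0, 99) pixels (99 rather than 100 so integer pixel rounding can never
push a copy past the proximal threshold); *complementary* ("sister")
copies resequence the opposing strand — identical genomic coordinates
with read1/read2 roles swapped — and land anywhere on the flowcell;
*pcr-like* copies land on a guaranteed different tile.  All but one
member of each group carry the duplicate flag; all members share a group
tag (`DI`) and carry their injected category (`DC`).  The flowcell is an
abstract grid of 10 000 x 10 000 dimensionless pixels per tile (default
4 tiles); read names encode `tile:x:y` as the final colon-separated
fields, the common short-read convention.

Qualities are emitted as two constants (`quality_given_correct` = 36,
`quality_given_error` = 14), i.e. perfectly calibrated in sign: an
erroneous base always reports lower quality than a correct one, which
makes the overlap attribution rule exact up to the O(e^2) case of both
mates erring at the same column.  The four-bin coarse reporting mode
(Q0-2 -> 2, Q3-17 -> 12, Q18-29 -> 24, Q30+ -> 40) can be applied on top.

What the generator does **not** emulate: sequencing chemistry (phasing,
avidite kinetics), PCR error propagation, indels, GC-dependent coverage
bias, mappability structure, quality-score miscalibration, or alignment
errors.  Passing recovery tests therefore demonstrates that the analysis
code measures what it claims to measure on data with known structure; it
does not certify behaviour on real data where these confounders exist.

## Analysis conventions

* Intervals are 0-based half-open everywhere; BED is read/written
  natively and VCF positions are converted on ingest.  Merging unions
  overlapping *and book-ended* intervals per (chrom, strand) key and
  carries absorbed-input counts, matching the defaults of the standard
  BED merging tool.
* Cycle indexing is 1-based in sequencing order; reverse-strand
  alignments are flipped (`cycle = query_length - query_position`).
* N bases and indel/clipped columns are excluded from numerator and
  denominator of every substitution rate.
* Reads failing the MAPQ floor (default 60) and duplicate-flagged reads
  are excluded from all profiling by default.
* Overlap attribution compares raw Phred values by default; the
  error-probability binning hook (bin width on the [0, 1] scale) is
  available but opt-in, because coarse bins turn most quality differences
  into ties.  Ties split 0.5/0.5, so attributed errors always sum to the
  number of disagreeing columns.  The per-pair denominator counts every
  overlapping column once per mate; the "total" overlap rate divides all
  attributed errors by the number of column pairs and so estimates the
  *sum* of the two per-mate rates.
* The mid-read window is cycles `ceil(0.5 L)` to `floor(0.6 L)` inclusive
  (75-90 for L = 150), and the summary is the median across cycles of the
  aggregate profile — the per-read median is equivalent in expectation
  but unstable at low per-read error counts.
* "Downstream" in context profiles means later sequencing cycles:
  reverse-strand reads are mirrored onto the offset axis.  A
  reference-oriented axis is available via `orientation="reference"` in
  both the stacking and pileup functions.  Only reads overlapping the
  region itself contribute to its flanks.  The change statistic uses the
  50 flank bases nearest the region, excludes inside-region columns,
  and reports the ratio (headline) plus the additive difference.  A zero
  upstream mean with errors downstream is guarded with 1/n and flagged;
  zero errors on both flanks make the ratio undefined (NaN) rather than
  zero, since no change is measurable.
* Soft-clip site discovery treats the *total* clipped length per read
  (both ends summed) as the threshold quantity, uses the aligned span
  (clips excluded) as the read's interval, and applies intersection
  semantics (any base overlap) when requiring loci to be shared across
  run replicates and subjects.  Dual-strand loci are removed from both
  strands; control loci, computed through the same per-strand pipeline
  (with the subject requirement capped at the number of control subjects)
  are subtracted at base level.
* Motif isolation removes *both* members of a close pair (< 300 bp) and
  any motif longer than 50 bp.  Pileups refuse non-isolated motifs.
* Depth uses reference-span semantics: deletions and skips add depth,
  insertions and clips do not.  Window filtering keeps windows with mean
  depth >= 10 and <= 2 x the median window depth, boundaries inclusive on
  the keep side (the stated exclusions are strictly-below and
  strictly-above).
* Variant clusters are measured edge-to-edge between reference spans
  (SNV = 1 base, indel = its REF span); a run of >= 2 variants each within
  10 bp of the previous is excluded with 50 bp slop.  SVs must be
  *strictly* longer than 50 bp to trigger exclusion.  Partially covered
  repeats are subtracted whole: a repeat interval not fully contained in
  the surviving confident set removes all of its bases.
* Pair-consistent downsampling hashes `seed:query_name` (CRC32), so both
  mates share the decision and the subset is reproducible.
* Stratifications spanning < 10 kb are excluded as unstable; label
  blocklists (ancestry-, functional- and genome-specific categories by
  default) are configurable.  Top-variance selection uses the sample
  variance of mean coverage across datasets per label, ties broken
  lexicographically.

## Test design and problem sizes

Recovery tests run on 100 kb genomes at 30x (10 000 fragments; 50 000 for
the duplicate-taxonomy scenario on a 500 kb genome so that category
fractions have tight binomial bands), sizes at which every stage's
statistics resolve their planted parameters within 3 standard errors
while the whole suite stays in the minutes range on one CPU.  Statistical
assertions use exact binomial standard errors at the planted parameter;
the per-cycle band uses a Bonferroni-style simultaneous quantile (z = 4.5
for ~300 simultaneous cycle comparisons) so that checking every cycle at
once preserves the intended 3-sigma overall confidence.  Interval
machinery is checked bit-identically against per-base boolean oracles on
randomized 10 kb instances across 50 seeds.

`scripts/acceptance.py` re-simulates each scenario under sub-seeds derived
from `--seed` and reports recovered quantities with their problem sizes.
Its benchmark stage calls homozygous SNVs naively (>= 10x depth, >= 80%
mismatching bases) inside regions built by the coverage-window cascade and
scores them against the planted truth with the disambiguated F1 — a
demonstration of the region/F1 machinery, not a variant caller.

## Known limitations

* The simulator's G4 mechanism affects only reads *entering* a motif from
  outside; reads starting inside a motif are untouched.  Real polony- or
  cluster-level effects may not respect that boundary.
* The built-in G4 finder is a canonical-motif regex
  (`G{3,}(N{1,7}G{3,}){3}`, leftmost match), a stand-in sufficient for
  synthetic sequence; genome-scale predictions should be supplied as BED
  from a dedicated predictor.
* Only substitution errors are modelled and profiled; indel error modes
  are out of scope throughout.
* `tally_duplicates(mode="vs_primary")` requires the retained
  (non-duplicate) representative to be present in the stream; sets
  consisting only of flagged reads are skipped.
* The discovery pipeline's supporting-read counts are summed over all
  contributing datasets at a locus and are provenance information, not a
  statistic.
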