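"""Synthetic reference and paired-end aligned-read simulator.

The simulator emits already-aligned, truth-annotated read records (it knows
every read's true origin), which keeps the whole analysis loop closed and
desk-scale: no external aligner is involved and soft-clips are written
directly into CIGARs.  Each phenomenon the profiling stages measure can be
switched on at configurable strength:

* per-cycle substitution errors with separate read-1/read-2 base rates and
  an optional end-of-read ramp;
* an elevated, substitution-biased error rate on read 2 of short-insert
  fragments;
* an error burst after traversing planted repeat features, applied in
  sequencing direction;
* a G-quadruplex effect on reads sequencing the strand opposite a planted
  motif: a Phred quality drop from motif entry onward, soft-clipping of the
  remainder of the read with a C-biased fill, and excess C calls inside the
  motif on reads that are not clipped;
* duplicate read pairs of three kinds -- optical (same tile, close on the
  flowcell), complementary/"sister" (opposing strand of the same fragment,
  read1/read2 roles swapped), and PCR-like (distant coordinates);
* homozygous single-nucleotide divergence between the sampled genome and
  the reference, so reference-based and overlap-based error measures differ
  by a known amount.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .records import FORWARD, REVERSE, AlignedReadRecord, revcomp

BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}

#: the 12 reference->read substitution types, read orientation
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FeaturePlan:
    """One class of planted reference feature.

    kind: homopolymer | tandem_repeat | gc_block | g4_motif
    """

    kind: str
    count: int = 1
    base: str = "G"  # homopolymer composition
    length: int = 15  # homopolymer / gc_block length
    unit: str = "AC"  # tandem-repeat unit
    copies: int = 10  # tandem-repeat copy number
    motif: str = "GGGATGGGATGGGATGGG"  # g4 motif (G-run strand)
    strand: str = "+"  # strand carrying the G-runs
    gc: float = 0.8  # gc_block GC fraction

    def instance_length(self) -> int:
        if self.kind == "homopolymer":
            return self.length
        if self.kind == "tandem_repeat":
            return len(self.unit) * self.copies
        if self.kind == "gc_block":
            return self.length
        if self.kind == "g4_motif":
            return len(self.motif)
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "homopolymer":
            return f"homopolymer_{self.base}{self.length}"
        if self.kind == "tandem_repeat":
            return f"tandem_repeat_{self.unit}x{self.copies}"
        if self.kind == "gc_block":
            return f"gc_block_{self.length}"
        return "g4_motif"


@dataclass
class ShortInsertBoost:
    """Multiplied, substitution-biased error rate for read 2 of short
    fragments.  ``bias`` assigns weights to the 12 read-orientation
    substitution types; error positions are drawn so that the realized joint
    (ref, alt) distribution among boosted errors matches the normalized
    weights (on a uniform-composition genome)."""

    threshold: int = 300  # |insert| below this is boosted
    multiplier: float = 4.0
    bias: dict[str, float] | None = None


@dataclass
class PostRepeatBurst:
    """Error-rate burst after traversing a repeat feature, in sequencing
    direction.  The multiplier holds at full strength for ``plateau`` bases
    past the feature exit (the perturbed state persists over tens of cycles)
    and then relaxes exponentially with scale ``decay``."""

    kinds: tuple[str, ...] = ("homopolymer",)
    multiplier: float = 1.0
    decay: int = 20
    plateau: int = 50


@dataclass
class G4Effect:
    """Effect on reads sequencing the strand complementary to a G4 motif and
    entering it.  Defaults are chosen for a clear, recoverable signal; the
    underlying magnitudes are free parameters of the generator, not measured
    quantities."""

    quality_drop: int = 0  # Phred drop from motif entry onward
    softclip_prob: float = 0.0  # P(rest of read soft-clipped at entry)
    c_excess: float = 0.0  # per-base P(forced C call inside motif), unclipped reads
    clip_c_weight: float = 0.7  # P(C) in the clipped fill


@dataclass
class ErrorModel:
    base_rate_r1: float = 0.0
    base_rate_r2: float = 0.0
    end_ramp: tuple[float, int] = (0.0, 0)  # (added rate per cycle, final k cycles)
    short_insert_r2_boost: ShortInsertBoost | None = None
    post_repeat_burst: PostRepeatBurst | None = None
    g4_effect: G4Effect | None = None
    quality_given_error: int = 14
    quality_given_correct: int = 36


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    feature_plan: list[FeaturePlan] = field(default_factory=list)
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 60.0
    depth: float = 30.0
    duplicate_rates: dict[str, float] = field(default_factory=dict)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    quality_binning: str = "off"  # off | four_bin
    variant_rate: float = 0.0  # homozygous SNV divergence vs reference
    seed: int = 0
    chrom: str = "sim1"
    feature_spacing: int = 500  # minimum gap between planted features
    n_tiles: int = 4
    tile_size: int = 10_000  # abstract pixel grid per tile

    def __post_init__(self) -> None:
        for k, p in self.duplicate_rates.items():
            if k not in ("optical", "complementary", "pcr_like"):
                raise ValueError(f"unknown duplicate category {k!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"duplicate rate {k}={p} outside [0,1]")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if self.duplicate_rates.get("pcr_like", 0) > 0 and self.n_tiles < 2:
            raise ValueError("pcr_like duplicates need n_tiles >= 2")


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests.

    substitutions: (query_name, mate, cycle 1-based, true base, emitted
    base), read orientation, aligned columns only.
    duplicates: (query_name, category, group_id); originals of duplicate
    groups appear with category "primary".
    fragments: (fragment_id, start, insert, read1_left).
    clip_events: (query_name, mate, motif_label) for injected soft-clips.
    read_features: (query_name, mate) -> overlapped feature labels.
    variant_positions: reference positions carrying planted SNVs.
    """

    substitutions: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    duplicates: list[tuple[str, str, int]] = field(default_factory=list)
    fragments: list[tuple[int, int, int, bool]] = field(default_factory=list)
    clip_events: list[tuple[str, int, str]] = field(default_factory=list)
    read_features: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)
    variant_positions: list[int] = field(default_factory=list)

    def substitution_count(self) -> int:
        return len(self.substitutions)

    def write_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            self.substitutions,
            columns=["query_name", "mate", "cycle", "true_base", "emitted_base"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def _feature_sequence(plan: FeaturePlan, rng: np.random.Generator) -> str:
    if plan.kind == "homopolymer":
        return plan.base * plan.length
    if plan.kind == "tandem_repeat":
        return plan.unit * plan.copies
    if plan.kind == "gc_block":
        p = np.array([(1 - plan.gc) / 2, plan.gc / 2, plan.gc / 2, (1 - plan.gc) / 2])
        return "".join(BASES[rng.choice(4, size=plan.length, p=p)])
    if plan.kind == "g4_motif":
        return plan.motif if plan.strand == "+" else revcomp(plan.motif)
    raise ValueError(plan.kind)


def build_reference(config: SimulationConfig) -> tuple[str, IntervalSet]:
    """Random background sequence with the planned features planted at
    recorded, non-overlapping intervals.  Features are laid out in equal
    slots with seeded jitter, guaranteeing at least ``feature_spacing``
    bases between any two; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    seq = BASES[rng.integers(0, 4, size=config.genome_length)]

    instances: list[FeaturePlan] = []
    for plan in config.feature_plan:
        instances.extend([plan] * plan.count)
    ivs: list[GenomicInterval] = []
    if instances:
        order = rng.permutation(len(instances))
        n = len(instances)
        slot = config.genome_length // n
        margin = config.feature_spacing // 2
        for slot_i, inst_i in enumerate(order):
            plan = instances[inst_i]
            flen = plan.instance_length()
            lo = slot_i * slot + margin
            hi = (slot_i + 1) * slot - margin - flen
            if hi < lo:
                need = sum(p.instance_length() for p in instances) + n * config.feature_spacing
                raise ValueError(
                    f"infeasible feature packing: need ~{need} bases, "
                    f"have {config.genome_length}"
                )
            start = int(rng.integers(lo, hi + 1))
            fseq = _feature_sequence(plan, rng)
            seq[start : start + flen] = list(fseq)
            strand = plan.strand if plan.kind == "g4_motif" else "."
            ivs.append(
                GenomicInterval(config.chrom, start, start + flen, strand, plan.label())
            )
    features = IntervalSet(ivs).sorted()
    return "".join(seq), features


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def _bias_tables(bias: dict[str, float]):
    """Normalize 12-type weights; return per-ref-base marginals W_b and
    per-ref-base alt distributions."""
    total = sum(bias.get(t, 0.0) for t in SUBSTITUTION_TYPES)
    if total <= 0:
        raise ValueError("substitution bias weights sum to zero")
    w = {t: bias.get(t, 0.0) / total for t in SUBSTITUTION_TYPES}
    marg = np.zeros(4)
    alts: dict[str, tuple[list[str], np.ndarray]] = {}
    for b in "ACGT":
        opts = [a for a in "ACGT" if a != b]
        probs = np.array([w[f"{b}>{a}"] for a in opts])
        marg[_BASE_IDX[b]] = probs.sum()
        alts[b] = (opts, probs / probs.sum() if probs.sum() > 0 else np.full(3, 1 / 3))
    return marg, alts


@dataclass
class _Fragment:
    frag_id: int
    start: int
    insert: int
    read1_left: bool


def _motif_entry(
    read_start: int, L: int, strand: str, motif: GenomicInterval
) -> int | None:
    """Read-space index at which a read enters a motif from outside, in
    sequencing direction; None if the read does not enter it."""
    f0, f1 = motif.start, motif.end
    if strand == FORWARD:
        if read_start < f0 < read_start + L:
            return f0 - read_start
    else:
        if read_start < f1 < read_start + L:
            return read_start + L - f1
    return None


class _ReadEmitter:
    """Per-read error/quality/clip machinery shared by all fragments."""

    def __init__(
        self,
        config: SimulationConfig,
        sample_genome: str,
        features: IntervalSet,
        rng: np.random.Generator,
    ) -> None:
        self.cfg = config
        self.em = config.error_model
        self.genome = np.frombuffer(sample_genome.encode(), dtype="S1")
        self.rng = rng
        self.features = list(features)
        burst = self.em.post_repeat_burst
        self.burst_features = (
            [f for f in self.features if any(f.label.startswith(k) for k in burst.kinds)]
            if burst
            else []
        )
        self.g4_features = [f for f in self.features if f.label == "g4_motif"]
        boost = self.em.short_insert_r2_boost
        if boost and boost.bias:
            self.boost_marg, self.boost_alts = _bias_tables(boost.bias)
        elif boost:
            self.boost_marg, self.boost_alts = None, None
        L = config.read_length
        ramp_rate, ramp_k = self.em.end_ramp
        self.ramp = np.zeros(L)
        if ramp_k > 0:
            k = min(ramp_k, L)
            self.ramp[L - k :] = ramp_rate * np.arange(1, k + 1)

    def emit(
        self,
        frag: _Fragment,
        mate: int,
        left: bool,
        query_name: str,
        truth: SimulationTruth,
        tags: dict,
        is_duplicate: bool,
    ) -> AlignedReadRecord:
        cfg, em, rng = self.cfg, self.em, self.rng
        L = cfg.read_length
        start = frag.start if left else frag.start + frag.insert - L
        strand = FORWARD if left else REVERSE
        true_ref = self.genome[start : start + L].tobytes().decode()
        true_read = true_ref if strand == FORWARD else revcomp(true_ref)
        true_arr = np.frombuffer(true_read.encode(), dtype="S1").copy()

        # --- error rate vector (read space) ---
        base_rate = em.base_rate_r1 if mate == 1 else em.base_rate_r2
        boost = em.short_insert_r2_boost
        biased = (
            boost is not None
            and mate == 2
            and abs(frag.insert) < boost.threshold
            and boost.multiplier != 1.0
        )
        if biased and self.boost_marg is not None:
            idx = np.searchsorted(
                np.frombuffer(b"ACGT", dtype="S1"), true_arr
            )  # maps A,C,G,T -> 0..3 (background has no N)
            rate = base_rate * boost.multiplier * 4.0 * self.boost_marg[idx]
        elif biased:
            rate = np.full(L, base_rate * boost.multiplier)
        else:
            rate = np.full(L, base_rate)
        rate = rate + self.ramp

        # --- post-repeat burst ---
        burst = em.post_repeat_burst
        if burst is not None and burst.multiplier != 1.0:
            for feat in self.burst_features:
                if not (start < feat.end and feat.start < start + L):
                    continue
                exit_i = (
                    feat.end - start if strand == FORWARD else start + L - feat.start
                )
                if exit_i < 1 or exit_i >= L:
                    continue
                d = np.arange(L - exit_i)
                s = np.where(
                    d < burst.plateau,
                    1.0,
                    np.exp(-(d - burst.plateau) / burst.decay),
                )
                rate[exit_i:] = rate[exit_i:] * (1.0 + (burst.multiplier - 1.0) * s)

        np.clip(rate, 0.0, 0.95, out=rate)
        err = rng.random(L) < rate

        emitted = true_arr.copy()
        err_idx = np.flatnonzero(err)
        for i in err_idx:
            b = true_arr[i].decode()
            if b == "N":
                err[i] = False
                continue
            if biased and self.boost_alts is not None:
                opts, probs = self.boost_alts[b]
                emitted[i] = rng.choice(opts, p=probs).encode()
            else:
                opts = [a for a in "ACGT" if a != b]
                emitted[i] = opts[rng.integers(0, 3)].encode()

        quals = np.full(L, em.quality_given_correct, dtype=np.int64)
        quals[err] = em.quality_given_error

        # --- G4 effect (opposite-strand reads entering a motif) ---
        clip_from: int | None = None
        g4 = em.g4_effect
        if g4 is not None and (
            g4.quality_drop or g4.softclip_prob or g4.c_excess
        ):
            for feat in self.g4_features:
                if feat.strand == strand:
                    continue
                entry = _motif_entry(start, L, strand, feat)
                if entry is None:
                    continue
                quals[entry:] = np.maximum(quals[entry:] - g4.quality_drop, 2)
                if rng.random() < g4.softclip_prob:
                    clip_from = entry
                    n_clip = L - entry
                    cw = g4.clip_c_weight
                    p = np.array([(1 - cw) / 3, cw, (1 - cw) / 3, (1 - cw) / 3])
                    fill = BASES[rng.choice(4, size=n_clip, p=p)]
                    emitted[entry:] = np.char.encode(fill)
                    truth.clip_events.append((query_name, mate, feat.label))
                elif g4.c_excess > 0:
                    span_end = min(L, entry + len(feat))
                    forced = rng.random(span_end - entry) < g4.c_excess
                    emitted[entry:span_end][forced] = b"C"
                break  # motifs are planted isolated; at most one entry matters

        # --- truth substitutions (aligned columns only) ---
        aligned_end = clip_from if clip_from is not None else L
        mism = np.flatnonzero(
            (emitted[:aligned_end] != true_arr[:aligned_end])
            & (true_arr[:aligned_end] != b"N")
        )
        for i in mism:
            truth.substitutions.append(
                (
                    query_name,
                    mate,
                    int(i) + 1,
                    true_arr[i].decode(),
                    emitted[i].decode(),
                )
            )

        # --- SAM-space record ---
        read_seq = emitted.tobytes().decode()
        if strand == FORWARD:
            sam_seq = read_seq
            sam_quals = quals.tolist()
            if clip_from is None:
                cigar = [("M", L)]
                pos = start
            else:
                cigar = [("M", clip_from), ("S", L - clip_from)]
                pos = start
        else:
            sam_seq = revcomp(read_seq)
            sam_quals = quals[::-1].tolist()
            if clip_from is None:
                cigar = [("M", L)]
                pos = start
            else:
                cigar = [("S", L - clip_from), ("M", clip_from)]
                pos = start + L - clip_from

        tlen = frag.insert if left else -frag.insert
        feats = tuple(
            f.label
            for f in self.features
            if start < f.end and f.start < start + L
        )
        if feats:
            truth.read_features[(query_name, mate)] = feats
        return AlignedReadRecord(
            query_name=query_name,
            reference_name=cfg.chrom,
            position=pos,
            strand=strand,
            mate_rank=mate,
            mapq=60,
            cigar=cigar,
            bases=sam_seq,
            base_qualities=sam_quals,
            template_length=tlen,
            is_duplicate=is_duplicate,
            tags=tags,
        )


# ---------------------------------------------------------------------------
# fragment / duplicate generation
# ---------------------------------------------------------------------------


def _mutate_genome(
    reference: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    if rate <= 0:
        return reference, []
    arr = np.frombuffer(reference.encode(), dtype="S1").copy()
    pos = np.flatnonzero(rng.random(len(arr)) < rate)
    positions = []
    for p in pos:
        b = arr[p].decode()
        if b == "N":
            continue
        opts = [a for a in "ACGT" if a != b]
        arr[p] = opts[rng.integers(0, 3)].encode()
        positions.append(int(p))
    return arr.tobytes().decode(), positions


def simulate_reads(
    config: SimulationConfig,
    reference: str,
    features: IntervalSet,
    read_seed: int | None = None,
) -> tuple[list[AlignedReadRecord], SimulationTruth]:
    """Emit coordinate-sorted aligned paired-end records plus ground truth.

    The fragment count is set so that non-duplicate reads alone give the
    configured mean depth; duplicate copies are emitted on top, flagged, and
    tagged with their group id (``DI``) and injected category (``DC``).
    ``read_seed`` overrides the sampling seed so several read datasets
    (e.g. run replicates over one reference) can share a configuration.
    """
    rng = np.random.default_rng(config.seed + 1 if read_seed is None else read_seed)
    G, L = config.genome_length, config.read_length
    truth = SimulationTruth()
    sample_genome, truth_variants = _mutate_genome(reference, config.variant_rate, rng)
    truth.variant_positions = truth_variants

    n_frags = int(round(config.depth * G / (2 * L)))
    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_frags)),
        L,
        G,
    ).astype(int)
    starts = rng.integers(0, G - inserts + 1)
    read1_left = rng.random(n_frags) < 0.5

    emitter = _ReadEmitter(config, sample_genome, features, rng)
    tiles = [str(1101 + t) for t in range(config.n_tiles)]
    dup_rates = config.duplicate_rates
    records: list[AlignedReadRecord] = []

    name_seed = config.seed + 1 if read_seed is None else read_seed

    def _name(frag_id: int, copy: int, tile: str, x: int, y: int) -> str:
        return f"SIM:{name_seed}:{frag_id}.{copy}:{tile}:{x}:{y}"

    for fi in range(n_frags):
        frag = _Fragment(fi, int(starts[fi]), int(inserts[fi]), bool(read1_left[fi]))
        truth.fragments.append((fi, frag.start, frag.insert, frag.read1_left))
        tile_i = int(rng.integers(0, config.n_tiles))
        x = int(rng.integers(0, config.tile_size))
        y = int(rng.integers(0, config.tile_size))

        copies: list[tuple[str, str, int, int]] = []  # (category, tile, x, y)
        for cat in ("optical", "complementary", "pcr_like"):
            p = dup_rates.get(cat, 0.0)
            if p > 0 and rng.random() < p:
                if cat == "optical":
                    # 99 rather than 100: integer pixel rounding may add up
                    # to ~0.71, and the copy must stay within the proximal
                    # threshold by construction
                    dist = rng.uniform(0, 99)
                    theta = rng.uniform(0, 2 * math.pi)
                    cx = min(max(int(round(x + dist * math.cos(theta))), 0),
                             config.tile_size - 1)
                    cy = min(max(int(round(y + dist * math.sin(theta))), 0),
                             config.tile_size - 1)
                    copies.append((cat, tiles[tile_i], cx, cy))
                elif cat == "complementary":
                    ct = int(rng.integers(0, config.n_tiles))
                    copies.append(
                        (cat, tiles[ct],
                         int(rng.integers(0, config.tile_size)),
                         int(rng.integers(0, config.tile_size)))
                    )
                else:  # pcr_like: guaranteed different tile
                    ct = int((tile_i + 1 + rng.integers(0, config.n_tiles - 1))
                             % config.n_tiles)
                    copies.append(
                        (cat, tiles[ct],
                         int(rng.integers(0, config.tile_size)),
                         int(rng.integers(0, config.tile_size)))
                    )

        group = [("primary", tiles[tile_i], x, y)] + copies
        has_group = len(group) > 1
        for ci, (cat, tile, cx, cy) in enumerate(group):
            qname = _name(fi, ci, tile, cx, cy)
            tags: dict = {"DC": cat}
            if has_group:
                tags["DI"] = fi
                truth.duplicates.append((qname, cat, fi))
            r1_left = frag.read1_left
            if cat == "complementary":
                r1_left = not r1_left  # opposing strand: mate roles swap ends
            for mate in (1, 2):
                left = r1_left if mate == 1 else not r1_left
                records.append(
                    emitter.emit(
                        frag, mate, left, qname, truth, dict(tags), cat != "primary"
                    )
                )

    if config.quality_binning == "four_bin":
        bin_qualities(records)
    records.sort(key=lambda r: (r.reference_name, r.position, r.query_name, r.mate_rank))
    return records, truth


# ---------------------------------------------------------------------------
# quality binning
# ---------------------------------------------------------------------------

_FOUR_BIN_EDGES = np.array([3, 18, 30])
_FOUR_BIN_VALUES = np.array([2, 12, 24, 40])


def bin_quality_value(q: int) -> int:
    """Four-bin coarse quality map: Q0-2 -> 2, Q3-17 -> 12, Q18-29 -> 24,
    Q30+ -> 40."""
    return int(_FOUR_BIN_VALUES[np.searchsorted(_FOUR_BIN_EDGES, q, side="right")])


def bin_qualities(
    records: Sequence[AlignedReadRecord], scheme: str = "four_bin"
) -> Sequence[AlignedReadRecord]:
    """Replace base qualities in place with their coarse-bin values; base
    calls are untouched."""
    if scheme != "four_bin":
        raise ValueError(f"unknown binning scheme {scheme!r}")
    for rec in records:
        q = np.asarray(rec.base_qualities)
        rec.base_qualities = _FOUR_BIN_VALUES[
            np.searchsorted(_FOUR_BIN_EDGES, q, side="right")
        ].tolist()
    return records
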