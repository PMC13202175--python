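"""G-quadruplex motif handling, recurrent soft-clip site discovery, and
strand-aware pileup profiling around isolated motifs.

G-quadruplexes (G4) are four-stranded structures formed by four guanine
runs separated by short loops.  They form on one strand only, so their
effect on sequencing is inherently strand-specific: reads synthesizing
across a G4-carrying template tend to lose quality and get soft-clipped by
the aligner where the called bases diverge.  The discovery pipeline finds
loci of recurrent, strand-specific soft-clipping shared across run
replicates and subjects, removes dual-strand loci (a structural-variant
signature, not a G4 one), subtracts control-platform loci, and relates the
survivors to predicted G4 motifs by strand.

The built-in canonical motif finder (``G{3,}(N{1,7}G{3,}){3}``) is a
simplified stand-in for dedicated G4 predictors, sufficient for synthetic
sequence; genome-scale predictions are consumed as BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, coverage_select
from .records import FORWARD, REVERSE, AlignedReadRecord

_G4_FWD = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}")
_G4_REV = re.compile(r"C{3,}(?:[ACGTN]{1,7}C{3,}){3}")

RELATIONS = ("same", "opposite", "both", "none")


def find_g4_motifs(sequence: str, chrom: str = "seq") -> list[GenomicInterval]:
    """Canonical G4 motifs on both strands of a sequence.

    Forward-strand motifs are maximal non-overlapping matches of four
    3+ G-runs with 1-7 base loops; the C-run form on the forward sequence
    is reported as a reverse-strand motif (G-runs on the reverse strand).
    Matches whose G-runs contain N are impossible by construction (the run
    classes exclude N; loops may contain it).
    """
    seq = sequence.upper()
    out = []
    for pattern, strand in ((_G4_FWD, "+"), (_G4_REV, "-")):
        for m in pattern.finditer(seq):
            out.append(
                GenomicInterval(chrom, m.start(), m.end(), strand, "g4_motif")
            )
    return sorted(out, key=lambda iv: (iv.start, iv.strand))


# ---------------------------------------------------------------------------
# soft-clip site discovery
# ---------------------------------------------------------------------------


def extract_softclip_spans(
    reads: Iterable[AlignedReadRecord],
    min_clip: int = 10,
    min_mapq: int = 60,
    min_tlen: int = 150,
    chroms: set[str] | None = None,
) -> dict[str, IntervalSet]:
    """Aligned spans of extensively soft-clipped reads, split by strand.

    A read qualifies when its *total* soft-clipped length (both ends
    summed) is at least ``min_clip``, MAPQ passes the floor, absolute
    template length exceeds ``min_tlen`` and, when ``chroms`` is given, it
    maps to an allowed chromosome.  The span is the aligned span with clips
    excluded (standard alignment-to-BED semantics); downstream slop
    recovers adjacency.
    """
    spans: dict[str, list[GenomicInterval]] = {FORWARD: [], REVERSE: []}
    for rec in reads:
        if rec.softclip_total < min_clip:
            continue
        if rec.mapq < min_mapq or abs(rec.template_length) <= min_tlen:
            continue
        if chroms is not None and rec.reference_name not in chroms:
            continue
        spans[rec.strand].append(
            GenomicInterval(
                rec.reference_name, rec.position, rec.reference_end, rec.strand
            )
        )
    return {s: IntervalSet(v).sorted() for s, v in spans.items()}


@dataclass
class SoftClipSite:
    interval: GenomicInterval
    supporting_reads: int
    shared_across_runs: bool = True
    shared_subjects: int = 0
    control_subtracted: bool = False

    @property
    def strand(self) -> str:
        return self.interval.strand


def _per_subject_loci(
    runs: Mapping[str, Mapping[str, IntervalSet]],
    strand: str,
    chrom_sizes: Mapping[str, int],
    slop: int,
    min_reads: int,
) -> IntervalSet:
    """Slop, merge-with-count and read-count filter per run, then base-level
    intersection across all of a subject's runs."""
    per_run = []
    for run_spans in runs.values():
        spans = run_spans.get(strand, IntervalSet())
        merged = spans.slop(slop, chrom_sizes).merge_count()
        kept = IntervalSet(
            [iv for iv, c in zip(merged.intervals, merged.counts) if c >= min_reads],
            [c for c in merged.counts if c >= min_reads],
        )
        per_run.append(kept)
    if not per_run:
        return IntervalSet()
    out = per_run[0]
    for other in per_run[1:]:
        out = out.intersect(other)
    return out


def discover_clip_sites(
    datasets: Mapping[str, Mapping[str, Mapping[str, IntervalSet]]],
    chrom_sizes: Mapping[str, int],
    slop: int = 10,
    min_reads: int = 2,
    min_subjects: int = 2,
    control: Mapping[str, Mapping[str, Mapping[str, IntervalSet]]] | None = None,
) -> list[SoftClipSite]:
    """Recurrent strand-specific soft-clip loci.

    ``datasets`` maps subject -> run -> strand -> clipped-read span set.
    Per strand the pipeline is: slop each dataset's spans, merge counting
    overlapping reads, keep loci with at least ``min_reads`` reads,
    intersect across each subject's runs, keep loci present in at least
    ``min_subjects`` subjects, drop loci overlapping a surviving locus on
    the other strand (both strands dropped), and finally subtract control
    loci computed through the same per-strand pipeline.  Empty inputs give
    an empty result.
    """
    per_strand: dict[str, IntervalSet] = {}
    counts_by_strand: dict[str, IntervalSet] = {}
    for strand in (FORWARD, REVERSE):
        subject_sets = [
            _per_subject_loci(runs, strand, chrom_sizes, slop, min_reads)
            for runs in datasets.values()
        ]
        per_strand[strand] = coverage_select(subject_sets, min_subjects)
        # read-support lookup: all runs' merged spans with counts
        allspans: list[GenomicInterval] = []
        allcounts: list[int] = []
        for runs in datasets.values():
            for run_spans in runs.values():
                m = run_spans.get(strand, IntervalSet()).slop(
                    slop, chrom_sizes
                ).merge_count()
                allspans.extend(m.intervals)
                allcounts.extend(m.counts)
        counts_by_strand[strand] = IntervalSet(allspans, allcounts)

    # dual-strand exclusion (symmetric, against pre-exclusion survivors)
    fwd, rev = per_strand[FORWARD], per_strand[REVERSE]
    kept = {
        FORWARD: _drop_overlapping(fwd, rev),
        REVERSE: _drop_overlapping(rev, fwd),
    }

    control_subtracted = control is not None
    if control is not None:
        for strand in (FORWARD, REVERSE):
            ctrl_subjects = [
                _per_subject_loci(runs, strand, chrom_sizes, slop, min_reads)
                for runs in control.values()
            ]
            need = min(min_subjects, max(len(ctrl_subjects), 1))
            ctrl = coverage_select(ctrl_subjects, need)
            kept[strand] = kept[strand].subtract(ctrl)

    n_subjects = len(datasets)
    sites = []
    for strand in (FORWARD, REVERSE):
        for iv in kept[strand]:
            support = sum(
                c
                for siv, c in zip(
                    counts_by_strand[strand].intervals,
                    counts_by_strand[strand].counts,
                )
                if siv.overlaps(iv)
            )
            sites.append(
                SoftClipSite(
                    GenomicInterval(iv.chrom, iv.start, iv.end, strand, "clip_site"),
                    supporting_reads=support,
                    shared_subjects=min(min_subjects, n_subjects),
                    control_subtracted=control_subtracted,
                )
            )
    return sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.strand))


def _drop_overlapping(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    keep = [iv for iv in a if not any(iv.overlaps(o) for o in b)]
    return IntervalSet(keep)


# ---------------------------------------------------------------------------
# motif relations and isolation
# ---------------------------------------------------------------------------


def overlap_with_motifs(
    sites: Sequence[SoftClipSite], motifs: Sequence[GenomicInterval]
) -> dict[str, int]:
    """Classify every site by its strand relation to overlapping motifs:
    same-strand only, opposite-strand only, both, or no overlap."""
    counts = dict.fromkeys(RELATIONS, 0)
    for site in sites:
        same = opposite = False
        for m in motifs:
            if site.interval.overlaps(m):
                if m.strand == site.strand:
                    same = True
                else:
                    opposite = True
        if same and opposite:
            counts["both"] += 1
        elif same:
            counts["same"] += 1
        elif opposite:
            counts["opposite"] += 1
        else:
            counts["none"] += 1
    return counts


def isolated_motifs(
    motifs: Sequence[GenomicInterval], min_gap: int = 300, max_len: int = 50
) -> list[GenomicInterval]:
    """Motifs suitable for single-site pileups: length at most ``max_len``
    and at least ``min_gap`` bases from the nearest other motif on either
    strand (both members of a close pair are removed)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    out = []
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda iv: iv.start)
        for i, m in enumerate(ms):
            if len(m) > max_len:
                continue
            near = False
            if i > 0 and m.start - ms[i - 1].end < min_gap:
                near = True
            if i + 1 < len(ms) and ms[i + 1].start - m.end < min_gap:
                near = True
            if not near:
                out.append(m)
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


# ---------------------------------------------------------------------------
# pileup profiling
# ---------------------------------------------------------------------------

_BASE_IDX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
_COMP_IDX = {b"A": 3, b"C": 2, b"G": 1, b"T": 0}  # read-orientation index
MAX_QUAL = 60


@dataclass
class PileupProfile:
    """Quality and mismatch pileups on a motif-anchored axis.

    Reads are grouped by their strand relative to the motif ("same" /
    "opposite") and their offsets are mirrored into sequencing direction,
    so the zones mean: ``before`` = flank sequenced before reaching the
    motif, ``inside`` = within it, ``after`` = flank sequenced after it.
    Mismatch bases are recorded in read orientation.
    """

    flank: int
    inside_len: int
    depth: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    qual_hist: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    mismatch: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    ZONES = ("before", "inside", "after")
    GROUPS = ("same", "opposite")

    def __post_init__(self) -> None:
        sizes = {"before": self.flank, "inside": self.inside_len,
                 "after": self.flank}
        for g in self.GROUPS:
            for z, n in sizes.items():
                self.depth.setdefault((g, z), np.zeros(n, dtype=np.int64))
                self.qual_hist.setdefault(
                    (g, z), np.zeros((n, MAX_QUAL + 1), dtype=np.int64)
                )
                self.mismatch.setdefault((g, z), np.zeros((n, 4), dtype=np.int64))

    def mean_quality(self, group: str, zone: str) -> np.ndarray:
        hist = self.qual_hist[group, zone]
        totals = hist.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (hist @ np.arange(MAX_QUAL + 1)) / totals

    def quality_quartiles(self, group: str, zone: str) -> np.ndarray:
        """(n_offsets, 3) array of Q25/Q50/Q75 per offset."""
        hist = self.qual_hist[group, zone]
        out = np.full((hist.shape[0], 3), np.nan)
        for i, row in enumerate(hist):
            tot = row.sum()
            if tot == 0:
                continue
            cum = np.cumsum(row)
            for j, q in enumerate((0.25, 0.5, 0.75)):
                out[i, j] = np.searchsorted(cum, q * tot)
        return out

    def mismatch_composition(self, group: str, zone: str = "inside") -> np.ndarray:
        """Fraction of mismatches by read base (A, C, G, T) in the zone."""
        tot = self.mismatch[group, zone].sum(axis=0)
        s = tot.sum()
        return tot / s if s else np.full(4, np.nan)


def profile_motif_pileup(
    reads: Iterable[AlignedReadRecord],
    motifs: Sequence[GenomicInterval],
    reference: Mapping[str, str],
    flank: int = 150,
    min_side_cover: int = 5,
    min_mapq: int = 0,
    exclude_duplicates: bool = True,
    orientation: str = "read",
) -> PileupProfile:
    """Pileup of base qualities and mismatches around isolated motifs.

    Only reads whose aligned span covers a motif by at least
    ``min_side_cover`` bases on each side contribute (no base-quality
    floor).  Raises if any motif's flank window touches another motif --
    callers should isolate motifs first.  ``orientation="reference"``
    keeps the offset axis in reference direction instead of mirroring
    reverse-strand reads into sequencing direction.
    """
    if orientation not in ("read", "reference"):
        raise ValueError(f"unknown orientation {orientation!r}")
    motifs = sorted(motifs, key=lambda m: (m.chrom, m.start))
    for a, b in zip(motifs, motifs[1:]):
        if a.chrom == b.chrom and b.start < a.end + flank:
            raise ValueError(
                f"motif at {b.chrom}:{b.start} not isolated within flank"
            )
    inside_len = max((len(m) for m in motifs), default=1)
    profile = PileupProfile(flank, inside_len)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    ref_cache: dict[str, np.ndarray] = {}

    for rec in reads:
        if rec.mapq < min_mapq or (exclude_duplicates and rec.is_duplicate):
            continue
        ms = by_chrom.get(rec.reference_name)
        if ms is None:
            if rec.reference_name not in reference:
                raise KeyError(f"unknown contig {rec.reference_name!r}")
            continue
        if rec.reference_name not in ref_cache:
            ref_cache[rec.reference_name] = np.frombuffer(
                reference[rec.reference_name].encode(), dtype="S1"
            )
        ref = ref_cache[rec.reference_name]
        for m in ms:
            if (
                rec.position <= m.start - min_side_cover
                and rec.reference_end >= m.end + min_side_cover
            ):
                _pile_read(profile, rec, ref, m, flank, orientation)
    return profile


def _pile_read(
    profile: PileupProfile,
    rec: AlignedReadRecord,
    ref: np.ndarray,
    motif: GenomicInterval,
    flank: int,
    orientation: str = "read",
) -> None:
    group = "same" if rec.strand == motif.strand else "opposite"
    read = np.frombuffer(rec.bases.encode(), dtype="S1")
    quals = np.asarray(rec.base_qualities)
    base_idx = _BASE_IDX if rec.strand == FORWARD else _COMP_IDX
    lo, hi = motif.start - flank, motif.end + flank
    for qs, rs, n in rec.aligned_blocks():
        s, e = max(rs, lo, 0), min(rs + n, hi, len(ref))
        if s >= e:
            continue
        rpos = np.arange(s, e)
        qpos = np.arange(qs + (s - rs), qs + (e - rs))
        if rec.strand == FORWARD or orientation == "reference":
            before = motif.start - rpos
            after = rpos - motif.end + 1
            inside = rpos - motif.start
        else:
            before = rpos - motif.end + 1
            after = motif.start - rpos
            inside = motif.end - 1 - rpos
        refseg, readseg, q = ref[rpos], read[qpos], quals[qpos]
        mism = (refseg != readseg) & (refseg != b"N") & (readseg != b"N")
        for zone, offs in (("before", before), ("after", after)):
            sel = (offs >= 1) & (offs <= flank)
            _pile_zone(profile, group, zone, offs[sel] - 1, q[sel],
                       readseg[sel], mism[sel], base_idx)
        sel = (inside >= 0) & (inside < len(motif))
        _pile_zone(profile, group, "inside", inside[sel], q[sel],
                   readseg[sel], mism[sel], base_idx)


def _pile_zone(profile, group, zone, offs, quals, bases, mism, base_idx) -> None:
    np.add.at(profile.depth[group, zone], offs, 1)
    np.add.at(
        profile.qual_hist[group, zone],
        (offs, np.clip(quals, 0, MAX_QUAL)),
        1,
    )
    if mism.any():
        mo = offs[mism]
        mb = bases[mism]
        for o, b in zip(mo, mb):
            idx = base_idx.get(bytes(b))
            if idx is not None:
                profile.mismatch[group, zone][o, idx] += 1
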