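"""Strand-aware error profiles around interval sets and the
downstream-vs-upstream change statistic.

For every interval (e.g. a repeat stratification region) and every
MAPQ-passing read overlapping it, aligned columns within the flanks and the
region itself are stacked onto a common offset grid.  Reads are split by
alignment strand and the offset axis of reverse-strand reads is mirrored,
so "downstream" always means *later sequencing cycles*: post-repeat
synthesis errors are directional along the read, not along the reference.

The change statistic compares the mean error rate over the 50 flank bases
nearest the region downstream against the same window upstream, reported
both as a ratio and as an additive difference.  A control set of short
random regions calibrates the null (ratio ~ 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .records import FORWARD, REVERSE, AlignedReadRecord

STRANDS = (FORWARD, REVERSE)


@dataclass
class StackedProfile:
    """Aggregate aligned-base / substitution counts per strand and offset.

    Offsets are in sequencing direction: ``upstream[d]`` is the flank base
    ``d+1`` before the region, ``inside[i]`` is region offset ``i`` from
    the entry edge, ``downstream[d]`` is flank base ``d+1`` after the
    region.
    """

    flank: int
    inside_len: int
    bases: dict[tuple[str, str], np.ndarray]
    errors: dict[tuple[str, str], np.ndarray]

    ZONES = ("upstream", "inside", "downstream")

    @classmethod
    def empty(cls, flank: int, inside_len: int) -> "StackedProfile":
        sizes = {"upstream": flank, "inside": inside_len, "downstream": flank}
        return cls(
            flank,
            inside_len,
            {(s, z): np.zeros(n, dtype=np.int64)
             for s in STRANDS for z, n in sizes.items()},
            {(s, z): np.zeros(n, dtype=np.int64)
             for s in STRANDS for z, n in sizes.items()},
        )

    def rate(self, strand: str, zone: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.errors[strand, zone] / self.bases[strand, zone]

    def add(self, other: "StackedProfile") -> "StackedProfile":
        assert self.flank == other.flank and self.inside_len == other.inside_len
        for key in self.bases:
            self.bases[key] += other.bases[key]
            self.errors[key] += other.errors[key]
        return self

    def mirrored(self) -> "StackedProfile":
        """Profile with the two strand labels exchanged."""
        swap = {FORWARD: REVERSE, REVERSE: FORWARD}
        return StackedProfile(
            self.flank,
            self.inside_len,
            {(swap[s], z): a.copy() for (s, z), a in self.bases.items()},
            {(swap[s], z): a.copy() for (s, z), a in self.errors.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand in STRANDS:
            for zone in self.ZONES:
                rate = self.rate(strand, zone)
                for i, (b, e) in enumerate(
                    zip(self.bases[strand, zone], self.errors[strand, zone])
                ):
                    rows.append((strand, zone, i + 1, int(b), int(e), rate[i]))
        return pd.DataFrame(
            rows, columns=["strand", "zone", "offset", "bases", "errors", "rate"]
        )


def stack_by_interval(
    reads: Iterable[AlignedReadRecord],
    reference: Mapping[str, str],
    intervals: IntervalSet,
    flank: int,
    min_mapq: int = 60,
    exclude_duplicates: bool = True,
    orientation: str = "read",
) -> StackedProfile:
    """Stack per-column substitution calls around every interval.

    Only reads overlapping an interval itself contribute; their aligned
    columns within ``[start - flank, end + flank)`` land on the offset grid,
    mirrored for reverse-strand reads.  Intervals reaching past contig
    bounds are clipped.  ``orientation="reference"`` keeps the offset axis
    in reference direction for both strands instead of mirroring.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if orientation not in ("read", "reference"):
        raise ValueError(f"unknown orientation {orientation!r}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    inside_len = max((len(iv) for iv in ivs), default=1)
    profile = StackedProfile.empty(flank, inside_len)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    ref_cache: dict[str, np.ndarray] = {}

    for rec in reads:
        if rec.mapq < min_mapq or (exclude_duplicates and rec.is_duplicate):
            continue
        chrom_ivs = by_chrom.get(rec.reference_name)
        if not chrom_ivs:
            continue
        if rec.reference_name not in ref_cache:
            seq = reference[rec.reference_name]
            ref_cache[rec.reference_name] = np.frombuffer(seq.encode(), dtype="S1")
        ref = ref_cache[rec.reference_name]
        r_start, r_end = rec.position, rec.reference_end
        # reads must overlap the region itself
        for iv in chrom_ivs:
            if iv.start >= r_end:
                break
            if iv.end <= r_start:
                continue
            _stack_read(profile, rec, ref, iv, flank, orientation)
    return profile


def _stack_read(
    profile: StackedProfile,
    rec: AlignedReadRecord,
    ref: np.ndarray,
    iv: GenomicInterval,
    flank: int,
    orientation: str = "read",
) -> None:
    lo, hi = iv.start - flank, iv.end + flank
    read = np.frombuffer(rec.bases.encode(), dtype="S1")
    for qs, rs, n in rec.aligned_blocks():
        s, e = max(rs, lo, 0), min(rs + n, hi, len(ref))
        if s >= e:
            continue
        rpos = np.arange(s, e)
        qpos = np.arange(qs + (s - rs), qs + (e - rs))
        refseg = ref[rpos]
        readseg = read[qpos]
        valid = (refseg != b"N") & (readseg != b"N")
        mism = valid & (refseg != readseg)
        if rec.strand == FORWARD or orientation == "reference":
            before = iv.start - rpos  # >0 in upstream flank
            after = rpos - iv.end + 1  # >0 in downstream flank
            inside_off = rpos - iv.start
        else:
            before = rpos - iv.end + 1
            after = iv.start - rpos
            inside_off = iv.end - 1 - rpos
        for zone, offs in (
            ("upstream", before),
            ("downstream", after),
        ):
            sel = valid & (offs >= 1) & (offs <= flank)
            np.add.at(profile.bases[rec.strand, zone], offs[sel] - 1, 1)
            selm = mism & (offs >= 1) & (offs <= flank)
            np.add.at(profile.errors[rec.strand, zone], offs[selm] - 1, 1)
        sel = valid & (inside_off >= 0) & (inside_off < len(iv))
        np.add.at(profile.bases[rec.strand, "inside"], inside_off[sel], 1)
        selm = mism & (inside_off >= 0) & (inside_off < len(iv))
        np.add.at(profile.errors[rec.strand, "inside"], inside_off[selm], 1)


@dataclass
class ErrorChange:
    """Downstream-vs-upstream change over the ``window`` flank bases
    nearest the region, per strand."""

    ratio: float
    difference: float
    upstream_rate: float
    downstream_rate: float
    upstream_bases: int
    downstream_bases: int
    zero_upstream_guarded: bool = False


def error_change(
    profile: StackedProfile, window: int = 50
) -> dict[str, ErrorChange]:
    """Mean downstream rate over the window divided by the mean upstream
    rate (plus the additive difference).  An upstream mean of exactly zero
    is guarded with 1/n and flagged; zero denominator bases yield NaN."""
    if profile.flank < window:
        raise ValueError("flank smaller than change window")
    out = {}
    for strand in STRANDS:
        ub = int(profile.bases[strand, "upstream"][:window].sum())
        ue = int(profile.errors[strand, "upstream"][:window].sum())
        db = int(profile.bases[strand, "downstream"][:window].sum())
        de = int(profile.errors[strand, "downstream"][:window].sum())
        out[strand] = _change_from_counts(ue, ub, de, db)
    return out


def _change_from_counts(ue: int, ub: int, de: int, db: int) -> ErrorChange:
    if ub == 0 or db == 0:
        return ErrorChange(math.nan, math.nan, math.nan, math.nan, ub, db)
    up = ue / ub
    down = de / db
    if ue == 0 and de == 0:
        # no errors on either flank: no change is measurable
        return ErrorChange(math.nan, 0.0, up, down, ub, db)
    guarded = False
    denom = up
    if denom == 0.0:
        denom = 1.0 / ub
        guarded = True
    return ErrorChange(down / denom, down - up, up, down, ub, db, guarded)


def pooled_error_change(profile: StackedProfile, window: int = 50) -> ErrorChange:
    """Change statistic pooling both strand profiles (each already in
    sequencing direction)."""
    ub = de = db = ue = 0
    for strand in STRANDS:
        ub += int(profile.bases[strand, "upstream"][:window].sum())
        ue += int(profile.errors[strand, "upstream"][:window].sum())
        db += int(profile.bases[strand, "downstream"][:window].sum())
        de += int(profile.errors[strand, "downstream"][:window].sum())
    return _change_from_counts(ue, ub, de, db)


def random_control_intervals(
    chrom_sizes: Mapping[str, int],
    n: int,
    length: int = 30,
    seed: int = 0,
) -> IntervalSet:
    """n random intervals of fixed length, chromosomes weighted by length;
    chromosomes shorter than the interval length are excluded."""
    rng = np.random.default_rng(seed)
    chroms = [c for c, size in chrom_sizes.items() if size >= length]
    if not chroms or n == 0:
        return IntervalSet()
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=n, p=weights)
    out = []
    for i in picks:
        c = chroms[i]
        start = int(rng.integers(0, chrom_sizes[c] - length + 1))
        out.append(GenomicInterval(c, start, start + length, label="random_control"))
    return IntervalSet(out).sorted()


def subsample_intervals(
    intervals: IntervalSet, max_n: int = 10_000, seed: int = 0
) -> IntervalSet:
    """Uniform without-replacement sample of at most ``max_n`` intervals
    (identity when the set is already small enough)."""
    if len(intervals) <= max_n:
        return intervals
    rng = np.random.default_rng(seed)
    keep = sorted(rng.choice(len(intervals), size=max_n, replace=False).tolist())
    return IntervalSet(
        [intervals[i] for i in keep], [intervals.counts[i] for i in keep]
    )
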