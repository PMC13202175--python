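"""Substitution error profiling by cycle, insert size and substitution type.

Two complementary error measures are implemented:

* **reference-based**: every aligned base that differs from the reference
  is counted as an error at its sequencing cycle.  This conflates true
  sample-vs-reference variants with sequencing errors but needs only one
  read per locus.
* **overlap-based**: for proper pairs with inserts shorter than twice the
  read length the two mates resequence the same molecule; disagreements
  between them within the overlap are sequencing errors by construction,
  blind to true variants and pre-sequencing DNA damage.  Each disagreeing
  column charges one error to the mate with the lower base quality (after
  optional coarse binning of qualities on the error-probability scale);
  exact ties split 0.5/0.5.

Cycle indexing is 1-based in sequencing order: reverse-strand alignments
are flipped so cycle 1 is always the first sequenced base.  N bases and
indel/clipped columns are excluded from numerator and denominator
everywhere (substitution-only error definition).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import FORWARD, AlignedReadRecord

DEFAULT_MIN_MAPQ = 60

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: collapsed 6-type view, pyrimidine-reference form
COLLAPSED_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _collapse_key(sub: str) -> str:
    ref, alt = sub[0], sub[2]
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{_PAIR[ref]}>{_PAIR[alt]}"


def _passes(rec: AlignedReadRecord, min_mapq: int, exclude_duplicates: bool) -> bool:
    if rec.mapq < min_mapq:
        return False
    if exclude_duplicates and rec.is_duplicate:
        return False
    return True


def _ref_bytes(reference: Mapping[str, str], chrom: str) -> np.ndarray:
    try:
        seq = reference[chrom]
    except KeyError:
        raise KeyError(f"no reference sequence for contig {chrom!r}") from None
    return np.frombuffer(seq.encode(), dtype="S1")


# ---------------------------------------------------------------------------
# per-cycle reference-based profile
# ---------------------------------------------------------------------------


@dataclass
class CycleErrorProfile:
    """Aligned-base and substitution counts per mate and sequencing cycle."""

    read_length: int
    aligned_bases: dict[int, np.ndarray]
    substitutions: dict[int, np.ndarray]

    @classmethod
    def empty(cls, read_length: int) -> "CycleErrorProfile":
        return cls(
            read_length,
            {m: np.zeros(read_length, dtype=np.int64) for m in (1, 2)},
            {m: np.zeros(read_length, dtype=np.float64) for m in (1, 2)},
        )

    def rates(self, mate: int) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.substitutions[mate] / self.aligned_bases[mate]

    def smoothed(self, mate: int, window: int = 5) -> np.ndarray:
        return rolling_smooth(self.rates(mate), window)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mate in (1, 2):
            rate = self.rates(mate)
            smooth = self.smoothed(mate)
            for c in range(self.read_length):
                rows.append(
                    (mate, c + 1, int(self.aligned_bases[mate][c]),
                     float(self.substitutions[mate][c]), rate[c], smooth[c])
                )
        return pd.DataFrame(
            rows, columns=["mate", "cycle", "bases", "errors", "rate", "smoothed"]
        )


def _mismatch_columns(rec: AlignedReadRecord, ref: np.ndarray):
    """Yield (qpos array, valid mask, mismatch mask, ref bytes, read bytes)
    per aligned block."""
    read = np.frombuffer(rec.bases.encode(), dtype="S1")
    for qs, rs, n in rec.aligned_blocks():
        refseg = ref[rs : rs + n]
        readseg = read[qs : qs + n]
        valid = (refseg != b"N") & (readseg != b"N")
        mism = valid & (refseg != readseg)
        yield qs, n, valid, mism, refseg, readseg


def _cycles(rec: AlignedReadRecord, qs: int, n: int) -> np.ndarray:
    """1-based cycles of query positions qs..qs+n-1."""
    q = np.arange(qs, qs + n)
    if rec.strand == FORWARD:
        return q + 1
    return rec.query_length - q


def reference_error_by_cycle(
    reads: Iterable[AlignedReadRecord],
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    read_length: int | None = None,
    exclude_duplicates: bool = True,
) -> CycleErrorProfile:
    """Substitutions versus the reference aggregated per mate and cycle.

    Only aligned (non-clipped, non-indel) columns of reads passing the MAPQ
    floor contribute; for reverse-strand alignments the cycle is recovered
    as ``query_length - query_position``.
    """
    profile: CycleErrorProfile | None = None
    ref_cache: dict[str, np.ndarray] = {}
    for rec in reads:
        if not _passes(rec, min_mapq, exclude_duplicates):
            continue
        if profile is None:
            profile = CycleErrorProfile.empty(read_length or rec.query_length)
        if rec.reference_name not in ref_cache:
            ref_cache[rec.reference_name] = _ref_bytes(reference, rec.reference_name)
        ref = ref_cache[rec.reference_name]
        bases = profile.aligned_bases[rec.mate_rank]
        subs = profile.substitutions[rec.mate_rank]
        for qs, n, valid, mism, _, _ in _mismatch_columns(rec, ref):
            cyc = _cycles(rec, qs, n) - 1
            np.add.at(bases, cyc[valid], 1)
            np.add.at(subs, cyc[mism], 1.0)
    if profile is None:
        profile = CycleErrorProfile.empty(read_length or 0)
    return profile


def rolling_smooth(rates: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return (
        pd.Series(np.asarray(rates, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# overlap-based profile
# ---------------------------------------------------------------------------


@dataclass
class OverlapErrorProfile:
    """Per-mate, per-cycle error attributions from mate-overlap
    disagreements.  ``errors`` holds float counts (ties contribute 0.5);
    ``columns`` counts every overlapping column once per mate."""

    read_length: int
    errors: dict[int, np.ndarray]
    columns: dict[int, np.ndarray]
    disagreeing_columns: float = 0.0
    column_pairs: int = 0
    skipped_pairs: int = 0

    @classmethod
    def empty(cls, read_length: int) -> "OverlapErrorProfile":
        return cls(
            read_length,
            {m: np.zeros(read_length, dtype=np.float64) for m in (1, 2)},
            {m: np.zeros(read_length, dtype=np.int64) for m in (1, 2)},
        )

    def rates(self, mate: int) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.errors[mate] / self.columns[mate]

    def total_rate(self) -> float:
        """Total attributed errors over overlapping column pairs;
        estimates the summed per-base error rate of the two mates."""
        if self.column_pairs == 0:
            return math.nan
        return (self.errors[1].sum() + self.errors[2].sum()) / self.column_pairs

    def mate_share(self, mate: int) -> float:
        tot = self.errors[1].sum() + self.errors[2].sum()
        return self.errors[mate].sum() / tot if tot else math.nan


def _quality_bin(q: np.ndarray, width: float) -> np.ndarray:
    """Coarsen Phred qualities into bins of the given width on the [0, 1]
    error-probability scale (mirrors the overlap tool's binning hook)."""
    p = np.power(10.0, -q / 10.0)
    return np.floor(p / width).astype(np.int64)


def overlap_error_by_cycle(
    reads: Iterable[AlignedReadRecord],
    quality_bin_width: float | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    read_length: int | None = None,
    exclude_duplicates: bool = True,
) -> OverlapErrorProfile:
    """Sequencing-error rates from mate-pair overlap disagreements.

    Proper pairs with ``|template_length| < 2 * read_length`` contribute;
    at every reference column covered by aligned bases of both mates, a
    disagreement charges one error to the lower-quality mate (tie: 0.5
    each) at that mate's cycle.  ``quality_bin_width`` optionally coarsens
    qualities into bins of that width on the [0, 1] error-probability
    scale before the comparison (the interface of the external overlap
    tool); by default raw Phred values are compared.
    """
    profile: OverlapErrorProfile | None = None
    pending: dict[str, AlignedReadRecord] = {}
    for rec in reads:
        if not _passes(rec, min_mapq, exclude_duplicates):
            continue
        if profile is None:
            profile = OverlapErrorProfile.empty(read_length or rec.query_length)
        if abs(rec.template_length) >= 2 * rec.query_length:
            continue
        other = pending.pop(rec.query_name, None)
        if other is None:
            pending[rec.query_name] = rec
            continue
        if other.reference_name != rec.reference_name:
            profile.skipped_pairs += 1
            continue
        r1, r2 = (rec, other) if rec.mate_rank == 1 else (other, rec)
        _accumulate_overlap(profile, r1, r2, quality_bin_width)
    if profile is None:
        profile = OverlapErrorProfile.empty(read_length or 0)
    return profile


def _read_columns(rec: AlignedReadRecord, lo: int, hi: int):
    """(refpos, qpos) arrays for aligned columns within [lo, hi)."""
    rp, qp = [], []
    for qs, rs, n in rec.aligned_blocks():
        s, e = max(rs, lo), min(rs + n, hi)
        if s < e:
            rp.append(np.arange(s, e))
            qp.append(np.arange(qs + (s - rs), qs + (e - rs)))
    if not rp:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(rp), np.concatenate(qp)


def _accumulate_overlap(
    profile: OverlapErrorProfile,
    r1: AlignedReadRecord,
    r2: AlignedReadRecord,
    bin_width: float | None,
) -> None:
    lo = max(r1.position, r2.position)
    hi = min(r1.reference_end, r2.reference_end)
    if lo >= hi:
        return
    rp1, qp1 = _read_columns(r1, lo, hi)
    rp2, qp2 = _read_columns(r2, lo, hi)
    common, i1, i2 = np.intersect1d(rp1, rp2, return_indices=True)
    if common.size == 0:
        return
    q1, q2 = qp1[i1], qp2[i2]
    b1 = np.frombuffer(r1.bases.encode(), dtype="S1")[q1]
    b2 = np.frombuffer(r2.bases.encode(), dtype="S1")[q2]
    valid = (b1 != b"N") & (b2 != b"N")
    if not valid.any():
        return
    q1, q2, b1, b2 = q1[valid], q2[valid], b1[valid], b2[valid]
    cyc1 = np.where(
        r1.strand == FORWARD, q1 + 1, r1.query_length - q1
    ).astype(int) - 1
    cyc2 = np.where(
        r2.strand == FORWARD, q2 + 1, r2.query_length - q2
    ).astype(int) - 1
    np.add.at(profile.columns[1], cyc1, 1)
    np.add.at(profile.columns[2], cyc2, 1)
    profile.column_pairs += int(valid.sum())

    dis = b1 != b2
    if not dis.any():
        return
    qual1 = np.asarray(r1.base_qualities)[q1[dis]]
    qual2 = np.asarray(r2.base_qualities)[q2[dis]]
    if bin_width is not None:
        # higher error-probability bin = lower quality
        bin1 = -_quality_bin(qual1, bin_width)
        bin2 = -_quality_bin(qual2, bin_width)
    else:
        bin1, bin2 = qual1, qual2
    # the lower-quality base loses the disagreement
    to1 = bin1 < bin2
    to2 = bin2 < bin1
    tie = ~(to1 | to2)
    c1, c2 = cyc1[dis], cyc2[dis]
    np.add.at(profile.errors[1], c1[to1], 1.0)
    np.add.at(profile.errors[2], c2[to2], 1.0)
    np.add.at(profile.errors[1], c1[tie], 0.5)
    np.add.at(profile.errors[2], c2[tie], 0.5)
    profile.disagreeing_columns += float(dis.sum())


# ---------------------------------------------------------------------------
# mid-read summary, insert-size bins, spectrum
# ---------------------------------------------------------------------------


def midread_window(read_length: int) -> tuple[int, int]:
    """Inclusive 1-based cycle bounds of the 50%-60% mid-read window."""
    if read_length < 10:
        raise ValueError("read length too short for a mid-read window")
    return math.ceil(0.5 * read_length), math.floor(0.6 * read_length)


def midread_median_rate(
    profile: CycleErrorProfile | OverlapErrorProfile,
) -> dict[int, float]:
    """Median per-cycle raw rate over cycles 50%-60% into the read, per
    mate.  The median is taken across cycles of the aggregate profile."""
    lo, hi = midread_window(profile.read_length)
    out = {}
    for mate in (1, 2):
        window = profile.rates(mate)[lo - 1 : hi]
        out[mate] = float(np.nanmedian(window)) if window.size else math.nan
    return out


@dataclass
class InsertSizeErrorProfile:
    """Per-mate substitution rate against the reference in 50 bp bins of
    absolute template length, with per-bin read counts as density."""

    bin_width: int
    aligned_bases: dict[tuple[int, int], int] = field(default_factory=dict)
    substitutions: dict[tuple[int, int], int] = field(default_factory=dict)
    reads: dict[tuple[int, int], int] = field(default_factory=dict)

    def bins(self) -> list[int]:
        return sorted({b for _, b in self.aligned_bases})

    def rate(self, mate: int, bin_index: int) -> float:
        denom = self.aligned_bases.get((mate, bin_index), 0)
        if denom == 0:
            return math.nan
        return self.substitutions.get((mate, bin_index), 0) / denom

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mate in (1, 2):
            for b in self.bins():
                rows.append(
                    (mate, b * self.bin_width, (b + 1) * self.bin_width,
                     self.aligned_bases.get((mate, b), 0),
                     self.substitutions.get((mate, b), 0),
                     self.rate(mate, b),
                     self.reads.get((mate, b), 0))
                )
        return pd.DataFrame(
            rows,
            columns=["mate", "insert_lo", "insert_hi", "bases", "errors",
                     "rate", "reads"],
        )


def error_by_insert_size(
    reads: Iterable[AlignedReadRecord],
    reference: Mapping[str, str],
    bin_width: int = 50,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_duplicates: bool = True,
) -> InsertSizeErrorProfile:
    """Reference-based substitution rate per 50 bp insert-size bin and mate.

    Reads with template length 0 (unknown) are skipped; bins are
    ``[k*bin, (k+1)*bin)`` on ``|template_length|``.
    """
    profile = InsertSizeErrorProfile(bin_width)
    ref_cache: dict[str, np.ndarray] = {}
    for rec in reads:
        if not _passes(rec, min_mapq, exclude_duplicates):
            continue
        if rec.template_length == 0:
            continue
        b = abs(rec.template_length) // bin_width
        key = (rec.mate_rank, b)
        if rec.reference_name not in ref_cache:
            ref_cache[rec.reference_name] = _ref_bytes(reference, rec.reference_name)
        ref = ref_cache[rec.reference_name]
        nb = ns = 0
        for _, _, valid, mism, _, _ in _mismatch_columns(rec, ref):
            nb += int(valid.sum())
            ns += int(mism.sum())
        profile.aligned_bases[key] = profile.aligned_bases.get(key, 0) + nb
        profile.substitutions[key] = profile.substitutions.get(key, 0) + ns
        profile.reads[key] = profile.reads.get(key, 0) + 1
    return profile


@dataclass
class SubstitutionSpectrum:
    """Counts of the 12 reference-to-read substitution types in read
    orientation, with the complement-collapsed 6-type view."""

    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())

    def collapsed(self) -> dict[str, int]:
        out = dict.fromkeys(COLLAPSED_TYPES, 0)
        for sub, n in self.counts.items():
            out[_collapse_key(sub)] += n
        return out

    def collapsed_share(self, key: str) -> float:
        tot = self.total()
        return self.collapsed()[key] / tot if tot else math.nan


def substitution_spectrum(
    reads: Iterable[AlignedReadRecord],
    reference: Mapping[str, str],
    mate: int | None = None,
    insert_below: int | None = None,
    insert_at_least: int | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_duplicates: bool = True,
) -> SubstitutionSpectrum:
    """Substitution-type counts for reads passing the optional mate and
    absolute-insert-size filters.  Types are keyed in read orientation:
    a reverse-strand alignment's reference G read as A is recorded C>T."""
    spectrum = SubstitutionSpectrum()
    ref_cache: dict[str, np.ndarray] = {}
    for rec in reads:
        if not _passes(rec, min_mapq, exclude_duplicates):
            continue
        if mate is not None and rec.mate_rank != mate:
            continue
        tlen = abs(rec.template_length)
        if insert_below is not None and tlen >= insert_below:
            continue
        if insert_at_least is not None and tlen < insert_at_least:
            continue
        if rec.reference_name not in ref_cache:
            ref_cache[rec.reference_name] = _ref_bytes(reference, rec.reference_name)
        ref = ref_cache[rec.reference_name]
        reverse = rec.strand != FORWARD
        for _, _, _, mism, refseg, readseg in _mismatch_columns(rec, ref):
            for rb, ab in zip(refseg[mism], readseg[mism]):
                r, a = rb.decode(), ab.decode()
                if reverse:
                    r, a = _PAIR[r], _PAIR[a]
                spectrum.counts[f"{r}>{a}"] += 1
    return spectrum
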