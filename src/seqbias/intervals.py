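"""Genomic intervals and base-level set algebra.

All intervals are 0-based half-open.  Merging unions overlapping *or
book-ended* intervals on the same (chrom, strand) key and carries the count
of absorbed inputs, matching the defaults of the standard BED merging tool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

UNSTRANDED = "."


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Ordered collection of :class:`GenomicInterval` with optional counts.

    ``counts[i]`` is the number of input intervals absorbed into interval
    ``i`` by :meth:`merge_count`; for sets not produced by merging it is 1.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        counts: Sequence[int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        if counts is None:
            self.counts = [1] * len(self.intervals)
        else:
            self.counts = list(counts)
            if len(self.counts) != len(self.intervals):
                raise ValueError("counts length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def sorted(self) -> "IntervalSet":
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        return IntervalSet(
            [self.intervals[i] for i in order], [self.counts[i] for i in order]
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        """Read BED3/BED6 (plain text, tab-separated, no header)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        ivs = []
        for row in df.itertuples(index=False):
            strand = row[5] if len(row) > 5 else UNSTRANDED
            label = str(row[3]) if len(row) > 3 else ""
            ivs.append(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, label)
            )
        return cls(ivs)

    def to_bed(self, path: str) -> None:
        rows = [
            (iv.chrom, iv.start, iv.end, iv.label or ".", c, iv.strand)
            for iv, c in zip(self.intervals, self.counts)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    # -- algebra ----------------------------------------------------------

    def slop(self, amount: int, bounds: Mapping[str, int]) -> "IntervalSet":
        """Grow every interval by ``amount`` on both sides, clipped to
        [0, chrom length]."""
        if amount < 0:
            raise ValueError("slop amount must be >= 0")
        out = []
        for iv in self.intervals:
            if iv.chrom not in bounds:
                raise KeyError(f"unknown chrom {iv.chrom!r} in slop bounds")
            out.append(
                replace(
                    iv,
                    start=max(0, iv.start - amount),
                    end=min(bounds[iv.chrom], iv.end + amount),
                )
            )
        return IntervalSet(out, list(self.counts))

    def merge_count(self) -> "IntervalSet":
        """Union overlapping/book-ended intervals per (chrom, strand) key,
        carrying the number of absorbed inputs."""
        groups: dict[tuple[str, str], list[tuple[GenomicInterval, int]]] = {}
        for iv, c in zip(self.intervals, self.counts):
            groups.setdefault((iv.chrom, iv.strand), []).append((iv, c))
        merged: list[GenomicInterval] = []
        counts: list[int] = []
        for (chrom, strand), items in sorted(groups.items()):
            items.sort(key=lambda t: (t[0].start, t[0].end))
            cur_s, cur_e, cur_c = items[0][0].start, items[0][0].end, items[0][1]
            label = items[0][0].label
            for iv, c in items[1:]:
                if iv.start <= cur_e:  # overlap or book-ended
                    cur_e = max(cur_e, iv.end)
                    cur_c += c
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e, strand, label))
                    counts.append(cur_c)
                    cur_s, cur_e, cur_c, label = iv.start, iv.end, c, iv.label
            merged.append(GenomicInterval(chrom, cur_s, cur_e, strand, label))
            counts.append(cur_c)
        return IntervalSet(merged, counts)

    def _merged_by_chrom(self, same_strand: bool) -> dict:
        """Disjoint sorted (start, end) lists keyed by chrom (or chrom+strand)."""
        key = (lambda iv: (iv.chrom, iv.strand)) if same_strand else (lambda iv: iv.chrom)
        groups: dict = {}
        for iv in self.intervals:
            groups.setdefault(key(iv), []).append((iv.start, iv.end))
        out = {}
        for k, spans in groups.items():
            spans.sort()
            merged = [list(spans[0])]
            for s, e in spans[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[k] = merged
        return out

    def intersect(self, other: "IntervalSet", same_strand: bool = False) -> "IntervalSet":
        """Base-level intersection.  Surviving pieces keep this set's
        strand/label.  With ``same_strand`` both inputs must be stranded and
        only matching strands intersect."""
        ob = other._merged_by_chrom(same_strand)
        out = []
        for iv in self.merge_count():
            key = (iv.chrom, iv.strand) if same_strand else iv.chrom
            for s, e in ob.get(key, ()):
                lo, hi = max(iv.start, s), min(iv.end, e)
                if lo < hi:
                    out.append(replace(iv, start=lo, end=hi))
        return IntervalSet(out).sorted()

    def subtract(self, other: "IntervalSet", same_strand: bool = False) -> "IntervalSet":
        """Base-level subtraction; surviving pieces keep strand/label."""
        ob = other._merged_by_chrom(same_strand)
        out = []
        for iv in self.merge_count():
            key = (iv.chrom, iv.strand) if same_strand else iv.chrom
            pos = iv.start
            for s, e in ob.get(key, ()):
                if e <= pos or s >= iv.end:
                    continue
                if s > pos:
                    out.append(replace(iv, start=pos, end=s))
                pos = max(pos, e)
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(replace(iv, start=pos, end=iv.end))
        return IntervalSet(out).sorted()


def coverage_select(sets: Sequence[IntervalSet], min_count: int) -> IntervalSet:
    """Bases covered by at least ``min_count`` of the given (independently
    merged) interval sets, componentized into maximal intervals.

    Used for "present in >= k subjects" style filters.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for iset in sets:
        for chrom, spans in iset._merged_by_chrom(False).items():
            ev = events.setdefault(chrom, [])
            for s, e in spans:
                ev.append((s, 1))
                ev.append((e, -1))
    out = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        start = None
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            while i < len(ev) and ev[i][0] == pos:
                depth += ev[i][1]
                i += 1
            if depth >= min_count and start is None:
                start = pos
            elif depth < min_count and start is not None:
                out.append(GenomicInterval(chrom, start, pos))
                start = None
    return IntervalSet(out)


def per_base_mask(iset: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base occupancy of a set on one chromosome (test oracle
    and window machinery)."""
    mask = np.zeros(length, dtype=bool)
    for iv in iset:
        if iv.chrom == chrom:
            mask[max(0, iv.start): min(length, iv.end)] = True
    return mask


def mask_to_intervals(
    mask: np.ndarray, chrom: str, strand: str = UNSTRANDED
) -> IntervalSet:
    """Componentize a boolean per-base mask into maximal intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    out = [
        GenomicInterval(chrom, int(s), int(e), strand)
        for s, e in zip(idx[::2], idx[1::2])
    ]
    return IntervalSet(out)
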