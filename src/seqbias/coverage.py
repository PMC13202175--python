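"""Downsampling, MAPQ-filtered depth, and stratified coverage comparison.

Coverage bias is measured by equalizing effective depth across datasets
(pair-consistent random downsampling to a common target), computing
per-base depth from confidently mapped reads only, averaging depth within
each genome stratification (a BED partition of context classes: GC bands,
homopolymers, tandem repeats, ...), and expressing each stratification as a
relative difference to the overall autosomal mean.  The stratifications
that vary most across datasets are selected by variance of the mean
coverage.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .records import AlignedReadRecord

DEFAULT_MIN_MAPQ = 60

#: stratification subcategories excluded from coverage comparison by default
DEFAULT_LABEL_BLOCKLIST = (
    "Ancestry",
    "FunctionalTechnicallyDifficult",
    "GenomeSpecific",
)


def downsample_pairs(
    reads: Iterable[AlignedReadRecord], fraction: float, seed: int = 0
) -> Iterator[AlignedReadRecord]:
    """Keep a random fraction of read *pairs*; both mates share the
    keep/drop decision, keyed on query name and seed, so no mate is ever
    orphaned.  Deterministic for a given seed."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        yield from reads
        return
    threshold = int(fraction * 2**32)
    for rec in reads:
        h = zlib.crc32(f"{seed}:{rec.query_name}".encode())
        if h < threshold:
            yield rec


@dataclass
class DepthTrack:
    """Per-chrom arrays of per-base depth from MAPQ-passing reads.

    Depth counts reference-consuming aligned bases (deletions included,
    matching reference-span depth semantics); soft-clips and insertions add
    nothing.
    """

    depth: dict[str, np.ndarray]

    def mean_over(self, intervals: IntervalSet) -> tuple[int, float]:
        """(span, mean depth) over the merged bases of a stratification."""
        merged = intervals.merge_count()
        span = 0
        total = 0.0
        for iv in merged:
            arr = self.depth.get(iv.chrom)
            if arr is None:
                continue
            s, e = max(0, iv.start), min(len(arr), iv.end)
            if s >= e:
                continue
            span += e - s
            total += float(arr[s:e].sum())
        return span, (total / span if span else math.nan)

    def global_mean(self) -> float:
        n = sum(len(a) for a in self.depth.values())
        s = sum(float(a.sum()) for a in self.depth.values())
        return s / n if n else math.nan


def depth_track(
    reads: Iterable[AlignedReadRecord],
    chrom_sizes: Mapping[str, int],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_duplicates: bool = True,
) -> DepthTrack:
    """Per-base depth using difference arrays over reference-consuming
    CIGAR spans of qualifying reads."""
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_sizes.items()}
    for rec in reads:
        if rec.mapq < min_mapq or (exclude_duplicates and rec.is_duplicate):
            continue
        arr = diff.get(rec.reference_name)
        if arr is None:
            continue
        rpos = rec.position
        for op, n in rec.cigar:
            if op in "M=XDN":
                arr[max(0, rpos)] += 1
                arr[min(len(arr) - 1, rpos + n)] -= 1
                rpos += n
    return DepthTrack({c: np.cumsum(a[:-1]) for c, a in diff.items()})


def strat_mean(track: DepthTrack, strat: IntervalSet) -> tuple[int, float]:
    """Total merged span and mean coverage of a stratification."""
    return track.mean_over(strat)


def relative_difference(strat_mean_cov: float, autosomal_mean: float) -> float:
    """Signed relative coverage difference, (strat / autosomal) - 1."""
    if autosomal_mean <= 0 or math.isnan(autosomal_mean):
        raise ValueError("autosomal mean coverage must be positive")
    return strat_mean_cov / autosomal_mean - 1.0


@dataclass
class StratCoverageReport:
    """Per-stratification coverage for one dataset."""

    dataset: str
    rows: pd.DataFrame  # columns: label, span, mean_cov, rel_diff, included, reason

    @classmethod
    def build(
        cls,
        dataset: str,
        track: DepthTrack,
        stratifications: Mapping[str, IntervalSet],
        autosomes: IntervalSet,
        min_span: int = 10_000,
        label_blocklist: tuple[str, ...] = DEFAULT_LABEL_BLOCKLIST,
    ) -> "StratCoverageReport":
        _, auto_mean = track.mean_over(autosomes)
        rows = []
        for label, ivs in stratifications.items():
            span, mean_cov = track.mean_over(ivs)
            included, reason = True, ""
            if any(block in label for block in label_blocklist):
                included, reason = False, "category_excluded"
            elif span < min_span:
                included, reason = False, "span_lt_10000"
            rel = (
                relative_difference(mean_cov, auto_mean)
                if included and not math.isnan(mean_cov)
                else math.nan
            )
            rows.append((label, span, mean_cov, rel, included, reason))
        return cls(
            dataset,
            pd.DataFrame(
                rows,
                columns=["label", "span", "mean_cov", "rel_diff", "included", "reason"],
            ),
        )


def top_variable_strats(
    reports: Iterable[StratCoverageReport], k: int = 15
) -> list[str]:
    """The k stratification labels most variable in mean coverage across
    datasets; ties (and the all-equal degenerate case) break
    lexicographically by label."""
    frames = []
    for rep in reports:
        df = rep.rows[rep.rows["included"]]
        frames.append(df.set_index("label")["mean_cov"].rename(rep.dataset))
    if len(frames) < 2:
        raise ValueError("need at least two datasets to rank variability")
    wide = pd.concat(frames, axis=1)
    var = wide.var(axis=1, ddof=1).fillna(0.0)
    order = sorted(var.index, key=lambda lab: (-var[lab], lab))
    return order[:k]
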