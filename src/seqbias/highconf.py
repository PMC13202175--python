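"""High-confidence benchmarking-region construction and the F1 statistic.

Variant benchmarking is only meaningful where every compared dataset has
adequate, unexceptional coverage and where the variant representation is
unambiguous.  The region builder therefore keeps 100 bp windows with
ordinary coverage in every dataset, intersects the short-read consensus
with the orthogonal (long-read) dataset, and removes regions around
clustered small variants, structural variants, CNVs, configured exclusion
BEDs, and partially covered repeats.

The benchmarking F1 statistic follows the truth/query-disambiguated form

    F1 = (TP_truth + TP_query) / (TP_truth + TP_query + FP + FN)

where TP_truth counts truth variants matched by the query, TP_query counts
query variants matched by the truth, FP counts unmatched query variants
and FN unmatched truth variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import DepthTrack
from .intervals import GenomicInterval, IntervalSet
from .samio import SmallVariant


@dataclass
class RegionBuildConfig:
    window: int = 100
    min_cov: float = 10.0
    max_cov_factor: float = 2.0
    cluster_count: int = 2
    cluster_window: int = 10
    cluster_slop: int = 50
    sv_min_len: int = 50
    sv_slop: int = 50
    cnv_slop: int = 1000


def coverage_windows(
    track: DepthTrack,
    window: int = 100,
    min_cov: float = 10.0,
    max_cov_factor: float = 2.0,
) -> IntervalSet:
    """Fixed windows with unexceptional mean depth, merged.

    A window is kept when its mean depth is at least ``min_cov`` and at
    most ``max_cov_factor`` times the median window depth of the whole
    dataset (both boundaries inclusive on the keep side: the exclusions are
    strictly-below and strictly-above).
    """
    means: dict[str, np.ndarray] = {}
    for chrom, arr in track.depth.items():
        n_win = math.ceil(len(arr) / window)
        padded = np.zeros(n_win * window)
        padded[: len(arr)] = arr
        sums = padded.reshape(n_win, window).sum(axis=1)
        sizes = np.full(n_win, window)
        if len(arr) % window:
            sizes[-1] = len(arr) % window
        means[chrom] = sums / sizes
    all_means = np.concatenate(list(means.values())) if means else np.array([])
    if all_means.size == 0:
        return IntervalSet()
    median = float(np.median(all_means))
    out = []
    for chrom, m in means.items():
        size = len(track.depth[chrom])
        keep = (m >= min_cov) & (m <= max_cov_factor * median)
        for w in np.flatnonzero(keep):
            out.append(
                GenomicInterval(chrom, int(w) * window, min(size, (int(w) + 1) * window))
            )
    return IntervalSet(out).sorted().merge_count()


def intersect_datasets(
    short_read_sets: Sequence[IntervalSet],
    orthogonal_sets: Sequence[IntervalSet] = (),
) -> IntervalSet:
    """Union of the short-read kept-window sets, then intersection with
    each orthogonal-technology set."""
    if not short_read_sets:
        raise ValueError("need at least one short-read window set")
    pooled = IntervalSet(
        [iv for s in short_read_sets for iv in s]
    ).merge_count()
    for other in orthogonal_sets:
        pooled = pooled.intersect(other)
    return pooled


def clustered_variant_exclusions(
    variants: Sequence[SmallVariant],
    count: int = 2,
    within: int = 10,
    slop: int = 50,
) -> IntervalSet:
    """Exclusion spans around runs of clustered small variants.

    Variants occupy their reference span; a maximal run where consecutive
    spans lie within ``within`` bases (edge to edge) and containing at
    least ``count`` variants is expanded by ``slop`` on each side.
    """
    by_chrom: dict[str, list[SmallVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out = []
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: (v.start, v.end))
        run_start, run_end, run_n = vs[0].start, vs[0].end, 1
        for v in vs[1:]:
            if v.start - run_end <= within:
                run_end = max(run_end, v.end)
                run_n += 1
            else:
                if run_n >= count:
                    out.append(
                        GenomicInterval(chrom, max(0, run_start - slop), run_end + slop)
                    )
                run_start, run_end, run_n = v.start, v.end, 1
        if run_n >= count:
            out.append(
                GenomicInterval(chrom, max(0, run_start - slop), run_end + slop)
            )
    return IntervalSet(out).sorted().merge_count()


def sv_cnv_exclusions(
    svs: Sequence[GenomicInterval],
    cnvs: Sequence[GenomicInterval] = (),
    sv_min_len: int = 50,
    sv_slop: int = 50,
    cnv_slop: int = 1000,
) -> IntervalSet:
    """Spans around structural variants strictly longer than ``sv_min_len``
    (expanded by ``sv_slop``) unioned with CNV calls expanded by
    ``cnv_slop``."""
    out = []
    for sv in svs:
        if len(sv) > sv_min_len:
            out.append(
                GenomicInterval(sv.chrom, max(0, sv.start - sv_slop), sv.end + sv_slop)
            )
    for cnv in cnvs:
        out.append(
            GenomicInterval(cnv.chrom, max(0, cnv.start - cnv_slop), cnv.end + cnv_slop)
        )
    return IntervalSet(out).sorted().merge_count()


def partial_repeat_exclusion(
    confident: IntervalSet, repeats: IntervalSet
) -> IntervalSet:
    """Remove every repeat interval not fully contained in the confident
    set.  A repeat straddling a confident-region edge is subtracted
    entirely; fully contained repeats leave the set unchanged."""
    merged_conf = confident.merge_count()
    partial = []
    for rep in repeats.merge_count():
        contained = any(
            iv.chrom == rep.chrom and iv.start <= rep.start and rep.end <= iv.end
            for iv in merged_conf
        )
        if not contained:
            partial.append(rep)
    if not partial:
        return merged_conf
    return merged_conf.subtract(IntervalSet(partial))


@dataclass
class RegionInputs:
    """Everything the region builder consumes."""

    short_read_windows: Sequence[IntervalSet]
    orthogonal_windows: Sequence[IntervalSet] = ()
    small_variants: Sequence[SmallVariant] = ()
    svs: Sequence[GenomicInterval] = ()
    cnvs: Sequence[GenomicInterval] = ()
    exclusion_beds: Sequence[IntervalSet] = ()
    repeats: IntervalSet = field(default_factory=IntervalSet)


def build_regions(config: RegionBuildConfig, inputs: RegionInputs) -> IntervalSet:
    """Compose the full exclusion cascade deterministically."""
    if not inputs.short_read_windows:
        raise ValueError("missing input: short-read coverage windows")
    regions = intersect_datasets(
        inputs.short_read_windows, inputs.orthogonal_windows
    )
    if inputs.small_variants:
        regions = regions.subtract(
            clustered_variant_exclusions(
                inputs.small_variants,
                config.cluster_count,
                config.cluster_window,
                config.cluster_slop,
            )
        )
    if inputs.svs or inputs.cnvs:
        regions = regions.subtract(
            sv_cnv_exclusions(
                inputs.svs,
                inputs.cnvs,
                config.sv_min_len,
                config.sv_slop,
                config.cnv_slop,
            )
        )
    for bed in inputs.exclusion_beds:
        regions = regions.subtract(bed)
    regions = partial_repeat_exclusion(regions, inputs.repeats)
    return regions


@dataclass(frozen=True)
class BenchCounts:
    tp_truth: int
    tp_query: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp_truth, self.tp_query, self.fp, self.fn) < 0:
            raise ValueError("benchmark counts must be non-negative")


def f1_score(counts: BenchCounts) -> float:
    """Truth/query-disambiguated F1; undefined (NaN) on all-zero counts."""
    num = counts.tp_truth + counts.tp_query
    denom = num + counts.fp + counts.fn
    if denom == 0:
        return math.nan
    return num / denom
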