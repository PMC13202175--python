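import math

import numpy as np
import pytest

from seqbias.coverage import DepthTrack
from seqbias.highconf import (
    BenchCounts,
    RegionBuildConfig,
    RegionInputs,
    build_regions,
    clustered_variant_exclusions,
    coverage_windows,
    f1_score,
    intersect_datasets,
    partial_repeat_exclusion,
    sv_cnv_exclusions,
)
from seqbias.intervals import GenomicInterval, IntervalSet, per_base_mask
from seqbias.samio import SmallVariant


def iv(start, end, chrom="c"):
    return GenomicInterval(chrom, start, end)


class TestCoverageWindows:
    def _track(self, depths):
        return DepthTrack({"c": np.asarray(depths, dtype=float)})

    def test_low_and_high_windows_excluded(self):
        # window means: 9 (too low), 30, 30, 61 (> 2 x median 30)
        depths = [9.0] * 100 + [30.0] * 100 + [30.0] * 100 + [61.0] * 100
        kept = coverage_windows(self._track(depths))
        assert [(v.start, v.end) for v in kept] == [(100, 300)]

    def test_boundaries_inclusive_on_keep_side(self):
        # mean exactly 10 kept; exactly 2 x median kept
        depths = [10.0] * 100 + [30.0] * 100 + [30.0] * 100 + [60.0] * 100
        kept = coverage_windows(self._track(depths))
        assert [(v.start, v.end) for v in kept] == [(0, 400)]

    def test_partial_tail_window(self):
        depths = [20.0] * 250
        kept = coverage_windows(self._track(depths))
        assert [(v.start, v.end) for v in kept] == [(0, 250)]

    @pytest.mark.parametrize("seed", range(10))
    def test_against_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depths = rng.integers(0, 40, 1000).astype(float)
        kept = coverage_windows(DepthTrack({"c": depths}))
        means = depths.reshape(10, 100).mean(axis=1)
        med = np.median(means)
        mask = np.zeros(1000, dtype=bool)
        for w in range(10):
            if means[w] >= 10 and means[w] <= 2 * med:
                mask[w * 100:(w + 1) * 100] = True
        assert np.array_equal(per_base_mask(kept, "c", 1000), mask)


class TestIntersectDatasets:
    def test_identity_and_disjoint(self):
        a = IntervalSet([iv(0, 100)])
        b = IntervalSet([iv(200, 300)])
        same = intersect_datasets([a], [a])
        assert [(v.start, v.end) for v in same] == [(0, 100)]
        assert len(intersect_datasets([a], [b])) == 0

    def test_union_then_intersection_semantics(self):
        short1 = IntervalSet([iv(0, 100)])
        short2 = IntervalSet([iv(50, 200)])
        ortho = IntervalSet([iv(80, 500)])
        out = intersect_datasets([short1, short2], [ortho])
        assert [(v.start, v.end) for v in out] == [(80, 200)]

    def test_requires_input(self):
        with pytest.raises(ValueError):
            intersect_datasets([])


class TestVariantAndSvExclusions:
    def test_clustered_pair_exact_bounds(self):
        vs = [SmallVariant("c", 100, 101), SmallVariant("c", 105, 106)]
        out = clustered_variant_exclusions(vs)
        assert [(v.start, v.end) for v in out] == [(50, 156)]

    def test_isolated_variant_no_exclusion(self):
        assert len(clustered_variant_exclusions([SmallVariant("c", 100, 101)])) == 0

    def test_chained_cluster_merges(self):
        vs = [SmallVariant("c", 100, 101), SmallVariant("c", 108, 109),
              SmallVariant("c", 115, 116)]
        out = clustered_variant_exclusions(vs)
        assert [(v.start, v.end) for v in out] == [(50, 166)]

    def test_gap_above_threshold_splits_runs(self):
        vs = [SmallVariant("c", 100, 101), SmallVariant("c", 120, 121),
              SmallVariant("c", 125, 126)]
        out = clustered_variant_exclusions(vs)
        assert [(v.start, v.end) for v in out] == [(70, 176)]

    def test_sv_strictly_greater_than_min_len(self):
        assert len(sv_cnv_exclusions([iv(0, 50)])) == 0  # span 50 not excluded
        out = sv_cnv_exclusions([iv(100, 151)])  # span 51
        assert [(v.start, v.end) for v in out] == [(50, 201)]

    def test_cnv_slop(self):
        out = sv_cnv_exclusions([], [iv(10_000, 20_000)])
        assert [(v.start, v.end) for v in out] == [(9_000, 21_000)]


class TestPartialRepeatExclusion:
    def test_contained_repeat_untouched(self):
        conf = IntervalSet([iv(0, 1000)])
        reps = IntervalSet([iv(100, 200)])
        out = partial_repeat_exclusion(conf, reps)
        assert out.total_bases() == 1000

    def test_straddling_repeat_fully_removed(self):
        conf = IntervalSet([iv(0, 150)])
        reps = IntervalSet([iv(100, 200)])
        out = partial_repeat_exclusion(conf, reps)
        assert [(v.start, v.end) for v in out] == [(0, 100)]

    @pytest.mark.parametrize("seed", range(10))
    def test_against_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = 10_000
        conf = IntervalSet(
            [iv(int(s), min(G, int(s) + int(l)))
             for s, l in zip(rng.integers(0, G - 1, 15), rng.integers(1, 500, 15))]
        )
        reps = IntervalSet(
            [iv(int(s), min(G, int(s) + int(l)))
             for s, l in zip(rng.integers(0, G - 1, 15), rng.integers(1, 200, 15))]
        )
        got = per_base_mask(partial_repeat_exclusion(conf, reps), "c", G)
        mc = per_base_mask(conf, "c", G)
        expect = mc.copy()
        for rep in reps.merge_count():
            if not mc[rep.start:rep.end].all():
                expect[rep.start:rep.end] = False
        assert np.array_equal(got, expect)


class TestBuildRegions:
    def _random_inputs(self, rng, G=10_000):
        def rand_set(n, max_len):
            return IntervalSet(
                [iv(int(s), min(G, int(s) + int(l)))
                 for s, l in zip(rng.integers(0, G - 1, n), rng.integers(1, max_len, n))]
            )

        variants = sorted(
            int(p) for p in rng.integers(0, G - 1, 40)
        )
        return RegionInputs(
            short_read_windows=[rand_set(6, 2000), rand_set(6, 2000)],
            orthogonal_windows=[rand_set(6, 4000)],
            small_variants=[SmallVariant("c", p, p + 1) for p in variants],
            svs=[*rand_set(3, 300)],
            cnvs=[*rand_set(1, 500)],
            exclusion_beds=[rand_set(2, 400)],
            repeats=rand_set(4, 150),
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_against_boolean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = 10_000
        inputs = self._random_inputs(rng, G)
        cfg = RegionBuildConfig()
        got = per_base_mask(build_regions(cfg, inputs), "c", G)

        # independent per-base composition
        mask = np.zeros(G, dtype=bool)
        for s in inputs.short_read_windows:
            mask |= per_base_mask(s, "c", G)
        for o in inputs.orthogonal_windows:
            mask &= per_base_mask(o, "c", G)
        ex = np.zeros(G, dtype=bool)
        # clustered variants
        positions = sorted((v.start, v.end) for v in inputs.small_variants)
        run = [positions[0]]
        runs = []
        for s, e in positions[1:]:
            if s - run[-1][1] <= 10:
                run.append((s, e))
            else:
                runs.append(run)
                run = [(s, e)]
        runs.append(run)
        for r in runs:
            if len(r) >= 2:
                lo = max(0, r[0][0] - 50)
                hi = min(G, max(e for _, e in r) + 50)
                ex[lo:hi] = True
        for sv in inputs.svs:
            if len(sv) > 50:
                ex[max(0, sv.start - 50): sv.end + 50] = True
        for cnv in inputs.cnvs:
            ex[max(0, cnv.start - 1000): min(G, cnv.end + 1000)] = True
        for bed in inputs.exclusion_beds:
            ex |= per_base_mask(bed, "c", G)
        mask &= ~ex
        for rep in inputs.repeats.merge_count():
            if not mask[rep.start:rep.end].all():
                mask[rep.start:rep.end] = False
        assert np.array_equal(got, mask)

    def test_exclusions_are_monotone(self):
        rng = np.random.default_rng(123)
        inputs = self._random_inputs(rng)
        cfg = RegionBuildConfig()
        full = build_regions(cfg, inputs).total_bases()
        no_excl = build_regions(
            cfg,
            RegionInputs(
                short_read_windows=inputs.short_read_windows,
                orthogonal_windows=inputs.orthogonal_windows,
            ),
        ).total_bases()
        assert full <= no_excl

    def test_everything_excluded_is_empty(self):
        inputs = RegionInputs(
            short_read_windows=[IntervalSet([iv(0, 1000)])],
            exclusion_beds=[IntervalSet([iv(0, 1000)])],
        )
        assert len(build_regions(RegionBuildConfig(), inputs)) == 0

    def test_missing_inputs_named(self):
        with pytest.raises(ValueError, match="coverage windows"):
            build_regions(RegionBuildConfig(), RegionInputs(short_read_windows=[]))


class TestF1:
    def test_printed_example(self):
        assert f1_score(BenchCounts(90, 92, 8, 10)) == pytest.approx(0.91)

    def test_perfect_and_zero(self):
        assert f1_score(BenchCounts(5, 5, 0, 0)) == 1.0
        assert f1_score(BenchCounts(0, 0, 5, 5)) == 0.0

    def test_all_zero_undefined(self):
        assert math.isnan(f1_score(BenchCounts(0, 0, 0, 0)))

    def test_symmetry_and_monotonicity(self):
        base = f1_score(BenchCounts(50, 40, 10, 5))
        assert base == f1_score(BenchCounts(40, 50, 10, 5))
        assert f1_score(BenchCounts(50, 40, 11, 5)) < base
        assert f1_score(BenchCounts(50, 40, 10, 6)) < base
        assert 0 <= base <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BenchCounts(-1, 0, 0, 0)
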