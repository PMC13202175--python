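import numpy as np
import pytest

from seqbias import (
    ErrorModel,
    FeaturePlan,
    G4Effect,
    SimulationConfig,
    build_reference,
    simulate_reads,
)
from seqbias.g4 import (
    SoftClipSite,
    discover_clip_sites,
    extract_softclip_spans,
    find_g4_motifs,
    isolated_motifs,
    overlap_with_motifs,
    profile_motif_pileup,
)
from seqbias.intervals import GenomicInterval, IntervalSet

from conftest import make_read


class TestMotifFinder:
    def test_canonical_forward_motif(self):
        motifs = find_g4_motifs("GGGATGGGATGGGATGGG")
        assert len(motifs) == 1
        assert (motifs[0].start, motifs[0].end, motifs[0].strand) == (0, 18, "+")

    def test_c_run_form_is_reverse_strand(self):
        motifs = find_g4_motifs("CCCATCCCATCCCATCCC")
        assert len(motifs) == 1
        assert motifs[0].strand == "-"

    def test_no_motifs_when_g_runs_capped_at_two(self):
        rng = np.random.default_rng(0)
        # build 100 kb where no base repeats three times in a row
        pieces = []
        prev2 = ("", "")
        while sum(len(p) for p in pieces) < 100_000:
            b = "ACGT"[rng.integers(0, 4)]
            if b == prev2[0] == prev2[1]:
                continue
            pieces.append(b)
            prev2 = (prev2[1], b)
        seq = "".join(pieces)
        assert find_g4_motifs(seq) == []

    def test_embedded_motif_located(self):
        seq = "T" * 500 + "GGGTTGGGTTGGGTTGGG" + "T" * 500
        motifs = find_g4_motifs(seq)
        assert [(m.start, m.end) for m in motifs] == [(500, 518)]


class TestSoftclipExtraction:
    def _read(self, cigar, mapq=60, tlen=400, **kw):
        n = sum(l for op, l in cigar if op in "MIS=X")
        return make_read(bases="A" * n, cigar=cigar, mapq=mapq, tlen=tlen, **kw)

    def test_thresholds(self):
        inc = self._read([("M", 140), ("S", 10)])
        spans = extract_softclip_spans([inc])
        assert len(spans["+"]) == 1

    def test_short_clip_excluded(self):
        rec = self._read([("M", 145), ("S", 5)])
        spans = extract_softclip_spans([rec])
        assert len(spans["+"]) == 0

    def test_clip_length_sums_both_ends(self):
        rec = self._read([("S", 5), ("M", 140), ("S", 5)])
        spans = extract_softclip_spans([rec])
        assert len(spans["+"]) == 1

    def test_mapq_tlen_chrom_filters(self):
        base = [("M", 140), ("S", 10)]
        assert len(extract_softclip_spans([self._read(base, mapq=59)])["+"]) == 0
        assert len(extract_softclip_spans([self._read(base, tlen=150)])["+"]) == 0
        assert len(
            extract_softclip_spans([self._read(base)], chroms={"chr2"})["+"]
        ) == 0

    def test_span_is_aligned_span_not_clip(self):
        rec = self._read([("M", 140), ("S", 10)], position=100)
        span = extract_softclip_spans([rec])["+"][0]
        assert (span.start, span.end) == (100, 240)


def spans(*ivs, strand="+"):
    return {
        "+": IntervalSet([i for i in ivs if strand == "+"]),
        "-": IntervalSet([i for i in ivs if strand == "-"]),
    }


def locus(start, end, chrom="c", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


SIZES = {"c": 100_000}


class TestDiscoveryPipeline:
    def _toy_spans(self, n_reads=3, start=1000, strand="+"):
        return {
            "+": IntervalSet(
                [locus(start + i, start + 150 + i) for i in range(n_reads)]
            ) if strand == "+" else IntervalSet(),
            "-": IntervalSet(
                [locus(start + i, start + 150 + i, strand="-") for i in range(n_reads)]
            ) if strand == "-" else IntervalSet(),
        }

    def test_hand_traceable_single_site(self):
        datasets = {
            subj: {run: self._toy_spans() for run in ("r1", "r2")}
            for subj in ("s1", "s2")
        }
        control = {"ctrl": {"r1": spans()}}
        sites = discover_clip_sites(datasets, SIZES, control=control)
        assert len(sites) == 1
        site = sites[0]
        assert site.strand == "+"
        assert site.interval.start <= 1000 and site.interval.end >= 1150
        assert site.control_subtracted

    def test_dual_strand_exclusion(self):
        both = {
            "+": self._toy_spans(strand="+")["+"],
            "-": self._toy_spans(n_reads=2, strand="-")["-"],
        }
        datasets = {s: {r: both for r in ("r1", "r2")} for s in ("s1", "s2")}
        sites = discover_clip_sites(datasets, SIZES)
        assert sites == []

    def test_min_subjects_rule(self):
        datasets = {
            "s1": {r: self._toy_spans() for r in ("r1", "r2")},
            "s2": {r: spans() for r in ("r1", "r2")},
        }
        assert discover_clip_sites(datasets, SIZES) == []

    def test_single_read_loci_dropped(self):
        datasets = {
            s: {r: self._toy_spans(n_reads=1) for r in ("r1", "r2")}
            for s in ("s1", "s2")
        }
        assert discover_clip_sites(datasets, SIZES) == []

    def test_run_intersection_required(self):
        datasets = {
            s: {"r1": self._toy_spans(), "r2": spans()} for s in ("s1", "s2")
        }
        assert discover_clip_sites(datasets, SIZES) == []

    def test_control_subtraction_removes_shared_loci(self):
        datasets = {
            s: {r: self._toy_spans() for r in ("r1", "r2")} for s in ("s1", "s2")
        }
        control = {"ctrl": {"r1": self._toy_spans()}}
        assert discover_clip_sites(datasets, SIZES, control=control) == []

    def test_each_filter_is_monotone(self):
        """Adding the subject filter, strand exclusion or control can only
        remove loci."""
        datasets = {
            s: {r: self._toy_spans() for r in ("r1", "r2")} for s in ("s1", "s2")
        }
        full = discover_clip_sites(datasets, SIZES)
        with_ctrl = discover_clip_sites(
            datasets, SIZES, control={"c": {"r": self._toy_spans()}}
        )
        stricter = discover_clip_sites(datasets, SIZES, min_subjects=3)
        assert len(with_ctrl) <= len(full)
        assert len(stricter) <= len(full)

    def test_empty_inputs_give_empty_output(self):
        assert discover_clip_sites({}, SIZES) == []


class TestMotifRelations:
    def test_strand_relations(self):
        motifs = [locus(100, 130, strand="-"), locus(500, 530, strand="+")]
        sites = [
            SoftClipSite(locus(95, 140, strand="+"), 3),   # opposite
            SoftClipSite(locus(495, 540, strand="+"), 3),  # same
            SoftClipSite(locus(5000, 5100, strand="+"), 3),  # none
        ]
        counts = overlap_with_motifs(sites, motifs)
        assert counts == {"same": 1, "opposite": 1, "both": 0, "none": 1}


class TestIsolation:
    def test_close_pair_both_removed(self):
        motifs = [locus(1000, 1020), locus(1120, 1140, strand="-")]
        assert isolated_motifs(motifs) == []

    def test_lone_short_motif_kept(self):
        motifs = [locus(1000, 1020)]
        assert isolated_motifs(motifs) == motifs

    def test_long_motif_removed(self):
        motifs = [locus(1000, 1060)]  # 60 bp > 50
        assert isolated_motifs(motifs) == []

    def test_long_motif_still_blocks_neighbours(self):
        motifs = [locus(1000, 1060), locus(1200, 1220)]
        assert isolated_motifs(motifs) == []


@pytest.fixture(scope="module")
def g4_world():
    effect = G4Effect(quality_drop=10, softclip_prob=0.5, c_excess=0.5)
    cfg = SimulationConfig(
        genome_length=100_000, depth=30, seed=42,
        feature_plan=[
            FeaturePlan("g4_motif", count=25, strand="+"),
            FeaturePlan("g4_motif", count=25, strand="-"),
        ],
        error_model=ErrorModel(0.001, 0.001, g4_effect=effect),
    )
    ref, feats = build_reference(cfg)
    return cfg, ref, feats


class TestPlantedEffectRecovery:
    def _run_datasets(self, cfg, ref, feats, g4_on=True, seeds=(0,)):
        cfg_run = cfg if g4_on else SimulationConfig(
            **{**cfg.__dict__, "error_model": ErrorModel(0.001, 0.001)}
        )
        out = []
        for s in seeds:
            recs, _ = simulate_reads(cfg_run, ref, feats, read_seed=5000 + s)
            out.append(recs)
        return out

    def test_sites_recover_planted_motifs(self, g4_world):
        cfg, ref, feats = g4_world
        datasets = {}
        for si, subj in enumerate(("s1", "s2")):
            runs = {}
            for ri, run in enumerate(("rA", "rB")):
                (recs,) = self._run_datasets(cfg, ref, feats, seeds=(10 * si + ri,))
                runs[run] = extract_softclip_spans(recs)
            datasets[subj] = runs
        (ctrl_recs,) = self._run_datasets(cfg, ref, feats, g4_on=False, seeds=(99,))
        control = {"ctrl": {"r": extract_softclip_spans(ctrl_recs)}}
        sizes = {cfg.chrom: cfg.genome_length}
        sites = discover_clip_sites(datasets, sizes, control=control)
        motifs = list(feats)
        slopped = feats.slop(10, sizes)
        # specificity 1.0: every site near a planted motif
        for s in sites:
            assert any(s.interval.overlaps(m) for m in slopped)
        # recall >= 0.9
        hit = sum(
            any(s.interval.overlaps(m) and s.strand != motifs[i].strand
                for s in sites)
            for i, m in enumerate(slopped)
        )
        assert hit / len(motifs) >= 0.9
        # strand relation almost exclusively opposite
        rel = overlap_with_motifs(sites, motifs)
        assert rel["same"] == 0
        assert rel["opposite"] / len(sites) >= 0.9
        assert all(s.supporting_reads >= 2 for s in sites)

    def test_no_effect_no_sites_across_replicates(self):
        """False-discovery null: without the G4 effect nothing clips, so
        discovery returns no sites in any replicate."""
        cfg = SimulationConfig(
            genome_length=20_000, depth=8, seed=3,
            feature_plan=[FeaturePlan("g4_motif", count=10, strand="+")],
            error_model=ErrorModel(0.001, 0.001),
        )
        ref, feats = build_reference(cfg)
        for rep in range(20):
            recs, _ = simulate_reads(cfg, ref, feats, read_seed=100 + rep)
            spans_ = extract_softclip_spans(recs)
            assert len(spans_["+"]) == 0 and len(spans_["-"]) == 0

    def test_pileup_quality_drop_and_c_mismatches(self, g4_world):
        cfg, ref, feats = g4_world
        iso = isolated_motifs(list(feats))
        assert len(iso) == 50  # planted with wide spacing
        (recs,) = self._run_datasets(cfg, ref, feats, seeds=(77,))
        prof = profile_motif_pileup(recs, iso, {cfg.chrom: ref}, flank=150)
        before = np.nanmean(prof.mean_quality("opposite", "before"))
        after = np.nanmean(prof.mean_quality("opposite", "after"))
        assert abs((before - after) - 10) <= 1
        same_delta = np.nanmean(prof.mean_quality("same", "before")) - np.nanmean(
            prof.mean_quality("same", "after")
        )
        assert abs(same_delta) <= 1
        comp = prof.mismatch_composition("opposite", "inside")
        assert comp[1] > 0.5  # C majority

    def test_pileup_depth_conservation(self, g4_world):
        """Depth at every offset equals the per-base count of qualifying
        reads covering it."""
        cfg, ref, feats = g4_world
        iso = isolated_motifs(list(feats))[:5]
        (recs,) = self._run_datasets(cfg, ref, feats, seeds=(78,))
        prof = profile_motif_pileup(recs, iso, {cfg.chrom: ref}, flank=50)
        # counting oracle
        expect = {
            (g, z): np.zeros_like(prof.depth[g, z]) for g in prof.GROUPS
            for z in prof.ZONES
        }
        for m in iso:
            for rec in recs:
                if rec.is_duplicate:
                    continue
                if not (rec.position <= m.start - 5 and rec.reference_end >= m.end + 5):
                    continue
                group = "same" if rec.strand == m.strand else "opposite"
                for _, rpos in rec.aligned_pairs():
                    if rec.strand == "+":
                        b, a, i = m.start - rpos, rpos - m.end + 1, rpos - m.start
                    else:
                        b, a, i = rpos - m.end + 1, m.start - rpos, m.end - 1 - rpos
                    if 1 <= b <= 50:
                        expect[group, "before"][b - 1] += 1
                    elif 1 <= a <= 50:
                        expect[group, "after"][a - 1] += 1
                    elif 0 <= i < len(m):
                        expect[group, "inside"][i] += 1
        for key in expect:
            assert np.array_equal(prof.depth[key], expect[key])

    def test_no_qualifying_reads_empty_profile(self, g4_world):
        cfg, ref, feats = g4_world
        iso = isolated_motifs(list(feats))[:3]
        prof = profile_motif_pileup([], iso, {cfg.chrom: ref})
        assert all(a.sum() == 0 for a in prof.depth.values())

    def test_non_isolated_motifs_rejected(self, g4_world):
        cfg, ref, feats = g4_world
        close = [
            GenomicInterval(cfg.chrom, 1000, 1020, "+"),
            GenomicInterval(cfg.chrom, 1100, 1120, "+"),
        ]
        with pytest.raises(ValueError, match="isolated"):
            profile_motif_pileup([], close, {cfg.chrom: ref}, flank=150)
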