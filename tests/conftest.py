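import pytest

from seqbias import (
    ErrorModel,
    SimulationConfig,
    build_reference,
    simulate_reads,
)
from seqbias.records import AlignedReadRecord


def make_read(
    position=0,
    strand="+",
    mate=1,
    bases="ACGT" * 5,
    cigar=None,
    quals=None,
    mapq=60,
    name="SIM:1:0.0:1101:100:200",
    tlen=400,
    chrom="chr1",
    dup=False,
    tags=None,
):
    """Hand-built alignment record for unit tests."""
    if cigar is None:
        cigar = [("M", len(bases))]
    if quals is None:
        quals = [30] * len(bases)
    return AlignedReadRecord(
        query_name=name,
        reference_name=chrom,
        position=position,
        strand=strand,
        mate_rank=mate,
        mapq=mapq,
        cigar=cigar,
        bases=bases,
        base_qualities=quals,
        template_length=tlen,
        is_duplicate=dup,
        tags=tags or {},
    )


@pytest.fixture(scope="session")
def uniform_error_sim():
    """100 kb, 30x, uniform per-base error rates, no structured effects."""
    cfg = SimulationConfig(
        genome_length=100_000,
        depth=30,
        seed=11,
        error_model=ErrorModel(base_rate_r1=0.001, base_rate_r2=0.004),
    )
    ref, feats = build_reference(cfg)
    recs, truth = simulate_reads(cfg, ref, feats)
    return cfg, ref, feats, recs, truth


@pytest.fixture(scope="session")
def null_sim():
    """Small dataset with every error and duplicate process off."""
    cfg = SimulationConfig(genome_length=30_000, depth=10, seed=7)
    ref, feats = build_reference(cfg)
    recs, truth = simulate_reads(cfg, ref, feats)
    return cfg, ref, feats, recs, truth


def random_interval_list(rng, n, genome=10_000, chrom="c", max_len=400, stranded=False):
    starts = rng.integers(0, genome - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    from seqbias.intervals import GenomicInterval, IntervalSet

    ivs = []
    for s, ln in zip(starts, lens):
        strand = rng.choice(["+", "-"]) if stranded else "."
        ivs.append(GenomicInterval(chrom, int(s), int(min(genome, s + ln)), strand))
    return IntervalSet(ivs)
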