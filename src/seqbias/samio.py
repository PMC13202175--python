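"""SAM/BAM, FASTA and VCF access behind the in-memory data model."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pysam
from pyfaidx import Fasta

from .intervals import GenomicInterval, IntervalSet
from .records import FORWARD, REVERSE, AlignedReadRecord

_CIGAR_OPS = "MIDNSHP=X"


def record_from_pysam(aln: pysam.AlignedSegment) -> AlignedReadRecord:
    return AlignedReadRecord(
        query_name=aln.query_name,
        reference_name=aln.reference_name,
        position=aln.reference_start,
        strand=REVERSE if aln.is_reverse else FORWARD,
        mate_rank=2 if aln.is_read2 else 1,
        mapq=aln.mapping_quality,
        cigar=[(_CIGAR_OPS[op], n) for op, n in (aln.cigartuples or [])],
        bases=aln.query_sequence or "",
        base_qualities=list(aln.query_qualities or []),
        template_length=aln.template_length,
        is_duplicate=aln.is_duplicate,
        tags=dict(aln.get_tags()),
    )


def read_alignments(
    path: str, region: str | None = None
) -> Iterator[AlignedReadRecord]:
    """Stream mapped primary alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(path) as fh:
        it = fh.fetch(region=region) if region else fh
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield record_from_pysam(aln)


def write_alignments(
    path: str,
    records: Iterable[AlignedReadRecord],
    chrom_sizes: Mapping[str, int],
) -> None:
    """Write records as SAM/BAM (mode inferred from extension)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    mode = "wb" if path.endswith(".bam") else "w"
    refids = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.query_name
            a.reference_id = refids[rec.reference_name]
            a.reference_start = rec.position
            a.mapping_quality = rec.mapq
            a.cigartuples = [(_CIGAR_OPS.index(op), n) for op, n in rec.cigar]
            a.query_sequence = rec.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.base_qualities)
            )
            a.template_length = rec.template_length
            flag = 0x1 | 0x2  # paired, proper pair
            if rec.strand == REVERSE:
                flag |= 0x10
            else:
                flag |= 0x20
            flag |= 0x40 if rec.mate_rank == 1 else 0x80
            if rec.is_duplicate:
                flag |= 0x400
            a.flag = flag
            for key, val in rec.tags.items():
                a.set_tag(key, val)
            out.write(a)


def load_fasta(path: str) -> dict[str, str]:
    """Load an (indexed) FASTA into plain uppercase strings."""
    fa = Fasta(path, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class SmallVariant:
    """A small variant occupying its reference span (0-based half-open)."""

    chrom: str
    start: int
    end: int  # start + len(REF)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def read_vcf_variants(path: str) -> list[SmallVariant]:
    """Read variant reference spans from a VCF (positions converted to
    0-based half-open on ingest)."""
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            out.append(SmallVariant(rec.chrom, rec.start, rec.start + len(rec.ref)))
    return out


def read_vcf_intervals(path: str) -> IntervalSet:
    return IntervalSet([v.span for v in read_vcf_variants(path)])
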