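"""Aligned-read records and flowcell-coordinate parsing.

The package works on plain in-memory read records so that every profiling
stage can be driven either from a SAM/BAM file (via :mod:`seqbias.samio`) or
directly from the synthetic-read simulator without touching disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

FORWARD = "+"
REVERSE = "-"

#: CIGAR operations that consume query bases.
_QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
_REF_OPS = frozenset("MDN=X")
#: CIGAR operations that align query to reference (columns usable for
#: substitution calling).
_ALIGN_OPS = frozenset("M=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlowcellCoordinate:
    """Cluster/polony location on a flowcell tile.

    x and y are dimensionless pixel units; their scale is instrument
    dependent, so only distances *within* a tile are meaningful.
    """

    tile: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative flowcell coordinate: ({self.x}, {self.y})")


def parse_flowcell_coordinate(query_name: str) -> FlowcellCoordinate | None:
    """Parse (tile, x, y) from a colon-delimited read identifier.

    Short-read identifiers encode the flowcell tile and the x/y pixel
    position of the cluster/polony as the final three colon-separated
    fields.  Returns ``None`` when the name has fewer than three fields or
    non-numeric x/y, so callers can exclude such reads from optical-distance
    analysis instead of aborting.
    """
    fields = query_name.split(":")
    if len(fields) < 3:
        return None
    tile, xs, ys = fields[-3], fields[-2], fields[-1]
    try:
        x = float(xs)
        y = float(ys)
    except ValueError:
        return None
    if x < 0 or y < 0:
        return None
    return FlowcellCoordinate(tile=tile, x=x, y=y)


def format_read_name(prefix: str, coord: FlowcellCoordinate) -> str:
    """Inverse of :func:`parse_flowcell_coordinate` for integer coordinates."""
    return f"{prefix}:{coord.tile}:{int(coord.x)}:{int(coord.y)}"


@dataclass
class AlignedReadRecord:
    """One read alignment, mirroring the SAM fields the analyses consume."""

    query_name: str
    reference_name: str
    position: int  # 0-based leftmost aligned reference coordinate
    strand: str  # FORWARD or REVERSE (alignment strand)
    mate_rank: int  # 1 or 2
    mapq: int
    cigar: list[tuple[str, int]]
    bases: str  # reference-orientation SEQ, as stored in SAM
    base_qualities: list[int]
    template_length: int = 0
    is_duplicate: bool = False
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.base_qualities):
            raise ValueError(
                f"{self.query_name}: {len(self.bases)} bases vs "
                f"{len(self.base_qualities)} qualities"
            )
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.bases):
            raise ValueError(
                f"{self.query_name}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.bases)}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mate_rank not in (1, 2):
            raise ValueError(f"bad mate rank {self.mate_rank}")

    @property
    def query_length(self) -> int:
        return len(self.bases)

    @property
    def is_reverse(self) -> bool:
        return self.strand == REVERSE

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.position + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def softclip_total(self) -> int:
        return sum(n for op, n in self.cigar if op == "S")

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_pos, ref_pos) for every aligned (M/=/X) column."""
        qpos = 0
        rpos = self.position
        for op, n in self.cigar:
            if op in _ALIGN_OPS:
                for i in range(n):
                    yield qpos + i, rpos + i
                qpos += n
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op in ("D", "N"):
                rpos += n
            # H consumes neither

    def aligned_blocks(self) -> Iterator[tuple[int, int, int]]:
        """Yield (query_start, ref_start, length) runs of aligned columns."""
        qpos = 0
        rpos = self.position
        for op, n in self.cigar:
            if op in _ALIGN_OPS:
                yield qpos, rpos, n
                qpos += n
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op in ("D", "N"):
                rpos += n

    def cycle_of(self, query_pos: int) -> int:
        """1-based sequencing cycle of a query position.

        Reverse-strand alignments store the sequence reverse-complemented,
        so the last stored base was the first one sequenced.
        """
        if self.strand == FORWARD:
            return query_pos + 1
        return self.query_length - query_pos

    def flowcell_coordinate(self) -> FlowcellCoordinate | None:
        return parse_flowcell_coordinate(self.query_name)
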