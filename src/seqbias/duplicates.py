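"""Classification of duplicate-marked read pairs by flowcell geometry.

Duplicate markers flag read pairs with identical outer alignment
coordinates, but the flag conflates physically distinct origins.  Two
signals separate them:

* **proximity** -- optical-type duplicates (one template detected or seeded
  as multiple clusters/polonies) sit close together on the same flowcell
  tile, so the Euclidean distance between the pairs' (x, y) pixel
  coordinates is small;
* **mate orientation** -- complementary ("sister") duplicates come from the
  two opposing strands of the same double-stranded fragment seeding
  independently, so the two pairs' read1/read2 roles occupy opposite
  fragment ends.

Every comparison is classified on both axes and tallied into the four
{proximal, distal} x {complementary, non-complementary} categories.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .records import FORWARD, AlignedReadRecord, FlowcellCoordinate

PROXIMAL_THRESHOLD = 100.0  # dimensionless flowcell pixels

CATEGORIES = (
    "proximal_complementary",
    "proximal_noncomplementary",
    "distal_complementary",
    "distal_noncomplementary",
)


@dataclass
class ReadPair:
    """Both mates of one read pair (assembled by query name)."""

    read1: AlignedReadRecord
    read2: AlignedReadRecord

    @property
    def query_name(self) -> str:
        return self.read1.query_name

    def coordinate(self) -> FlowcellCoordinate | None:
        return self.read1.flowcell_coordinate()

    def read1_is_forward(self) -> bool:
        """For FR pairs: whether read1 occupies the left (forward) fragment
        end."""
        return self.read1.strand == FORWARD


@dataclass
class PairComparison:
    distance: float  # math.inf when tiles differ
    same_tile: bool
    orientation_swapped: bool
    coordinates_available: bool = True


@dataclass
class DuplicateTally:
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    coordinate_unavailable: int = 0
    incomplete_pairs: int = 0

    @property
    def total_classified(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        tot = self.total_classified
        return {c: (n / tot if tot else float("nan")) for c, n in self.counts.items()}


def compare_pairs(a: ReadPair, b: ReadPair) -> PairComparison:
    """Distance and relative read1/2 order between two duplicate pairs.

    Distance is Euclidean in flowcell pixels when the pairs share a tile and
    infinite otherwise (reads on different tiles, lanes or flowcells are
    never physically proximal).  Orientation is swapped when one pair's
    read1 aligns to the fragment end where the other's read2 aligns.
    """
    swapped = a.read1_is_forward() != b.read1_is_forward()
    ca, cb = a.coordinate(), b.coordinate()
    if ca is None or cb is None:
        return PairComparison(math.nan, False, swapped, coordinates_available=False)
    if ca.tile != cb.tile:
        return PairComparison(math.inf, False, swapped)
    dist = math.hypot(ca.x - cb.x, ca.y - cb.y)
    return PairComparison(dist, True, swapped)


def classify(
    comparison: PairComparison, proximal_threshold: float = PROXIMAL_THRESHOLD
) -> str:
    """Joint category label; proximal means same tile and distance within
    the threshold (inclusive)."""
    proximal = comparison.same_tile and comparison.distance <= proximal_threshold
    prox = "proximal" if proximal else "distal"
    comp = "complementary" if comparison.orientation_swapped else "noncomplementary"
    return f"{prox}_{comp}"


def assemble_pairs(records: Iterable[AlignedReadRecord]) -> Iterator[ReadPair]:
    """Pair mates by query name; incomplete pairs are dropped silently
    (callers that need the count use :func:`tally_duplicates`)."""
    pending: dict[str, AlignedReadRecord] = {}
    for rec in records:
        other = pending.pop(rec.query_name, None)
        if other is None:
            pending[rec.query_name] = rec
        else:
            r1, r2 = (rec, other) if rec.mate_rank == 1 else (other, rec)
            yield ReadPair(r1, r2)


def tally_duplicates(
    records: Iterable[AlignedReadRecord],
    mode: str = "vs_primary",
    proximal_threshold: float = PROXIMAL_THRESHOLD,
    set_tag: str = "DI",
) -> DuplicateTally:
    """Tally duplicate categories over a stream of set-tagged alignments.

    ``all_pairs`` compares every unordered member combination of each
    duplicate set; ``vs_primary`` assigns each duplicate-marked pair the
    category of its comparison with the set's retained (non-duplicate)
    representative, mirroring per-marked-read rate reporting.
    """
    if mode not in ("all_pairs", "vs_primary"):
        raise ValueError(f"unknown mode {mode!r}")
    tally = DuplicateTally()

    sets: dict[object, list[ReadPair]] = defaultdict(list)
    pending: dict[str, AlignedReadRecord] = {}
    n_seen: dict[object, int] = defaultdict(int)
    for rec in records:
        if set_tag not in rec.tags:
            continue
        key = rec.tags[set_tag]
        other = pending.pop(rec.query_name, None)
        if other is None:
            pending[rec.query_name] = rec
            n_seen[key] += 1
        else:
            r1, r2 = (rec, other) if rec.mate_rank == 1 else (other, rec)
            sets[key].append(ReadPair(r1, r2))
    # mates never completed
    tally.incomplete_pairs = len(pending)

    for key, members in sets.items():
        if len(members) < 2:
            continue
        if mode == "all_pairs":
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    _tally_one(tally, members[i], members[j], proximal_threshold)
        else:
            primaries = [m for m in members if not m.read1.is_duplicate]
            if not primaries:
                continue
            primary = primaries[0]
            for m in members:
                if m is primary:
                    continue
                _tally_one(tally, primary, m, proximal_threshold)
    return tally


def _tally_one(
    tally: DuplicateTally, a: ReadPair, b: ReadPair, threshold: float
) -> None:
    cmp = compare_pairs(a, b)
    if not cmp.coordinates_available:
        tally.coordinate_unavailable += 1
        return
    tally.counts[classify(cmp, threshold)] += 1
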