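"""STR locus annotations: BED parsing, extraction regions, proximity queries.

Known STR loci come from a Tandem Repeats Finder annotation of the reference
genome, distributed either as a plain BED file with two extra columns (repeat
unit, reference copy number) or as the UCSC ``simpleRepeat`` table dump.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import bisect
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .motifs import InvalidMotifError, canonical_unit

logger = logging.getLogger(__name__)

__all__ = [
    "STRLocus",
    "GenomeRegionSet",
    "LocusIndex",
    "parse_str_bed",
    "parse_locus_id",
    "expand_extraction_regions",
    "proximity_fraction",
]


@dataclass(frozen=True)
class STRLocus:
    """A genomic STR interval with canonical repeat unit.

    ``ref_copies`` is the (possibly fractional) number of repeat copies in
    the reference allele, as reported by Tandem Repeats Finder.
    """

    chrom: str
    start: int
    end: int
    unit: str
    ref_copies: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.ref_copies < 0:
            raise ValueError("ref_copies must be >= 0")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.unit}"


def parse_locus_id(locus_id: str) -> STRLocus:
    """Inverse of :attr:`STRLocus.locus_id` (ref_copies is not encoded; set 0)."""
    chrom, coords, unit = locus_id.rsplit(":", 2)
    start, end = coords.split("-")
    return STRLocus(chrom=chrom, start=int(start), end=int(end), unit=unit, ref_copies=0.0)


# Column mappings (0-based) per dialect: chrom, start, end, unit, copies.
_DIALECTS = {
    "bed": (0, 1, 2, 3, 4),
    # UCSC simpleRepeat.txt: bin chrom chromStart chromEnd name period
    # copyNum consensusSize perMatch perIndel score A C G T entropy sequence
    "simplerepeat": (1, 2, 3, 16, 6),
}


def parse_str_bed(path: str | os.PathLike, dialect: str = "bed") -> list[STRLocus]:
    """Parse a TRF-style STR annotation into loci with canonical units.

    Rows whose motif cannot be canonicalized (ambiguity codes, length > 6 bp)
    are skipped with a warning; malformed coordinates raise with the offending
    line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ic, istart, iend, iunit, icopies = _DIALECTS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    need = max(ic, istart, iend, iunit, icopies) + 1
    if df.shape[1] < need:
        raise ValueError(
            f"{path}: expected >= {need} tab-separated columns for dialect "
            f"{dialect!r}, found {df.shape[1]}"
        )
    loci: list[STRLocus] = []
    skipped = 0
    for row in df.itertuples(index=True):
        line_no = row[0] + 1
        fields = row[1:]
        try:
            start, end = int(fields[istart]), int(fields[iend])
            copies = float(fields[icopies])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {line_no}: malformed record ({exc})") from exc
        try:
            unit = canonical_unit(fields[iunit])
        except InvalidMotifError as exc:
            logger.warning("%s: line %d skipped: %s", path, line_no, exc)
            skipped += 1
            continue
        try:
            loci.append(STRLocus(str(fields[ic]), start, end, unit, copies))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    if skipped:
        logger.warning("%s: skipped %d rows with non-canonicalizable motifs", path, skipped)
    return loci


class GenomeRegionSet:
    """Sorted, merged genomic intervals (0-based half-open) per chromosome."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((max(0, start), end))
        self._regions: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:  # overlap or abut -> merge
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._regions[chrom] = [(s, e) for s, e in merged]
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._regions.items()}

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._regions):
            for s, e in self._regions[chrom]:
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._regions.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeRegionSet) and self._regions == other._regions

    def total_span(self) -> int:
        return sum(e - s for ivs in self._regions.values() for s, e in ivs)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any region on ``chrom``."""
        ivs = self._regions.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(self._starts[chrom], start) - 1
        if i >= 0 and ivs[i][1] > start:
            return True
        return i + 1 < len(ivs) and ivs[i + 1][0] < end


def expand_extraction_regions(loci: Sequence[STRLocus], flank: int = 800) -> GenomeRegionSet:
    """Widen each locus by ``flank`` bp both sides (clamped at 0) and merge.

    The default 800 bp covers the fragment length of typical short-read
    libraries, so both mates of any STR-containing pair fall in the regions.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomeRegionSet(
        (l.chrom, max(0, l.start - flank), l.end + flank) for l in loci
    )


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge distance between two half-open intervals; 0 if overlapping."""
    return max(a_start - b_end, b_start - a_end, 0)


class LocusIndex:
    """Nearest same-unit locus queries, indexed per (chrom, canonical unit)."""

    def __init__(self, loci: Sequence[STRLocus]):
        seen: set[str] = set()
        for l in loci:
            if l.locus_id in seen:
                raise ValueError(f"duplicate locus_id {l.locus_id}")
            seen.add(l.locus_id)
        self._groups: dict[tuple[str, str], list[STRLocus]] = {}
        for l in loci:
            self._groups.setdefault((l.chrom, l.unit), []).append(l)
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._maxlen: dict[tuple[str, str], int] = {}
        for key, group in self._groups.items():
            group.sort(key=lambda l: (l.start, l.end))
            self._starts[key] = [l.start for l in group]
            self._maxlen[key] = max(l.end - l.start for l in group)

    def __len__(self) -> int:
        return sum(len(g) for g in self._groups.values())

    @property
    def loci(self) -> list[STRLocus]:
        return [l for g in self._groups.values() for l in g]

    def nearest(
        self,
        chrom: str,
        pos_start: int,
        pos_end: int,
        unit: str,
        max_dist: int = 500,
    ) -> STRLocus | None:
        """Closest locus on ``chrom`` with the same canonical ``unit`` within
        ``max_dist`` bp (edge-to-edge) of [pos_start, pos_end), or None.

        Equidistant candidates tie-break on smaller start coordinate.
        """
        key = (chrom, canonical_unit(unit))
        group = self._groups.get(key)
        if not group:
            return None
        starts = self._starts[key]
        lo = bisect.bisect_left(starts, pos_start - max_dist - self._maxlen[key])
        hi = bisect.bisect_right(starts, pos_end + max_dist)
        best: STRLocus | None = None
        best_gap = max_dist + 1
        for l in group[lo:hi]:
            g = _gap(l.start, l.end, pos_start, pos_end)
            if g < best_gap or (g == best_gap and best is not None and l.start < best.start):
                best, best_gap = l, g
        return best if best_gap <= max_dist else None


def proximity_fraction(loci: Sequence[STRLocus], distance: int) -> float:
    """Fraction of loci with another same-unit locus within ``distance`` bp.

    Distance is edge-to-edge (0 for overlapping loci).  A read allocated by
    its mate's position can be misassigned only between such neighbouring
    same-unit loci, so this fraction bounds the misallocation opportunity.
    """
    if not loci:
        raise ValueError("proximity_fraction requires at least one locus")
    groups: dict[tuple[str, str], list[STRLocus]] = {}
    for l in loci:
        groups.setdefault((l.chrom, l.unit), []).append(l)
    has_neighbor: set[int] = set()
    for group in groups.values():
        group.sort(key=lambda l: (l.start, l.end))
        for i, li in enumerate(group):
            for j in range(i + 1, len(group)):
                lj = group[j]
                if lj.start - li.end > distance:
                    break
                if _gap(li.start, li.end, lj.start, lj.end) <= distance:
                    has_neighbor.add(id(li))
                    has_neighbor.add(id(lj))
    return len(has_neighbor) / len(loci)
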