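"""Read counting and mate-pair allocation from decoy-aware alignments.

Reads aligning to an STR decoy chromosome are presumed to have originated
from an STR locus somewhere in the genome.  Because a decoy-mapped read is
pure repeat it carries no positional information itself, so its mate's
mapping position is used: if the mate maps within ``max_dist`` (default
500 bp) of a known STR locus with the same canonical repeat unit, the read
is allocated to that locus (the closest such locus if several qualify).
Reads whose mate is unmapped, itself decoy-mapped, or near no matching
locus stay unassigned but are still tallied per unit.
"""

from __future__ import annotations

import logging
import os
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .annotation import GenomeRegionSet, LocusIndex
from .motifs import DECOY_PREFIX, unit_from_decoy_name

logger = logging.getLogger(__name__)

__all__ = [
    "DecoyHit",
    "LocusCountTable",
    "count_decoy_reads",
    "collect_decoy_hits",
    "assign_reads_to_loci",
    "extract_candidate_reads",
    "write_fastq_pairs",
    "median_coverage",
]


@dataclass(frozen=True)
class DecoyHit:
    """A primary alignment on a decoy chromosome, with its mate's location."""

    read_name: str
    unit: str
    mate_chrom: str | None
    mate_start: int | None
    mate_end: int | None
    mate_mapped: bool


@dataclass
class LocusCountTable:
    """Per-sample decoy read counts: assigned per locus, unassigned per unit."""

    sample_id: str
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    median_coverage: float = float("nan")

    def total_for_unit(self, unit: str, locus_units: dict[str, str]) -> int:
        t = self.unassigned.get(unit, 0)
        t += sum(n for lid, n in self.assigned.items() if locus_units[lid] == unit)
        return t

    def to_tsv(self, path: str | os.PathLike) -> str:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\n")
            fh.write(f"#median_coverage={self.median_coverage!r}\n")
            fh.write("kind\tkey\tcount\n")
            for lid in sorted(self.assigned):
                fh.write(f"assigned\t{lid}\t{self.assigned[lid]}\n")
            for unit in sorted(self.unassigned):
                fh.write(f"unassigned\t{unit}\t{self.unassigned[unit]}\n")
        return os.fspath(path)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "LocusCountTable":
        sample_id, median_cov = "", float("nan")
        assigned: dict[str, int] = {}
        unassigned: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#sample_id="):
                    sample_id = line.split("=", 1)[1]
                elif line.startswith("#median_coverage="):
                    median_cov = float(line.split("=", 1)[1])
                elif not line or line.startswith(("kind\t", "#")):
                    continue
                else:
                    kind, key, count = line.split("\t")
                    (assigned if kind == "assigned" else unassigned)[key] = int(count)
        return cls(sample_id, assigned, unassigned, median_cov)


def _is_countable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def _open(alignment: str | os.PathLike | pysam.AlignmentFile) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignment, pysam.AlignmentFile):
        return alignment, False
    return pysam.AlignmentFile(os.fspath(alignment)), True


def count_decoy_reads(alignment: str | os.PathLike | pysam.AlignmentFile) -> dict[str, int]:
    """Count primary, non-duplicate, non-supplementary reads per decoy unit."""
    af, close = _open(alignment)
    counts: dict[str, int] = {}
    try:
        for read in af:
            if not _is_countable(read):
                continue
            if read.reference_name and read.reference_name.startswith(DECOY_PREFIX):
                unit = unit_from_decoy_name(read.reference_name)
                counts[unit] = counts.get(unit, 0) + 1
    finally:
        if close:
            af.close()
    return counts


def collect_decoy_hits(alignment: str | os.PathLike | pysam.AlignmentFile) -> list[DecoyHit]:
    """Gather decoy alignments with their mates' mapping coordinates.

    The mate interval is approximated as ``[mate_start, mate_start + read
    length)`` from the record's mate fields; no second pass over the file
    is made.
    """
    af, close = _open(alignment)
    hits: list[DecoyHit] = []
    try:
        for read in af:
            if not _is_countable(read):
                continue
            rname = read.reference_name
            if not (rname and rname.startswith(DECOY_PREFIX)):
                continue
            unit = unit_from_decoy_name(rname)
            mate_mapped = read.is_paired and not read.mate_is_unmapped
            if mate_mapped:
                mlen = read.query_length or read.infer_read_length() or 1
                hits.append(
                    DecoyHit(
                        read_name=read.query_name,
                        unit=unit,
                        mate_chrom=read.next_reference_name,
                        mate_start=read.next_reference_start,
                        mate_end=read.next_reference_start + mlen,
                        mate_mapped=True,
                    )
                )
            else:
                hits.append(DecoyHit(read.query_name, unit, None, None, None, False))
    finally:
        if close:
            af.close()
    return hits


def assign_reads_to_loci(
    hits: Iterable[DecoyHit],
    locus_index: LocusIndex,
    max_dist: int = 500,
    sample_id: str = "",
    median_coverage: float = float("nan"),
) -> LocusCountTable:
    """Allocate decoy hits to STR loci via their mates.

    Hits whose mate is unmapped or itself on a decoy chromosome, or whose
    mate is near no same-unit locus, are tallied under ``unassigned`` by
    unit, so assigned + unassigned always equals the decoy read total.
    """
    table = LocusCountTable(sample_id=sample_id, median_coverage=median_coverage)
    for hit in hits:
        locus = None
        if hit.mate_mapped and hit.mate_chrom and not hit.mate_chrom.startswith(DECOY_PREFIX):
            locus = locus_index.nearest(
                hit.mate_chrom, hit.mate_start, hit.mate_end, hit.unit, max_dist
            )
        if locus is None:
            table.unassigned[hit.unit] = table.unassigned.get(hit.unit, 0) + 1
        else:
            lid = locus.locus_id
            table.assigned[lid] = table.assigned.get(lid, 0) + 1
    return table


def extract_candidate_reads(
    alignment: str | os.PathLike | pysam.AlignmentFile,
    regions: GenomeRegionSet,
) -> list[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Extract complete read pairs likely to contain STR sequence.

    A pair qualifies if at least one mate overlaps an extraction region
    (STR loci widened by their flank) or is unmapped.  Unpaired reads
    (mate absent from the stream) are discarded.  Each pair is returned
    once, primary alignments only.
    """
    af, close = _open(alignment)
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[tuple[pysam.AlignedSegment, pysam.AlignedSegment]] = []
    try:
        for read in af:
            if read.is_secondary or read.is_supplementary or not read.is_paired:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            if any(
                r.is_unmapped
                or regions.overlaps(r.reference_name, r.reference_start, r.reference_end)
                for r in (r1, r2)
            ):
                pairs.append((r1, r2))
    finally:
        if close:
            af.close()
    if pending:
        logger.info("discarded %d unpaired reads", len(pending))
    return pairs


def write_fastq_pairs(
    pairs: Sequence[tuple[pysam.AlignedSegment, pysam.AlignedSegment]],
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
) -> None:
    """Emit extracted pairs as name-matched R1/R2 FASTQ for re-mapping."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r1, r2 in pairs:
            for read, fh in ((r1, f1), (r2, f2)):
                seq = read.get_forward_sequence() or ""
                if read.query_qualities is not None:
                    qual = "".join(chr(q + 33) for q in read.get_forward_qualities())
                else:
                    qual = "I" * len(seq)
                fh.write(f"@{read.query_name}\n{seq}\n+\n{qual}\n")


def median_coverage(
    alignment: str | os.PathLike | pysam.AlignmentFile,
    target: GenomeRegionSet | None = None,
    stride: int = 1000,
) -> float:
    """Median per-base depth sampled on a deterministic position grid.

    Depth is evaluated every ``stride`` bp on each non-decoy contig (or on
    ``target`` regions when given), counting primary mapped non-duplicate
    reads covering the position.  Works on plain (unindexed) SAM by a
    single streaming pass.
    """
    af, close = _open(alignment)
    try:
        lengths = {c: l for c, l in zip(af.references, af.lengths)
                   if not c.startswith(DECOY_PREFIX)}
        starts: dict[str, list[int]] = {c: [] for c in lengths}
        ends: dict[str, list[int]] = {c: [] for c in lengths}
        for read in af:
            if not _is_countable(read):
                continue
            c = read.reference_name
            if c in lengths:
                starts[c].append(read.reference_start)
                ends[c].append(read.reference_end)
    finally:
        if close:
            af.close()

    if target is None:
        grid = {c: range(0, l, stride) for c, l in lengths.items()}
    else:
        grid = {}
        for chrom, s, e in target:
            if chrom in lengths:
                grid.setdefault(chrom, [])
                grid[chrom] = list(grid[chrom]) + list(range(s, min(e, lengths[chrom]), stride))

    depths: list[int] = []
    for chrom, positions in grid.items():
        pos = np.fromiter(positions, dtype=np.int64)
        if pos.size == 0:
            continue
        s = np.sort(np.asarray(starts[chrom], dtype=np.int64))
        e = np.sort(np.asarray(ends[chrom], dtype=np.int64))
        # depth(p) = #reads with start <= p minus #reads with end <= p
        depth = np.searchsorted(s, pos, side="right") - np.searchsorted(e, pos, side="right")
        depths.extend(depth.tolist())
    if not depths:
        raise ValueError("no usable positions for median coverage")
    return float(statistics.median(depths))
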