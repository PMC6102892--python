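"""Synthetic decoy-aware alignment generator.

Emulates paired-end short-read sequencing of diploid STR loci in which one
allele may be expanded, and emits the alignments a decoy-aware aligner
would produce — directly as SAM, so the rest of the package can be
exercised without an external aligner or reference download.

The model: fragments are drawn uniformly along each haplotype (flank +
repeat tract + flank), with fragment length ~ Normal(insert_mean,
insert_sd) and each haplotype sequenced at half the total coverage, so
fragment counts are proportional to haplotype length.  A read whose STR
tract content is at least ``str_fraction`` of its bases is emitted as
aligned to the decoy chromosome of the locus's unit; all other reads are
placed at their (reference-projected) genomic position.  Pairs where both
reads are repeat-saturated land wholly on the decoy — reproducing the
signal saturation seen for alleles much longer than the insert size.

Defaults mirror a standard 30x PCR-free WGS run: 150 bp paired-end reads,
insert 500 +/- 50 bp.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import STRLocus
from .motifs import decoy_name, revcomp

__all__ = [
    "ExpansionSpec",
    "LocusTruth",
    "simulate_locus_reads",
    "simulate_cohort",
    "simulate_calibration_dataset",
    "make_test_loci",
    "make_header",
    "write_sam",
    "DEFAULT_DECOY_LENGTH",
]

DEFAULT_DECOY_LENGTH = 2000


@dataclass(frozen=True)
class ExpansionSpec:
    """One simulated diploid locus: allele_a copies / allele_b copies."""

    locus: STRLocus
    allele_b_units: int
    allele_a_units: int = 16
    coverage: float = 30.0
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    seed: int | None = None
    flank: int = 1000
    str_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("ExpansionSpec requires an explicit seed")
        if self.read_length <= 0 or self.coverage <= 0:
            raise ValueError("read_length and coverage must be positive")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if self.locus.start < self.flank:
            raise ValueError(
                f"locus start {self.locus.start} leaves no room for a "
                f"{self.flank} bp left flank"
            )
        if min(self.allele_a_units, self.allele_b_units) < 0:
            raise ValueError("allele sizes must be >= 0")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one simulated locus in one sample."""

    sample_id: str
    locus_id: str
    allele_a_units: int
    allele_b_units: int
    decoy_reads: int       # reads emitted on the decoy chromosome
    assigned_reads: int    # decoy reads whose mate localizes them to the locus
    pairs: int             # fragments generated


class _Read:
    __slots__ = ("chrom", "pos", "reverse", "hap", "hap_start", "is_decoy")

    def __init__(self, chrom, pos, reverse, hap, hap_start, is_decoy):
        self.chrom = chrom
        self.pos = pos
        self.reverse = reverse
        self.hap = hap
        self.hap_start = hap_start
        self.is_decoy = is_decoy


def _simulate_pairs(spec: ExpansionSpec, rng: np.random.Generator):
    """Fragment placement for both haplotypes; returns list of read pairs."""
    locus = spec.locus
    unit_len = len(locus.unit)
    ref_tract = locus.end - locus.start
    region_start = locus.start - spec.flank
    rl = spec.read_length
    dname = decoy_name(locus.unit)
    decoy_span = max(1, DEFAULT_DECOY_LENGTH - rl)
    pairs = []
    for hap, allele in enumerate((spec.allele_a_units, spec.allele_b_units)):
        tract = allele * unit_len
        hap_len = 2 * spec.flank + tract
        delta = tract - ref_tract
        n_pairs = int(round((spec.coverage / 2.0) * hap_len / (2.0 * rl)))
        if n_pairs == 0:
            continue
        frag = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs))
        frag = np.clip(frag, rl, hap_len).astype(np.int64)
        starts = np.floor(rng.random(n_pairs) * (hap_len - frag + 1)).astype(np.int64)

        def project(p: int) -> int:
            if p < spec.flank:
                return region_start + p
            if p >= spec.flank + tract:
                return region_start + p - delta
            return region_start + spec.flank + min(p - spec.flank, max(ref_tract - 1, 0))

        for s, f in zip(starts.tolist(), frag.tolist()):
            reads = []
            for rs, rev in ((s, False), (s + f - rl, True)):
                ov = min(rs + rl, spec.flank + tract) - max(rs, spec.flank)
                if ov / rl >= spec.str_fraction:
                    reads.append(_Read(dname, rs % decoy_span, rev, hap, rs, True))
                else:
                    reads.append(_Read(locus.chrom, project(rs), rev, hap, rs, False))
            pairs.append((reads[0], reads[1], f))
    return pairs


def _count_pairs(spec: ExpansionSpec, pairs, max_dist: int = 500) -> tuple[int, int]:
    """(decoy reads, mate-allocatable decoy reads) for a simulated locus."""
    locus = spec.locus
    rl = spec.read_length
    decoy = assigned = 0
    for r1, r2, _f in pairs:
        for read, mate in ((r1, r2), (r2, r1)):
            if not read.is_decoy:
                continue
            decoy += 1
            if mate.is_decoy:
                continue
            gap = max(locus.start - (mate.pos + rl), mate.pos - locus.end, 0)
            if gap <= max_dist:
                assigned += 1
    return decoy, assigned


def _hap_sequence(spec: ExpansionSpec, allele_units: int) -> str:
    """Deterministic haplotype sequence: flanks keyed on the locus identity."""
    locus = spec.locus
    tag = f"{locus.chrom}:{locus.start}-{locus.end}"
    rng = np.random.default_rng(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, spec.flank))
    right = "".join(rng.choice(bases, spec.flank))
    return left + locus.unit * allele_units + right


def make_header(
    contigs: Mapping[str, int],
    units: Iterable[str],
    decoy_length: int = DEFAULT_DECOY_LENGTH,
) -> pysam.AlignmentHeader:
    sq = [{"SN": c, "LN": int(l)} for c, l in contigs.items()]
    sq += [{"SN": decoy_name(u), "LN": decoy_length} for u in sorted(set(units))]
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    )


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    read: _Read,
    mate: _Read,
    first: bool,
    frag: int,
    rl: int,
    seq: str | None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    flag = 0x1
    if read.chrom == mate.chrom:
        flag |= 0x2
    if read.reverse:
        flag |= 0x10
    if mate.reverse:
        flag |= 0x20
    flag |= 0x40 if first else 0x80
    a.flag = flag
    a.reference_id = header.get_tid(read.chrom)
    a.reference_start = int(read.pos)
    a.mapping_quality = 0 if read.is_decoy else 60
    a.cigartuples = [(0, rl)]
    a.next_reference_id = header.get_tid(mate.chrom)
    a.next_reference_start = int(mate.pos)
    if read.chrom == mate.chrom:
        left = min(read.pos, mate.pos)
        tlen = max(read.pos, mate.pos) + rl - left
        a.template_length = tlen if read.pos == left else -tlen
    else:
        a.template_length = 0
    if seq is not None:
        a.query_sequence = revcomp(seq) if read.reverse else seq
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
    return a


def simulate_locus_reads(
    spec: ExpansionSpec,
    header: pysam.AlignmentHeader | None = None,
    sample_id: str = "sim",
    with_sequences: bool = True,
) -> tuple[list[pysam.AlignedSegment], LocusTruth]:
    """Simulate one diploid locus and return decoy-aware SAM records + truth.

    Deterministic given ``spec.seed``.  When ``header`` is omitted a
    minimal one covering the locus contig and its decoy is created.
    """
    locus = spec.locus
    if header is None:
        header = make_header(
            {locus.chrom: locus.end + spec.flank}, [locus.unit]
        )
    rng = np.random.default_rng(spec.seed)
    pairs = _simulate_pairs(spec, rng)
    decoy, assigned = _count_pairs(spec, pairs)
    haps = None
    if with_sequences:
        haps = [_hap_sequence(spec, spec.allele_a_units),
                _hap_sequence(spec, spec.allele_b_units)]
    records: list[pysam.AlignedSegment] = []
    rl = spec.read_length
    for i, (r1, r2, frag) in enumerate(pairs):
        qname = f"{sample_id}:{locus.chrom}_{locus.start}:h{r1.hap}:{i}"
        for read, mate, first in ((r1, r2, True), (r2, r1, False)):
            seq = haps[read.hap][read.hap_start:read.hap_start + rl] if haps else None
            records.append(_make_record(header, qname, read, mate, first, frag, rl, seq))
    truth = LocusTruth(
        sample_id=sample_id,
        locus_id=locus.locus_id,
        allele_a_units=spec.allele_a_units,
        allele_b_units=spec.allele_b_units,
        decoy_reads=decoy,
        assigned_reads=assigned,
        pairs=len(pairs),
    )
    return records, truth


def write_sam(
    records: Sequence[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | os.PathLike,
) -> str:
    """Write records coordinate-sorted as headered SAM text."""
    ordered = sorted(records, key=lambda r: (r.reference_id, r.reference_start,
                                             r.query_name, r.flag))
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for r in ordered:
            out.write(r)
    return os.fspath(path)


def make_test_loci(
    n: int,
    seed: int,
    chrom: str = "chrS",
    spacing: int = 5000,
    first_start: int = 2000,
) -> list[STRLocus]:
    """Well-separated synthetic STR loci with varied units and copy numbers."""
    rng = np.random.default_rng(seed)
    units = ["AGC", "AAAG", "AT", "AAG", "ACAG", "AAAAT", "AC"]
    loci = []
    for i in range(n):
        unit = units[int(rng.integers(len(units)))]
        copies = int(rng.integers(8, 21))
        start = first_start + i * spacing
        loci.append(STRLocus(chrom, start, start + copies * len(unit), unit,
                             float(copies)))
    return loci


def _max_ref_str_fraction(locus: STRLocus, read_length: int) -> float:
    return (locus.end - locus.start) / read_length


def simulate_cohort(
    n_samples: int,
    loci: Sequence[STRLocus],
    spike: Mapping[str, ExpansionSpec],
    seed: int,
    out_dir: str | os.PathLike,
    noise_rate: float = 1.0,
    coverage: float = 30.0,
    read_length: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    flank: int = 1000,
    background_length: int = 6000,
    str_fraction: float = 0.9,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate a cohort of decoy-aware SAM files plus a truth table.

    Non-spiked samples carry reference-length alleles at every locus, plus
    Poisson(``noise_rate``) stray decoy read pairs per locus whose mates
    localize to the locus (ambient repeat reads).  Each sample also
    carries a uniformly covered background contig ``chrBG`` that defines
    its median coverage.  Reference-length loci whose tract is too short
    for any read to reach the STR-content threshold are provably decoy-free
    and skip fragment simulation.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for a cohort")
    sample_ids = [f"sample_{i:03d}" for i in range(n_samples)]
    unknown = set(spike) - set(sample_ids)
    if unknown:
        raise ValueError(f"spike references unknown samples: {sorted(unknown)}")
    by_id = {l.locus_id: l for l in loci}
    for sid, sp in spike.items():
        if sp.locus.locus_id not in by_id:
            raise ValueError(f"spike locus {sp.locus.locus_id} not in cohort loci")

    contigs: dict[str, int] = {"chrBG": background_length}
    for l in loci:
        contigs[l.chrom] = max(contigs.get(l.chrom, 0), l.end + flank)
    header = make_header(contigs, [l.unit for l in loci])

    os.makedirs(out_dir, exist_ok=True)
    rl = read_length
    paths: dict[str, str] = {}
    truth_rows = []
    for idx, sid in enumerate(sample_ids):
        rng = np.random.default_rng([seed, idx])
        records: list[pysam.AlignedSegment] = []

        # background contig at uniform coverage -> median coverage anchor
        n_bg = int(round(coverage * background_length / (2.0 * rl)))
        frag = np.clip(np.rint(rng.normal(insert_mean, insert_sd, n_bg)),
                       rl, background_length).astype(np.int64)
        starts = np.floor(rng.random(n_bg) * (background_length - frag + 1)).astype(np.int64)
        for i, (s, f) in enumerate(zip(starts.tolist(), frag.tolist())):
            r1 = _Read("chrBG", s, False, 0, s, False)
            r2 = _Read("chrBG", s + f - rl, True, 0, s + f - rl, False)
            qn = f"{sid}:bg:{i}"
            records.append(_make_record(header, qn, r1, r2, True, f, rl, None))
            records.append(_make_record(header, qn, r2, r1, False, f, rl, None))

        for l in loci:
            sp = spike.get(sid)
            spiked_here = sp is not None and sp.locus.locus_id == l.locus_id
            if spiked_here:
                spec = replace(sp, seed=int(rng.integers(2**31)))
            else:
                spec = ExpansionSpec(
                    locus=l,
                    allele_a_units=int(round(l.ref_copies)),
                    allele_b_units=int(round(l.ref_copies)),
                    coverage=coverage, read_length=rl,
                    insert_mean=insert_mean, insert_sd=insert_sd,
                    seed=int(rng.integers(2**31)), flank=flank,
                    str_fraction=str_fraction,
                )
            decoy = assigned = pairs = 0
            if spiked_here or _max_ref_str_fraction(l, rl) >= str_fraction:
                recs, t = simulate_locus_reads(spec, header=header, sample_id=sid,
                                               with_sequences=False)
                records.extend(recs)
                decoy, assigned, pairs = t.decoy_reads, t.assigned_reads, t.pairs
            # ambient decoy noise pairs, mate at the locus
            k = int(rng.poisson(noise_rate))
            for j in range(k):
                dpos = int(rng.integers(0, DEFAULT_DECOY_LENGTH - rl))
                mpos = max(0, l.start - int(rng.integers(0, 300)))
                rd = _Read(decoy_name(l.unit), dpos, False, 0, dpos, True)
                rm = _Read(l.chrom, mpos, True, 0, mpos, False)
                qn = f"{sid}:noise:{l.locus_id}:{j}"
                records.append(_make_record(header, qn, rd, rm, True, 0, rl, None))
                records.append(_make_record(header, qn, rm, rd, False, 0, rl, None))
            decoy += k
            assigned += k
            truth_rows.append(
                (sid, l.locus_id, spec.allele_a_units, spec.allele_b_units,
                 decoy, assigned, pairs)
            )

        path = os.path.join(os.fspath(out_dir), f"{sid}.sam")
        write_sam(records, header, path)
        paths[sid] = path

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "locus_id", "allele_a_units", "allele_b_units",
                 "decoy_reads", "assigned_reads", "pairs"],
    )
    return paths, truth


def simulate_calibration_dataset(
    n: int = 100,
    size_range: tuple[int, int] = (0, 500),
    seed: int | None = None,
    locus: STRLocus | None = None,
    coverage: float = 30.0,
    read_length: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    flank: int = 1000,
) -> list[tuple[float, float]]:
    """(log2 normalized decoy read count, log2 inserted bp) calibration pairs.

    Simulates ``n`` diploid individuals at one locus with the short allele
    held at the reference copy number and the other allele uniform on
    ``size_range`` repeat units, mirroring a 16xAGC/Nx AGC design.  The
    response is the total decoy-mapped read count — in a single-locus
    simulation every decoy read belongs to that locus — which grows
    linearly with tract length.  (Per-locus counts measured on real data
    come from mate allocation and saturate near the insert size, which is
    why very long alleles are underestimated.)  Individuals with zero
    decoy reads or a non-positive insertion are dropped (log undefined).
    """
    from .stats import normalize_count

    if n < 10:
        raise ValueError("need n >= 10 calibration individuals")
    if seed is None:
        raise ValueError("simulate_calibration_dataset requires a seed")
    if locus is None:
        locus = STRLocus("chrSim", 2000, 2048, "AGC", 16.0)
    rng = np.random.default_rng(seed)
    ref_units = int(round(locus.ref_copies))
    unit_len = len(locus.unit)
    points: list[tuple[float, float]] = []
    for _ in range(n):
        allele_b = int(rng.integers(size_range[0], size_range[1] + 1))
        spec = ExpansionSpec(
            locus=locus, allele_a_units=ref_units, allele_b_units=allele_b,
            coverage=coverage, read_length=read_length,
            insert_mean=insert_mean, insert_sd=insert_sd,
            seed=int(rng.integers(2**31)), flank=flank,
        )
        pairs = _simulate_pairs(spec, np.random.default_rng(spec.seed))
        decoy, _assigned = _count_pairs(spec, pairs)
        inserted_bp = (allele_b - ref_units) * unit_len
        if decoy > 0 and inserted_bp > 0:
            y = normalize_count(decoy, coverage)
            points.append((y, float(np.log2(inserted_bp))))
    return points
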