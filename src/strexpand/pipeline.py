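"""End-to-end orchestration: allocate -> normalize -> test -> size -> report.

Reports are tab-delimited, one row per locus with at least one assigned
read in the sample, sorted so the most significant candidate expansions
come first (ascending adjusted p, ties broken by descending z then
locus_id).  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import allocation, stats
from .annotation import GenomeRegionSet, LocusIndex, STRLocus, parse_str_bed
from .sizing import CalibrationModel, estimate_allele_size, load_default_calibration
from .stats import ControlParameters, OutlierCall

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportRow", "REPORT_COLUMNS", "write_report",
           "build_report_rows", "run_pipeline"]

REPORT_COLUMNS = [
    "chrom", "start", "end", "unit", "ref_copies", "sample_id",
    "raw_count", "normalized_count", "z", "p", "p_adj",
    "estimated_size_units",
]


@dataclass(frozen=True)
class ReportRow:
    chrom: str
    start: int
    end: int
    unit: str
    ref_copies: float
    sample_id: str
    raw_count: int
    normalized_count: float
    z: float
    p: float
    p_adj: float
    estimated_size_units: float


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one control mode is active."""

    annotation_path: str
    output_dir: str
    bed_dialect: str = "bed"
    control_mode: str = "internal"          # "internal" | "reference-file"
    controls_path: str | None = None
    alpha: float = stats.DEFAULT_ALPHA
    max_dist: int = 500
    flank: int = 800
    calibration_path: str | None = None
    median_coverage: float | None = None    # bypass computation when given
    coverage_target: list[tuple[str, int, int]] | None = None
    stride: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.control_mode not in ("internal", "reference-file"):
            raise ValueError(f"unknown control mode {self.control_mode!r}")
        if (self.control_mode == "reference-file") != (self.controls_path is not None):
            raise ValueError(
                "controls_path must be given exactly when control_mode is "
                "'reference-file'"
            )
        if not os.path.exists(self.annotation_path):
            raise ValueError(f"annotation not found: {self.annotation_path}")
        if self.controls_path and not os.path.exists(self.controls_path):
            raise ValueError(f"controls not found: {self.controls_path}")
        if self.calibration_path and not os.path.exists(self.calibration_path):
            raise ValueError(f"calibration not found: {self.calibration_path}")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(rows: Sequence[ReportRow], path: str | os.PathLike) -> str:
    """Write report rows, most significant first, with fixed column order."""
    ordered = sorted(
        rows,
        key=lambda r: (r.p_adj, -r.z, f"{r.chrom}:{r.start}-{r.end}:{r.unit}"),
    )
    with open(path, "w") as fh:
        fh.write("#coordinates: 0-based half-open\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in ordered:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in REPORT_COLUMNS) + "\n")
    return os.fspath(path)


def read_report(path: str | os.PathLike) -> list[ReportRow]:
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            d = dict(zip(header, line.split("\t")))
            rows.append(ReportRow(
                chrom=d["chrom"], start=int(d["start"]), end=int(d["end"]),
                unit=d["unit"], ref_copies=float(d["ref_copies"]),
                sample_id=d["sample_id"], raw_count=int(d["raw_count"]),
                normalized_count=float(d["normalized_count"]), z=float(d["z"]),
                p=float(d["p"]), p_adj=float(d["p_adj"]),
                estimated_size_units=float(d["estimated_size_units"]),
            ))
    return rows


def build_report_rows(
    calls: Sequence[OutlierCall],
    loci_by_id: dict[str, STRLocus],
    calibration: CalibrationModel,
) -> list[ReportRow]:
    rows = []
    for c in calls:
        locus = loci_by_id[c.locus_id]
        est = estimate_allele_size(c.y, calibration, locus)
        rows.append(ReportRow(
            chrom=locus.chrom, start=locus.start, end=locus.end,
            unit=locus.unit, ref_copies=locus.ref_copies,
            sample_id=c.sample_id, raw_count=c.raw_count,
            normalized_count=c.y, z=c.z, p=c.p, p_adj=c.p_adj,
            estimated_size_units=est.repeat_units_total,
        ))
    return rows


def _count_sample(
    path: str, index: LocusIndex, config: RunConfig, sample_id: str
) -> allocation.LocusCountTable:
    hits = allocation.collect_decoy_hits(path)
    if config.median_coverage is not None:
        mcov = config.median_coverage
    else:
        target = (GenomeRegionSet(config.coverage_target)
                  if config.coverage_target else None)
        mcov = allocation.median_coverage(path, target=target, stride=config.stride)
    table = allocation.assign_reads_to_loci(
        hits, index, max_dist=config.max_dist,
        sample_id=sample_id, median_coverage=mcov,
    )
    logger.info("%s: %d decoy reads, %d assigned, median coverage %.1f",
                sample_id, len(hits), sum(table.assigned.values()), mcov)
    return table


def run_pipeline(
    config: RunConfig, sample_alignments: Sequence[str | os.PathLike]
) -> dict[str, str]:
    """Run the full pipeline; returns sample_id -> report path.

    Sample ids are alignment file basenames without extension.  In
    internal-control mode the null parameters are estimated across all
    provided samples (each sample is included in its own null; robust
    estimation keeps a minority of true expansions from inflating it).
    """
    config.validate()
    loci = parse_str_bed(config.annotation_path, dialect=config.bed_dialect)
    index = LocusIndex(loci)
    loci_by_id = {l.locus_id: l for l in loci}
    calibration = (CalibrationModel.from_json(config.calibration_path)
                   if config.calibration_path else load_default_calibration())
    os.makedirs(config.output_dir, exist_ok=True)

    sample_ids = [os.path.splitext(os.path.basename(os.fspath(p)))[0]
                  for p in sample_alignments]
    tables = [
        _count_sample(os.fspath(p), index, config, sid)
        for p, sid in zip(sample_alignments, sample_ids)
    ]

    if config.control_mode == "internal":
        controls = stats.build_control_parameters(tables)
    else:
        controls = ControlParameters.from_tsv(config.controls_path)

    with open(os.path.join(config.output_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)

    reports: dict[str, str] = {}
    for table in tables:
        calls = stats.call_outliers(table, controls, alpha=config.alpha)
        rows = build_report_rows(calls, loci_by_id, calibration)
        out = os.path.join(config.output_dir, f"{table.sample_id}.report.tsv")
        reports[table.sample_id] = write_report(rows, out)
    return reports
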