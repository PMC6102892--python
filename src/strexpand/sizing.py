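"""Allele-size estimation from normalized decoy read counts.

The number of reads containing STR sequence grows with the length of the
expanded allele, so after calibrating a linear model on simulated data

    y = beta0 + beta * x + eps,   eps ~ N(0, sigma^2),

with y = log2(normalized decoy coverage at the locus) and x = log2(allele
size in inserted base pairs), the size of a new expansion is estimated by
inverting the fit:

    log2(allele_size) = (log2(coverage) - beta0) / beta.

Estimates saturate for alleles much longer than the sequencing insert size
(both mates of a fragment then lie wholly inside the repeat, map to the
decoy, and cannot be allocated to the locus), so very large expansions are
underestimated; this is inherent to the read-pair signal and is not
corrected here.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Sequence

import numpy as np

from .annotation import STRLocus

__all__ = [
    "CalibrationModel",
    "AlleleSizeEstimate",
    "fit_calibration",
    "estimate_allele_size",
    "load_default_calibration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """OLS fit of log2(coverage) on log2(allele size in bp)."""

    beta0: float
    beta: float
    residual_sd: float
    n_points: int
    note: str = ""

    def to_json(self, path: str | os.PathLike) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")
        return os.fspath(path)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class AlleleSizeEstimate:
    locus_id: str
    inserted_bp: float
    repeat_units_total: float


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Least-squares line through (log2_coverage, log2_allele_bp) pairs.

    log2_coverage is the response, log2_allele_bp the predictor.  The
    residual standard deviation uses n - 2 degrees of freedom (0 for an
    exactly interpolating two-point fit).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    y = np.asarray([p[0] for p in points], dtype=float)
    x = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("calibration points have no spread in allele size")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta0, beta = float(coef[0]), float(coef[1])
    resid = y - (beta0 + beta * x)
    n = len(points)
    rss = float(resid @ resid)
    residual_sd = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    if rss < 1e-20:
        residual_sd = 0.0
    return CalibrationModel(beta0=beta0, beta=beta, residual_sd=residual_sd, n_points=n)


def estimate_allele_size(
    y_log2_coverage: float,
    model: CalibrationModel,
    locus: STRLocus,
) -> AlleleSizeEstimate:
    """Invert the calibration to get inserted bp and total repeat units.

    ``inserted_bp = 2 ** ((y - beta0) / beta)`` is the estimated number of
    bases inserted relative to the reference allele; the total size in
    repeat units adds the reference copy number.
    """
    if model.beta == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    inserted_bp = 2.0 ** ((y_log2_coverage - model.beta0) / model.beta)
    units_total = locus.ref_copies + inserted_bp / len(locus.unit)
    return AlleleSizeEstimate(
        locus_id=locus.locus_id,
        inserted_bp=inserted_bp,
        repeat_units_total=units_total,
    )


def load_default_calibration() -> CalibrationModel:
    """Calibration shipped with the package.

    Fitted on the package's own read simulator (synthetic data emulating a
    16-copy/N-copy AGC locus, N in 0-500, 150 bp paired-end reads, 30x
    coverage, insert 500 +/- 50 bp); see the bundled JSON's note field.
    Users sequencing under different conditions should refit with
    ``strexpand calibrate``.
    """
    ref = resources.files("strexpand").joinpath("data/calibration_default.json")
    with resources.as_file(ref) as path:
        return CalibrationModel.from_json(path)
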