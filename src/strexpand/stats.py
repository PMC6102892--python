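"""Outlier statistics for STR expansion detection.

Per-locus decoy read counts are log2-normalized to a median coverage of
100x, a robust location M and scale sigma_M are estimated across control
samples with Huber's joint location/scale M-estimator ("Proposal 2"), and
each test sample receives a robust z-score

    z = (y - M) / sigma_M

with a one-sided upper-tail normal p-value (the alternative is that the
sample's log-normalized count exceeds the control median, i.e. an
expansion).  P-values are Benjamini-Hochberg adjusted across all loci
with at least one assigned read in the tested sample.

The Huber estimator is used so that genuine expansions present among the
controls inflate neither the location nor the scale of the null.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .allocation import LocusCountTable
from .annotation import STRLocus, parse_locus_id

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_SCALE_FLOOR",
    "ControlParameters",
    "OutlierCall",
    "normalize_count",
    "huber_location_scale",
    "outlier_test",
    "adjust_bh",
    "build_control_parameters",
    "call_outliers",
]

DEFAULT_ALPHA = 0.05

#: Minimum sigma_M on the log2 scale.  Without a floor, a locus whose
#: control counts are all identical would give an infinite z-score for a
#: single extra read.
DEFAULT_SCALE_FLOOR = 0.01


def normalize_count(raw: int, median_cov: float) -> float:
    """Log2 read count normalized to a median sample coverage of 100x.

    ``log2(100 * (raw + 1) / median_cov)``; the +1 keeps zero counts finite.
    """
    if median_cov <= 0 or not math.isfinite(median_cov):
        raise ValueError(f"median coverage must be positive, got {median_cov}")
    if raw < 0:
        raise ValueError("raw count must be >= 0")
    return math.log2(100.0 * (raw + 1) / median_cov)


def _huber_kappa(k: float) -> float:
    # E[min(|Z|, k)^2] for standard normal Z; consistency constant for the
    # Proposal-2 scale equation.
    return (2 * norm.cdf(k) - 1) - 2 * k * norm.pdf(k) + 2 * k * k * norm.sf(k)


def huber_location_scale(
    values: Sequence[float],
    tuning_k: float = 1.5,
    tol: float = 1e-6,
    max_iter: int = 200,
    scale_floor: float = DEFAULT_SCALE_FLOOR,
) -> tuple[float, float]:
    """Huber's joint location/scale fixed point ("Proposal 2").

    Iterates

        M   <- M + s * mean(psi_k((x - M)/s))
        s^2 <- s^2 * sum(psi_k((x - M)/s)^2) / ((n - 1) * kappa(k))

    from the median and normalized MAD until both changes fall below
    ``tol`` (relative to s).  On non-convergence it falls back to the
    median and normalized MAD with a warning.  The returned scale is
    floored at ``scale_floor`` (degenerate inputs drive s to zero).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    med = float(np.median(x))
    mad = 1.482602218505602 * float(np.median(np.abs(x - med)))
    if np.ptp(x) == 0:
        return med, scale_floor
    M = med
    s = mad if mad > 0 else float(np.std(x))
    kappa = _huber_kappa(tuning_k)
    n = x.size
    converged = False
    for _ in range(max_iter):
        if s < 1e-12:  # collapsed onto the majority value
            converged = True
            break
        u = (x - M) / s
        psi = np.clip(u, -tuning_k, tuning_k)
        M_new = M + s * float(psi.mean())
        s_new = s * math.sqrt(float((psi**2).sum()) / ((n - 1) * kappa))
        done = abs(M_new - M) < tol * s and abs(s_new - s) < tol * s
        # Once the scale shrinks below the floor the clipped update factor is
        # constant and < 1: collapse onto the majority value is certain.
        collapsing = s_new < min(s, scale_floor)
        M, s = M_new, s_new
        if done or collapsing:
            converged = True
            break
    if not converged:
        logger.warning(
            "Huber Proposal-2 did not converge in %d iterations; "
            "falling back to median/MAD", max_iter,
        )
        M, s = med, mad
    return float(M), float(max(s, scale_floor))


def outlier_test(y: float, M: float, sigma_M: float) -> tuple[float, float]:
    """Robust z-score and one-sided upper-tail normal p-value.

    ``z = (y - M) / sigma_M``; p is P(Z >= z) under the standard normal, so
    values below the control location give p > 0.5 rather than NA.
    """
    if sigma_M <= 0:
        raise ValueError("sigma_M must be positive (apply the scale floor first)")
    z = (y - M) / sigma_M
    return z, float(norm.sf(z))


def adjust_bh(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, position-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass
class ControlParameters:
    """Per-locus robust null parameters estimated from control samples."""

    params: dict[str, tuple[float, float, int]]  # locus_id -> (M, sigma_M, n)

    def __len__(self) -> int:
        return len(self.params)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.params

    def median_sigma(self) -> float:
        if not self.params:
            raise ValueError("no control parameters")
        return float(np.median([s for _, s, _ in self.params.values()]))

    def to_tsv(self, path: str | os.PathLike) -> str:
        rows = []
        for lid in sorted(self.params):
            locus = parse_locus_id(lid)
            M, s, n = self.params[lid]
            rows.append((lid, locus.chrom, locus.start, locus.end, locus.unit,
                         repr(M), repr(s), n))
        pd.DataFrame(
            rows,
            columns=["locus_id", "chrom", "start", "end", "unit",
                     "M", "sigma_M", "n_controls"],
        ).to_csv(path, sep="\t", index=False)
        return os.fspath(path)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ControlParameters":
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
        return cls(
            {r.locus_id: (float(r.M), float(r.sigma_M), int(r.n_controls))
             for r in df.itertuples()}
        )


def build_control_parameters(
    count_tables: Sequence[LocusCountTable],
    tuning_k: float = 1.5,
    scale_floor: float = DEFAULT_SCALE_FLOOR,
) -> ControlParameters:
    """Estimate (M, sigma_M) for every locus seen in any control table.

    Samples lacking a locus contribute a raw count of 0 (the absence of
    decoy reads is informative, not missing data).
    """
    if len(count_tables) < 2:
        raise ValueError("need at least 2 control samples")
    loci: set[str] = set()
    for t in count_tables:
        loci |= set(t.assigned)
    params: dict[str, tuple[float, float, int]] = {}
    for lid in loci:
        ys = [
            normalize_count(t.assigned.get(lid, 0), t.median_coverage)
            for t in count_tables
        ]
        M, s = huber_location_scale(ys, tuning_k=tuning_k, scale_floor=scale_floor)
        params[lid] = (M, s, len(ys))
    return ControlParameters(params)


@dataclass(frozen=True)
class OutlierCall:
    locus_id: str
    sample_id: str
    raw_count: int
    y: float
    z: float
    p: float
    p_adj: float
    significant: bool


def call_outliers(
    sample: LocusCountTable,
    controls: ControlParameters,
    alpha: float = DEFAULT_ALPHA,
) -> list[OutlierCall]:
    """Test every locus with >= 1 assigned read in ``sample`` for expansion.

    Loci absent from the controls (e.g. added to the annotation after the
    control parameters were built) are still tested, using the normalized
    zero count as location and the median control sigma as scale.  BH
    adjustment runs across exactly this call set; output is sorted by
    ascending p (ties: larger z, then locus_id).
    """
    if not len(controls):
        raise ValueError("controls are empty")
    tested = sorted(lid for lid, n in sample.assigned.items() if n >= 1)
    if not tested:
        return []
    fallback_M = normalize_count(0, 100.0)
    fallback_s = controls.median_sigma()
    zs, ps = [], []
    for lid in tested:
        if lid in controls:
            M, s, _ = controls.params[lid]
        else:
            logger.info("locus %s absent from controls; using fallback parameters", lid)
            M, s = fallback_M, fallback_s
        y = normalize_count(sample.assigned[lid], sample.median_coverage)
        z, p = outlier_test(y, M, s)
        zs.append(z)
        ps.append(p)
    p_adj = adjust_bh(ps)
    calls = [
        OutlierCall(
            locus_id=lid,
            sample_id=sample.sample_id,
            raw_count=sample.assigned[lid],
            y=normalize_count(sample.assigned[lid], sample.median_coverage),
            z=z,
            p=p,
            p_adj=pa,
            significant=pa < alpha,
        )
        for lid, z, p, pa in zip(tested, zs, ps, p_adj)
    ]
    calls.sort(key=lambda c: (c.p, -c.z, c.locus_id))
    return calls
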