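"""Normalization, robust location/scale, outlier testing, BH adjustment."""

import math

import numpy as np
import pytest
from scipy.stats import norm
from statsmodels.robust.scale import Huber as SmHuber

from strexpand.allocation import LocusCountTable
from strexpand.stats import (
    DEFAULT_SCALE_FLOOR,
    ControlParameters,
    adjust_bh,
    build_control_parameters,
    call_outliers,
    huber_location_scale,
    normalize_count,
    outlier_test,
)


class TestNormalizeCount:
    @pytest.mark.parametrize(
        "raw,cov,expected",
        [
            (0, 100.0, 0.0),
            (99, 100.0, math.log2(100)),
            (0, 50.0, 1.0),
        ],
    )
    def test_values(self, raw, cov, expected):
        assert normalize_count(raw, cov) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_raw(self):
        ys = [normalize_count(r, 30.0) for r in range(0, 50)]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    @pytest.mark.parametrize("cov", [0.0, -1.0, float("nan")])
    def test_bad_coverage_rejected(self, cov):
        with pytest.raises(ValueError):
            normalize_count(1, cov)


def _oracle_proposal2(values, k=1.5, tol=1e-10, iters=5000):
    """Independent brute-force fixed-point iteration of the joint Huber
    location/scale equations (winsorized-mean form, chi consistency for
    the normal)."""
    x = np.asarray(values, float)
    n = len(x)
    kappa = (2 * norm.cdf(k) - 1) - 2 * k * norm.pdf(k) + 2 * k * k * norm.sf(k)
    M = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - M))) or float(np.std(x))
    for _ in range(iters):
        lo, hi = M - k * s, M + k * s
        w = np.clip(x, lo, hi)
        M_new = float(w.mean())
        s_new = math.sqrt(float(((w - M) ** 2).sum()) / ((n - 1) * kappa))
        if abs(M_new - M) < tol and abs(s_new - s) < tol:
            return M_new, s_new
        M, s = M_new, s_new
    return M, s


class TestHuberLocationScale:
    def test_symmetric_data_location(self):
        M, s = huber_location_scale([1.0, 2.0, 3.0])
        assert M == pytest.approx(2.0, abs=1e-9)

    def test_agrees_with_statsmodels_on_well_behaved_data(self, rng):
        for _ in range(10):
            x = rng.normal(5.0, 2.0, size=30)
            x[:3] += 15  # contaminate
            M, s = huber_location_scale(x, tol=1e-9, max_iter=500)
            sm_M, sm_s = SmHuber(c=1.5, tol=1e-9, maxiter=500)(x)
            assert M == pytest.approx(float(sm_M), abs=1e-5)
            assert s == pytest.approx(float(sm_s), abs=1e-5)

    def test_matches_brute_force_fixed_point(self, rng):
        for x in ([1.0, 2.0, 3.0, 4.0, 10.0], list(rng.normal(0, 1, 25))):
            M, s = huber_location_scale(x, tol=1e-9, max_iter=2000)
            oM, os_ = _oracle_proposal2(x)
            assert M == pytest.approx(oM, abs=1e-6)
            assert s == pytest.approx(os_, abs=1e-6)

    def test_majority_identical_values_collapse_to_floor(self):
        # 4/5 identical values: the Proposal-2 scale collapses onto the
        # majority; iteration stops once s is below the floor, so the
        # location is within one floor-unit of the majority value.
        M, s = huber_location_scale([0.0, 0.0, 0.0, 0.0, 10.0])
        assert M == pytest.approx(0.0, abs=DEFAULT_SCALE_FLOOR)
        assert s == DEFAULT_SCALE_FLOOR

    def test_constant_data_floor(self):
        M, s = huber_location_scale([3.3] * 10)
        assert (M, s) == (3.3, DEFAULT_SCALE_FLOOR)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            huber_location_scale([1.0])


class TestOutlierTest:
    def test_at_location_p_half(self):
        z, p = outlier_test(4.0, 4.0, 1.0)
        assert z == 0.0 and p == 0.5

    def test_three_sigma_upper_tail(self):
        z, p = outlier_test(10.0, 4.0, 2.0)
        assert z == 3.0
        assert p == pytest.approx(1.3498980316300946e-3, rel=1e-9)

    def test_one_sidedness(self):
        z, p = outlier_test(2.0, 4.0, 1.0)
        assert z < 0 and p > 0.5

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            outlier_test(1.0, 0.0, 0.0)

    def test_affine_equivariance(self, rng):
        """z is unchanged when controls and test value share y -> a*y + b."""
        x = list(rng.normal(3, 1, 20))
        y = 7.5
        M, s = huber_location_scale(x, tol=1e-10, max_iter=2000)
        z0, _ = outlier_test(y, M, s)
        for a, b in [(2.0, 1.0), (0.3, -4.0), (10.0, 100.0)]:
            Ma, sa = huber_location_scale([a * v + b for v in x], tol=1e-10, max_iter=2000)
            za, _ = outlier_test(a * y + b, Ma, sa)
            assert za == pytest.approx(z0, rel=1e-5)

    def test_z_strictly_increasing_in_raw_count(self):
        M, s = 2.0, 0.5
        zs = [outlier_test(normalize_count(r, 30.0), M, s)[0] for r in range(0, 40)]
        assert all(b > a for a, b in zip(zs, zs[1:]))


class TestAdjustBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03], abs=1e-12)

    def test_single_and_ties(self):
        assert adjust_bh([0.2]) == [0.2]
        assert adjust_bh([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_against_step_up_oracle(self, rng):
        p = rng.random(50)
        expected = np.empty_like(p)
        order = np.argsort(p)
        m = len(p)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        assert adjust_bh(p) == pytest.approx(expected.tolist(), abs=1e-12)

    def test_never_decreases_and_validates(self):
        p = [0.001, 0.5, 0.9]
        adj = adjust_bh(p)
        assert all(a >= b for a, b in zip(adj, p))
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


def _table(sid, counts, cov=30.0):
    return LocusCountTable(sid, dict(counts), {}, cov)


LID = "chr1:1000-1030:AGC"
LID2 = "chr1:5000-5040:AT"


class TestBuildControlParameters:
    def test_identical_samples_floor_scale(self):
        tables = [_table(f"s{i}", {LID: 5}) for i in range(3)]
        params = build_control_parameters(tables)
        M, s, n = params.params[LID]
        assert M == pytest.approx(normalize_count(5, 30.0))
        assert s == DEFAULT_SCALE_FLOOR
        assert n == 3

    def test_absent_locus_contributes_zero_count(self):
        tables = [_table("s0", {LID: 12})] + [_table(f"s{i}", {}) for i in range(1, 5)]
        params = build_control_parameters(tables)
        ys = [normalize_count(12, 30.0)] + [normalize_count(0, 30.0)] * 4
        expected = huber_location_scale(ys)
        assert params.params[LID][:2] == pytest.approx(expected)
        assert params.params[LID][2] == 5

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            build_control_parameters([_table("s0", {LID: 1})])

    def test_tsv_round_trip(self, tmp_path):
        tables = [_table(f"s{i}", {LID: i, LID2: 2 * i}) for i in range(5)]
        params = build_control_parameters(tables)
        p = tmp_path / "controls.tsv"
        params.to_tsv(p)
        assert ControlParameters.from_tsv(p) == params


class TestCallOutliers:
    def _controls(self, rng, n=20, lam=1.0, loci=(LID, LID2)):
        tables = [
            _table(f"c{i}", {l: int(rng.poisson(lam)) for l in loci})
            for i in range(n)
        ]
        return tables, build_control_parameters(tables)

    def test_spiked_locus_ranks_first_and_significant(self, rng):
        _, controls = self._controls(rng)
        sample = _table("case", {LID: 30, LID2: 1})
        calls = call_outliers(sample, controls)
        assert calls[0].locus_id == LID
        assert calls[0].significant and calls[0].p_adj < 0.05
        # direct formula recomputation
        M, s, _ = controls.params[LID]
        z, p = outlier_test(normalize_count(30, 30.0), M, s)
        assert calls[0].z == pytest.approx(z) and calls[0].p == pytest.approx(p)

    def test_sample_matching_controls_not_significant(self, rng):
        tables, controls = self._controls(rng)
        sample = _table("case", {LID: 1, LID2: 1})
        assert not any(c.significant for c in call_outliers(sample, controls))

    def test_locus_absent_from_controls_uses_fallback(self, rng):
        _, controls = self._controls(rng, loci=(LID,))
        sample = _table("case", {LID: 1, LID2: 25})
        calls = call_outliers(sample, controls)
        novel = [c for c in calls if c.locus_id == LID2][0]
        z, p = outlier_test(
            normalize_count(25, 30.0), normalize_count(0, 100.0), controls.median_sigma()
        )
        assert novel.z == pytest.approx(z) and novel.p == pytest.approx(p)

    def test_only_assigned_loci_tested_sorted_by_p(self, rng):
        _, controls = self._controls(rng)
        sample = _table("case", {LID: 9, LID2: 2})
        calls = call_outliers(sample, controls)
        assert [c.locus_id for c in calls] == sorted(
            (c.locus_id for c in calls),
            key=lambda lid: [c.p for c in calls if c.locus_id == lid][0],
        )
        assert len(calls) == 2

    def test_significant_subset_of_unadjusted(self, rng):
        _, controls = self._controls(rng)
        sample = _table("case", {LID: 30, LID2: 3})
        for c in call_outliers(sample, controls):
            assert c.p_adj >= c.p
            if c.significant:
                assert c.p < 0.05
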