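"""Bland–Altman, bias regression and Pearson correlation against oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from dietscreen import (
    DailyServesProfile,
    DietScore,
    FoodGroup,
    ReportingThresholds,
    bland_altman,
    paired_scores,
    pearson,
    stratified_correlations,
)


def ba_oracle(x, y, mult=2.0):
    """Direct-formula Bland–Altman: plain sums, no shared code paths."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    d = [a - b for a, b in zip(x, y)]
    m = [(a + b) / 2 for a, b in zip(x, y)]
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    mbar = sum(m) / n
    sxx = sum((v - mbar) ** 2 for v in m)
    slope = sum((a - mbar) * (b - mean) for a, b in zip(m, d)) / sxx if sxx else None
    intercept = mean - slope * mbar if slope is not None else None
    return mean, sd, mean - mult * sd, mean + mult * sd, slope, intercept


def _score(rid, total, provenance="ffq"):
    return DietScore(
        respondent_id=rid, provenance=provenance, component_points={}, total=total, max_total=30
    )


class TestPairedScores:
    def test_identical_id_sets_keep_all_pairs(self):
        a = [_score(f"r{i}", 10 + i) for i in range(5)]
        b = [_score(f"r{i}", 12, "sdq") for i in range(5)]
        assert len(paired_scores(a, b)) == 5

    def test_disjoint_id_sets_error(self):
        with pytest.raises(ValueError, match="overlap"):
            paired_scores([_score("a", 1)], [_score("b", 2)])

    def test_partial_overlap_keeps_intersection(self, caplog):
        import logging

        a = [_score(f"r{i}", 10) for i in range(5)]
        b = [_score(f"r{i}", 11, "sdq") for i in range(2, 7)]
        with caplog.at_level(logging.WARNING, logger="dietscreen"):
            pairs = paired_scores(a, b)
        assert len(pairs) == 3
        assert "excluded" in caplog.text


class TestBlandAltman:
    def test_hand_computed_example(self):
        """FFQ=[10,12,14] vs SDQ=[11,11,15]: diffs (−1, 1, −1)."""
        res = bland_altman([10, 12, 14], [11, 11, 15])
        assert res.mean_diff == pytest.approx(-1 / 3, abs=1e-9)
        assert res.sd_diff == pytest.approx(2 / math.sqrt(3), abs=1e-9)
        assert res.loa_lower == pytest.approx(-1 / 3 - 4 / math.sqrt(3), abs=1e-9)
        assert res.loa_upper == pytest.approx(-1 / 3 + 4 / math.sqrt(3), abs=1e-9)

    def test_identical_series(self):
        res = bland_altman([10, 12, 14], [10, 12, 14])
        assert res.mean_diff == 0 and res.loa_lower == 0 and res.loa_upper == 0
        assert res.slope == pytest.approx(0)

    def test_constant_shift(self):
        res = bland_altman([12, 14, 16], [10, 12, 14])
        assert res.mean_diff == pytest.approx(2)
        assert res.sd_diff == 0
        assert (res.loa_lower, res.loa_upper) == (pytest.approx(2), pytest.approx(2))
        assert res.slope == pytest.approx(0)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])

    def test_zero_variance_of_means_flagged_degenerate(self):
        res = bland_altman([10, 10, 10], [10, 10, 10])
        assert not res.slope_defined and math.isnan(res.slope)

    def test_swap_negates_mean_and_mirrors_loa(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(14, 4, 30), rng.normal(13, 4, 30)
        ab, ba = bland_altman(x, y), bland_altman(y, x)
        assert ba.mean_diff == pytest.approx(-ab.mean_diff)
        assert ba.sd_diff == pytest.approx(ab.sd_diff)
        assert ba.loa_lower == pytest.approx(-ab.loa_upper)
        assert ba.loa_upper == pytest.approx(-ab.loa_lower)

    def test_location_invariance_of_differences(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(14, 4, 40), rng.normal(13, 4, 40)
        a, b = bland_altman(x, y), bland_altman(x + 5, y + 5)
        assert b.mean_diff == pytest.approx(a.mean_diff)
        assert b.sd_diff == pytest.approx(a.sd_diff)
        assert b.slope == pytest.approx(a.slope)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            x = rng.normal(14, 4, n)
            y = rng.normal(13, 4, n)
            res = bland_altman(x, y)
            mean, sd, lo, hi, slope, intercept = ba_oracle(x, y)
            assert res.mean_diff == pytest.approx(mean, abs=1e-12)
            assert res.sd_diff == pytest.approx(sd, abs=1e-12)
            assert res.loa_lower == pytest.approx(lo, abs=1e-12)
            assert res.loa_upper == pytest.approx(hi, abs=1e-12)
            assert res.slope == pytest.approx(slope, abs=1e-12)
            assert res.intercept == pytest.approx(intercept, abs=1e-12)

    def test_slope_inference_matches_linregress(self):
        """Classical t CI and p on the bias slope, cross-checked with scipy."""
        rng = np.random.default_rng(12)
        x = rng.normal(14, 4, 50)
        y = x * 0.8 + rng.normal(0, 2, 50)
        res = bland_altman(x, y)
        lr = sps.linregress((x + y) / 2, x - y)
        assert res.slope == pytest.approx(lr.slope, abs=1e-12)
        assert res.slope_p == pytest.approx(lr.pvalue, abs=1e-10)
        half = sps.t.ppf(0.975, 48) * lr.stderr
        assert res.slope_ci_low == pytest.approx(lr.slope - half, abs=1e-10)
        assert res.slope_ci_high == pytest.approx(lr.slope + half, abs=1e-10)


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative_linearity(self):
        x = [1.0, 2.0, 3.0]
        r, _ = pearson(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        r, _ = pearson([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_input_undefined(self):
        r, p = pearson([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            x = rng.normal(0, 1, n)
            y = 0.4 * x + rng.normal(0, 1, n)
            r, p = pearson(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_positive_affine_transforms(self):
        rng = np.random.default_rng(22)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r0, _ = pearson(x, y)
        r1, _ = pearson(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r0, abs=1e-12)


def _profiles(vals, ages, provenance):
    return [
        DailyServesProfile(
            respondent_id=f"r{i}",
            serves={FoodGroup.FRUIT: v},
            provenance=provenance,
            age_years=a,
        )
        for i, (v, a) in enumerate(zip(vals, ages))
    ]


class TestStratifiedCorrelations:
    def test_age_boundary_79_is_under_80_is_plus(self):
        ages = [79, 80, 79, 80, 79, 80]
        rng = np.random.default_rng(5)
        f = _profiles(rng.uniform(0, 3, 6), ages, "ffq")
        s = _profiles(rng.uniform(0, 3, 6), ages, "sdq")
        rows = {(c.group, c.stratum): c for c in stratified_correlations(f, s)}
        assert rows[("fruit", "under_80")].n == 3
        assert rows[("fruit", "80_plus")].n == 3
        assert rows[("fruit", "all")].n == 6

    def test_empty_stratum_flagged_undefined(self):
        ages = [70, 71, 72, 73]
        rng = np.random.default_rng(6)
        f = _profiles(rng.uniform(0, 3, 4), ages, "ffq")
        s = _profiles(rng.uniform(0, 3, 4), ages, "sdq")
        rows = {(c.group, c.stratum): c for c in stratified_correlations(f, s)}
        old = rows[("fruit", "80_plus")]
        assert old.n == 0 and math.isnan(old.r)

    def test_identical_profiles_give_r_one(self):
        ages = [70, 75, 82, 85, 77, 88]
        vals = [1.0, 2.0, 3.0, 0.5, 2.5, 1.5]
        f = _profiles(vals, ages, "ffq")
        s = _profiles(vals, ages, "sdq")
        for c in stratified_correlations(f, s):
            assert c.r == pytest.approx(1.0)
            assert not c.negligible

    def test_negligible_flag_below_030(self):
        rng = np.random.default_rng(7)
        ages = [70] * 40 + [85] * 40
        x = rng.normal(2, 1, 80)
        y = rng.normal(2, 1, 80)  # independent: r near 0
        f = _profiles(x, ages, "ffq")
        s = _profiles(y, ages, "sdq")
        rows = {(c.group, c.stratum): c for c in stratified_correlations(f, s)}
        c = rows[("fruit", "all")]
        assert abs(c.r) < 0.3 and c.negligible

    def test_missing_values_use_pairwise_complete(self):
        ages = [70, 71, 72, 73, 85]
        vals = [1.0, 2.0, 3.0, float("nan"), 2.0]
        f = _profiles(vals, ages, "ffq")
        s = _profiles([1.1, 2.2, 2.9, 1.0, 2.0], ages, "sdq")
        rows = {(c.group, c.stratum): c for c in stratified_correlations(f, s)}
        assert rows[("fruit", "under_80")].n == 3


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "delta,sigma", [(-1.5, 4.2), (0.0, 2.0), (3.0, 1.0)]
    )
    def test_mean_and_sd_recovered_at_n5000(self, delta, sigma):
        from dietscreen import paired_totals_with_difference

        n = 5000
        ffq, sdq = paired_totals_with_difference(n, delta, sigma, seed=1)
        res = bland_altman(ffq, sdq)
        assert abs(res.mean_diff - delta) <= 4 * sigma / math.sqrt(n)
        assert abs(res.sd_diff - sigma) / sigma <= 0.10
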