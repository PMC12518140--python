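"""Tumour volumetrics and toxicity statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribpet.cohort import (
    CaliperMeasurement,
    SE_MEDIAN_FACTOR,
    SpineActivityRecord,
    ellipsoid_volume,
    grip_metrics,
    growth_summary,
    mann_whitney,
    mood_median_test,
    pearson_corr,
    se_median,
    spine_fraction,
)


class TestEllipsoidVolume:
    def test_unit_case(self):
        assert ellipsoid_volume(CaliperMeasurement(1.0, 1.0)) == pytest.approx(
            4.0 * math.pi / 3.0
        )

    def test_asymmetric_case(self):
        # a=2, b=1 -> c=1.5, V = (4/3) pi * 2 * 1 * 1.5 = 4 pi
        assert ellipsoid_volume(CaliperMeasurement(2.0, 1.0)) == pytest.approx(
            4.0 * math.pi
        )

    def test_degenerate_axis(self):
        assert ellipsoid_volume(CaliperMeasurement(0.0, 3.0)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CaliperMeasurement(-1.0, 2.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 30.0), st.floats(0.1, 30.0), st.floats(0.5, 3.0)
    )
    def test_symmetry_and_cubic_scaling(self, a, b, s):
        v = ellipsoid_volume(CaliperMeasurement(a, b))
        assert ellipsoid_volume(CaliperMeasurement(b, a)) == pytest.approx(v)
        assert ellipsoid_volume(
            CaliperMeasurement(s * a, s * b)
        ) == pytest.approx(s**3 * v, rel=1e-9)


class TestGrowthSummary:
    def test_single_animal_flagged_with_nan_sem(self):
        df = pd.DataFrame(
            {"animal_id": ["m1"], "group": [0], "day": [0.0], "volume_mm3": [50.0]}
        )
        out = growth_summary(df)
        assert out.loc[0, "mean"] == 50.0
        assert out.loc[0, "n"] == 1
        assert np.isnan(out.loc[0, "sem"])

    def test_two_equal_animals_have_zero_sem(self):
        df = pd.DataFrame(
            {
                "animal_id": ["m1", "m2"],
                "group": [0, 0],
                "day": [0.0, 0.0],
                "volume_mm3": [50.0, 50.0],
            }
        )
        out = growth_summary(df)
        assert out.loc[0, "sem"] == 0.0

    def test_caliper_columns_converted(self):
        df = pd.DataFrame(
            {
                "animal_id": ["m1"],
                "group": [0],
                "day": [0.0],
                "a_mm": [2.0],
                "b_mm": [1.0],
            }
        )
        out = growth_summary(df)
        assert out.loc[0, "mean"] == pytest.approx(4.0 * math.pi)

    def test_known_group_means_recovered(self):
        rng = np.random.default_rng(5)
        rows = []
        for g, mu in ((0, 200.0), (20, 20.0)):
            for i in range(30):
                rows.append(
                    {
                        "animal_id": f"{g}-{i}",
                        "group": g,
                        "day": 7.0,
                        "volume_mm3": mu * rng.lognormal(0, 0.1),
                    }
                )
        out = growth_summary(pd.DataFrame(rows)).set_index("group")
        for g, mu in ((0, 200.0), (20, 20.0)):
            assert out.loc[g, "mean"] == pytest.approx(mu, rel=0.15)
            assert out.loc[g, "sem"] > 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            growth_summary(pd.DataFrame({"animal_id": [], "day": []}))


class TestSeMedian:
    def test_factor_is_sqrt_pi_over_two(self):
        assert SE_MEDIAN_FACTOR == pytest.approx(1.2533, abs=5e-5)

    def test_scales_as_sd_over_sqrt_n(self):
        v = np.array([0.0, 2.0])  # sd = sqrt(2), n = 2
        assert se_median(v) == pytest.approx(
            SE_MEDIAN_FACTOR * np.sqrt(2.0) / np.sqrt(2.0)
        )

    def test_constant_sample_zero(self):
        assert se_median([3.0, 3.0, 3.0]) == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            se_median([1.0])

    def test_bootstrap_oracle_on_normal_sample(self):
        # the SD of bootstrap medians of a large normal sample approaches
        # 1.2533 * sigma / sqrt(n)
        rng = np.random.default_rng(12)
        sample = rng.normal(0.0, 1.0, 2000)
        boots = np.array(
            [
                np.median(rng.choice(sample, sample.size, replace=True))
                for _ in range(2000)
            ]
        )
        assert se_median(sample) == pytest.approx(boots.std(ddof=1), rel=0.12)


class TestGripMetrics:
    @staticmethod
    def table(values_by_week, animal="m1", group="irradiated(20)"):
        return pd.DataFrame(
            [
                {
                    "animal_id": animal,
                    "group": group,
                    "week": w,
                    "peak_force": f,
                }
                for w, f in values_by_week
            ]
        )

    def test_all_strong_timepoints(self):
        out = grip_metrics(self.table([(6, 120.0), (8, 120.0)]))
        assert out.loc[0, "frac_below"] == 0.0
        assert out.loc[0, "median_strength"] == 120.0

    def test_half_below_threshold(self):
        out = grip_metrics(self.table([(6, 90.0), (8, 110.0)]))
        assert out.loc[0, "frac_below"] == 0.5

    def test_early_weeks_excluded(self):
        out = grip_metrics(self.table([(1, 10.0), (3, 10.0), (6, 120.0)]))
        assert out.loc[0, "median_strength"] == 120.0
        assert out.loc[0, "n_timepoints"] == 1

    def test_no_late_records_rejected(self):
        with pytest.raises(ValueError, match="week"):
            grip_metrics(self.table([(1, 100.0), (3, 100.0)]))


class TestNonparametricTests:
    def test_mood_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        stat, p = mood_median_test(a, a)
        assert p > 0.9

    def test_mood_matches_hand_counts_on_separated_groups(self):
        # groups fully separated around the pooled median: the 2x2 table is
        # [[n,0],[0,m]] (above/below) and the chi-square is maximal
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 11.0, 12.0, 13.0]
        stat, p = mood_median_test(a, b)
        assert p < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mann_whitney_matches_exact_enumeration(self, seed):
        """Permutation oracle: enumerate all group labellings for n <= 6."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 7), rng.integers(3, 7)
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct, no ties
        a, b = pooled[:n], pooled[n:]
        u_obs, p_obs = mann_whitney(a, b)

        def u_stat(x, y):
            return sum(
                1.0 if xi > yi else (0.5 if xi == yi else 0.0)
                for xi in x
                for yi in y
            )

        values = sorted(pooled)
        null_u = [
            u_stat(comb, [v for v in values if v not in comb])
            for comb in itertools.combinations(values, n)
        ]
        null_u = np.array(null_u)
        center = n * m / 2.0
        p_exact = np.mean(
            np.abs(null_u - center) >= abs(u_stat(a, b) - center) - 1e-12
        )
        assert u_obs == pytest.approx(u_stat(a, b))
        assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_perfect_line_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_corr(x, 2.0 * x + 1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert math.isnan(res.r)

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = pearson_corr(x, y)
        assert res.ci_low < res.r < res.ci_high


class TestSpineFraction:
    @pytest.mark.parametrize(
        "spine,total,expected", [(0.0, 100.0, 0.0), (100.0, 100.0, 1.0), (3.0, 12.0, 0.25)]
    )
    def test_fraction(self, spine, total, expected):
        assert spine_fraction(
            SpineActivityRecord("m1", spine, total)
        ) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            spine_fraction(SpineActivityRecord("m1", 0.0, 0.0))

    def test_counts_ordering_enforced(self):
        with pytest.raises(ValueError):
            SpineActivityRecord("m1", 10.0, 5.0)
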