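"""Washout model fitting, model selection and group statistics."""

import numpy as np
import pytest

from ribpet.decay import TimeActivitySeries, fraction_remaining
from ribpet.synth import CohortSpec, gen_washout_series
from ribpet.washout import (
    BioWashoutParams,
    FitResult,
    compare_groups,
    detect_outliers,
    f_test,
    fit_washout,
    fit_washout_pooled,
    washout_activity,
)

# Independent Decimal evaluation (40 digits) of
# A0=1000, Ws=0.6, ks=1e-3, kf=1e-2, pure ^11C, t=600 s.
WASHOUT_ORACLE_600S = 234.89905302847397


def make_series(params, mix, times, rng=None):
    mean = washout_activity(params, mix, times)
    values = rng.poisson(mean).astype(float) if rng is not None else np.asarray(mean)
    return TimeActivitySeries(times, values, 60.0)


class TestModel:
    def test_activity_at_time_zero_is_a0(self, mix):
        p = BioWashoutParams(a0=123.0, ws=0.4, ks=1e-3, kf=1e-2)
        assert washout_activity(p, mix, 0.0) == pytest.approx(123.0)

    def test_single_component_reduction(self, pure_c11):
        p1 = BioWashoutParams(a0=50.0, ws=1.0, ks=2e-3, kf=2e-3, n_components=1)
        t = np.linspace(0, 1800, 7)
        expected = 50.0 * fraction_remaining(pure_c11, t) * np.exp(-2e-3 * t)
        assert washout_activity(p1, pure_c11, t) == pytest.approx(expected)

    def test_oracle_value(self, pure_c11):
        p = BioWashoutParams(a0=1000.0, ws=0.6, ks=1e-3, kf=1e-2)
        assert washout_activity(p, pure_c11, 600.0) == pytest.approx(
            WASHOUT_ORACLE_600S, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a0": -1.0, "ws": 0.5, "ks": 1e-3, "kf": 1e-2},
            {"a0": 1.0, "ws": 1.5, "ks": 1e-3, "kf": 1e-2},
            {"a0": 1.0, "ws": 0.5, "ks": 1e-2, "kf": 1e-3},  # ks > kf
            {"a0": 1.0, "ws": 0.5, "ks": 1e-3, "kf": 1e-2, "n_components": 1},
        ],
    )
    def test_parameter_invariants(self, kwargs):
        with pytest.raises(ValueError):
            BioWashoutParams(**kwargs)


class TestFit:
    def test_noiseless_two_component_roundtrip(self, mix, washout_times):
        truth = BioWashoutParams(a0=2e4, ws=0.6, ks=1e-3, kf=1e-2)
        fit = fit_washout(make_series(truth, mix, washout_times), mix, 2)
        assert fit.converged
        assert fit.params.ks == pytest.approx(truth.ks, rel=1e-4)
        assert fit.params.kf == pytest.approx(truth.kf, rel=1e-4)
        assert fit.params.ws == pytest.approx(truth.ws, abs=1e-4)
        assert fit.params.a0 == pytest.approx(truth.a0, rel=1e-4)

    def test_noiseless_single_component_roundtrip(self, mix, washout_times):
        truth = BioWashoutParams(a0=2e4, ws=1.0, ks=2e-3, kf=2e-3, n_components=1)
        fit = fit_washout(make_series(truth, mix, washout_times), mix, 1)
        assert fit.params.ks == pytest.approx(2e-3, rel=1e-6)

    def test_pure_physical_decay_gives_zero_rate(self, mix, washout_times):
        series = TimeActivitySeries(
            washout_times, 2e4 * fraction_remaining(mix, washout_times), 60.0
        )
        fit = fit_washout(series, mix, 1)
        assert fit.params.ks <= 1e-6

    def test_two_component_never_fits_worse(self, mix, washout_times):
        truth = BioWashoutParams(a0=2e4, ws=0.7, ks=8e-4, kf=1.5e-2)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            series = make_series(truth, mix, washout_times, rng)
            f1 = fit_washout(series, mix, 1)
            f2 = fit_washout(series, mix, 2)
            assert f2.chi2 <= f1.chi2 + 1e-9

    def test_labels_sorted_slow_fast(self, mix, washout_times):
        truth = BioWashoutParams(a0=2e4, ws=0.3, ks=5e-4, kf=3e-2)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fit = fit_washout(make_series(truth, mix, washout_times, rng), mix, 2)
            assert fit.params.ks <= fit.params.kf

    def test_parameter_recovery_under_poisson_noise(self, mix):
        """Median recovery error across seeded synthetic animals stays small."""
        spec = CohortSpec(seed=11, n_per_group={5: 30}, )
        animals = gen_washout_series(spec, 5)
        errs = []
        for a in animals:
            fit = fit_washout(a.series, mix, 2)
            errs.append(
                (
                    abs(fit.params.ks / a.truth.ks - 1),
                    abs(fit.params.kf / a.truth.kf - 1),
                    abs(fit.params.ws - a.truth.ws),
                )
            )
        med = np.median(np.array(errs), axis=0)
        assert med[0] < 0.10  # ks relative
        assert med[1] < 0.10  # kf relative
        assert med[2] < 0.10  # Ws absolute

    def test_too_few_points_rejected(self, mix):
        t = np.arange(30.0, 400.0, 60.0)  # 7 points
        series = TimeActivitySeries(t, np.full(t.size, 100.0), 60.0)
        with pytest.raises(ValueError, match="points"):
            fit_washout(series, mix, 1)
        with pytest.raises(ValueError, match="points"):
            fit_washout(series, mix, 2)

    def test_fit_window_excludes_late_samples(self, mix):
        t = np.arange(30.0, 3600.0, 60.0)
        truth = BioWashoutParams(a0=2e4, ws=1.0, ks=1e-3, kf=1e-3, n_components=1)
        series = make_series(truth, mix, t)
        fit = fit_washout(series, mix, 1, t_max=1800.0)
        assert fit.dof == int((t <= 1800.0).sum()) - 2

    def test_pooled_fit_concatenates_animals(self, mix, washout_times):
        truth = BioWashoutParams(a0=2e4, ws=0.5, ks=8e-4, kf=1.2e-2)
        series = [make_series(truth, mix, washout_times) for _ in range(3)]
        fit = fit_washout_pooled(series, mix, 2)
        assert fit.dof == 3 * washout_times.size - 4
        assert fit.params.ks == pytest.approx(truth.ks, rel=1e-3)


class TestFTest:
    @staticmethod
    def dummy_fit(chi2, dof, n_free):
        p = BioWashoutParams(a0=1.0, ws=1.0, ks=1e-3, kf=1e-3, n_components=1)
        return FitResult(p, chi2, dof, n_free, {}, True)

    def test_no_improvement_selects_single(self):
        sel = f_test(self.dummy_fit(100.0, 102, 2), self.dummy_fit(100.0, 100, 4))
        assert sel.f_stat == 0.0
        assert sel.chosen == "single"
        assert sel.chi2_ratio == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # F = ((200-100)/2)/(100/100) = 50; p has the closed form
        # (1 + 2F/d2)^(-d2/2) for 2 numerator dof
        sel = f_test(self.dummy_fit(200.0, 102, 2), self.dummy_fit(100.0, 100, 4))
        assert sel.f_stat == pytest.approx(50.0)
        assert sel.p_value == pytest.approx((1 + 2 * 50.0 / 100) ** (-50), rel=1e-10)
        assert sel.chosen == "double"
        assert sel.chi2_ratio == pytest.approx(2.0)

    def test_non_nested_fits_rejected(self):
        with pytest.raises(ValueError):
            f_test(self.dummy_fit(200.0, 50, 2), self.dummy_fit(100.0, 100, 4))

    def test_near_degenerate_truth_leaves_double_unsupported(self, mix, washout_times):
        # with Ws -> 1 the extra component explains nothing beyond noise:
        # both conventions agree it is unsupported (F small, ratio ~ 1)
        truth = BioWashoutParams(a0=2e4, ws=1.0, ks=1e-3, kf=1e-3, n_components=1)
        rng = np.random.default_rng(0)
        series = make_series(truth, mix, washout_times, rng)
        sel = f_test(
            fit_washout(series, mix, 1), fit_washout(series, mix, 2)
        )
        assert sel.chosen == "single"
        assert sel.chi2_ratio == pytest.approx(1.0, abs=0.15)


class TestOutliers:
    def test_tight_symmetric_sample_kept(self):
        assert detect_outliers([1, 2, 3, 4, 5]).all()

    def test_gross_outlier_excluded(self):
        # median 3, IQR 2, bounds [0, 6]
        mask = detect_outliers([1, 2, 3, 4, 100])
        assert mask.tolist() == [True, True, True, True, False]

    def test_degenerate_iqr_excludes_nothing(self):
        with pytest.warns(UserWarning, match="IQR"):
            assert detect_outliers([2.0, 2.0, 2.0, 2.0]).all()

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            detect_outliers([1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_identical_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # means 2 and 5, pooled variance 1, se = sqrt(2/3)
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.p_value == pytest.approx(0.0213116411287567, rel=1e-9)

    def test_zero_variance_unequal_means_flagged(self):
        res = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert res.zero_variance
        assert res.p_value == 0.0

    def test_dose_group_power(self, mix):
        """Distinct fast-component truths separate 5 vs 20 Gy-like cohorts."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = CohortSpec(seed=1000 + seed, n_per_group={5: 8, 20: 8})
            ws5 = [
                fit_washout(a.series, mix, 2).params.ws
                for a in gen_washout_series(spec, 5)
            ]
            ws20 = [
                fit_washout(a.series, mix, 2).params.ws
                for a in gen_washout_series(spec, 20)
            ]
            if compare_groups(ws5, ws20).p_value < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep
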