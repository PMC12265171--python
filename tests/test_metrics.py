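"""Evaluation statistics: mixture peaks, outlier bands, dependence
measures, effect sizes and the paired bootstrap."""

import numpy as np
import pytest

from deepsuvr.metrics import (
    GMM2Fit,
    auc,
    cohens_d,
    derive_outlier_band,
    emergent_classification,
    fit_gmm2,
    hsic,
    hsic_permutation_test,
    outlier_fraction,
    paired_bootstrap,
    peak_stability,
    r_squared,
    spearman,
)


class TestGmm2:
    def test_recovers_generating_mixture(self):
        rng = np.random.default_rng(0)
        n = 2000
        comp = rng.random(n) < 0.7
        values = np.where(comp, rng.normal(0, 6, n), rng.normal(80, 20, n))
        fit = fit_gmm2(values, seed=0)
        assert -1.0 <= fit.first_peak_mean <= 1.0
        assert 5.4 <= fit.first_peak_sd <= 6.6

    def test_recovery_across_seeds(self):
        """Parameter recovery holds for at least 18 of 20 generator seeds."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            comp = rng.random(n) < 0.7
            values = np.where(comp, rng.normal(0, 6, n), rng.normal(80, 20, n))
            fit = fit_gmm2(values, seed=0)
            if -1.0 <= fit.first_peak_mean <= 1.0 and 5.4 <= fit.first_peak_sd <= 6.6:
                ok += 1
        assert ok >= 18

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gmm2(np.full(50, 3.0))

    def test_separated_clusters(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 100), rng.normal(100, 1, 100)])
        fit = fit_gmm2(values, seed=0)
        assert fit.first_peak_mean == pytest.approx(0.0, abs=0.5)
        assert max(fit.means) == pytest.approx(100.0, abs=0.5)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="20"):
            fit_gmm2(np.arange(19.0))


class TestOutlierBand:
    def test_uniform_reference_gives_inner_percentiles(self):
        rng = np.random.default_rng(0)
        band = derive_outlier_band(rng.uniform(-10, 10, 100_000))
        assert band.lower == pytest.approx(-9.0, abs=0.1)
        assert band.upper == pytest.approx(9.0, abs=0.1)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            derive_outlier_band(np.full(100, 2.0))

    def test_self_application_flags_ten_percent(self):
        rng = np.random.default_rng(2)
        rates = rng.normal(2, 4, 50_000)
        band = derive_outlier_band(rates)
        neg, pos = outlier_fraction(rates, band)
        assert neg + pos == pytest.approx(10.0, abs=0.5)

    def test_fraction_counting(self):
        from deepsuvr.metrics import OutlierBand

        band = OutlierBand(-5.8, 11.2)
        rates = np.array([-7.0, 12.0] + [0.0] * 8)
        assert outlier_fraction(rates, band) == (10.0, 10.0)
        assert outlier_fraction(np.array([]), band) == (0.0, 0.0)

    def test_fraction_additivity(self, rng):
        from deepsuvr.metrics import OutlierBand

        band = OutlierBand(-2.0, 2.0)
        a = rng.normal(0, 2, 400)
        b = rng.normal(1, 3, 100)
        na, pa = outlier_fraction(a, band)
        nb, pb = outlier_fraction(b, band)
        nc, pc = outlier_fraction(np.concatenate([a, b]), band)
        assert nc == pytest.approx((400 * na + 100 * nb) / 500)
        assert pc == pytest.approx((400 * pa + 100 * pb) / 500)


class TestHsic:
    def test_constant_input_gives_zero(self, rng):
        x = np.full(50, 3.0)
        y = rng.normal(size=50)
        assert hsic(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert hsic(x, y) == pytest.approx(hsic(y, x), rel=1e-9)

    def test_detects_nonmonotone_dependence(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 3, 200)
        y = np.sin(x)
        stat, p, null = hsic_permutation_test(x, y, n_permutations=1000, seed=0)
        assert stat > np.percentile(null, 99)
        assert p < 0.01

    def test_independent_samples_look_null(self):
        """HSIC of independent normals stays below the 95th permutation
        percentile in at least 90% of replicate draws."""
        rng = np.random.default_rng(0)
        below = 0
        n_rep = 40
        for _ in range(n_rep):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            stat, _, null = hsic_permutation_test(x, y, n_permutations=100, seed=1)
            if stat <= np.percentile(null, 95):
                below += 1
        assert below >= 0.9 * n_rep

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hsic(np.zeros(10), np.zeros(11))


class TestEffectSizesAndAuc:
    def test_identical_groups_give_zero_d(self, rng):
        a = rng.normal(size=100)
        assert cohens_d(a, a.copy()) == 0.0

    def test_unit_shift_gives_unit_d_at_large_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_d_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 60)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_perfect_separation_auc(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert auc(scores, labels) == 1.0

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        assert auc(np.exp(scores), labels) == pytest.approx(auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.arange(5.0), np.ones(5))

    def test_spearman_and_r2_on_monotone_data(self):
        x = np.arange(50.0)
        y = x**3
        assert spearman(x, y) == pytest.approx(1.0)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(10), np.arange(10.0))


class TestPairedBootstrap:
    def test_identical_methods_not_significant(self, rng):
        a = rng.normal(size=60)
        res = paired_bootstrap(np.mean, a, a.copy(), n_boot=500, seed=0)
        assert res.mean_diff == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_uniform_improvement_is_significant(self, rng):
        b = rng.normal(size=60)
        a = b + 5.0
        res = paired_bootstrap(np.mean, a, b, n_boot=2000, seed=0)
        assert res.p_value < 0.001
        assert res.ci95[0] > 0

    def test_seeded_determinism(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        r1 = paired_bootstrap(np.mean, a, b, n_boot=300, seed=11)
        r2 = paired_bootstrap(np.mean, a, b, n_boot=300, seed=11)
        assert (r1.mean_diff, r1.ci95, r1.p_value) == (r2.mean_diff, r2.ci95, r2.p_value)


class TestPeakStability:
    @staticmethod
    def _fit(mean, sd=5.0):
        return GMM2Fit(means=(mean, 80.0), sds=(sd, 15.0), weights=(0.7, 0.3))

    def test_identical_methods_zero_difference(self):
        fits = [self._fit(m) for m in (0.0, 2.0, -3.0, 1.0)]
        res = peak_stability(fits, [self._fit(m) for m in (0.0, 2.0, -3.0, 1.0)], n_boot=300, seed=0)
        assert res.mean_diff == pytest.approx(0.0)

    def test_shrunken_means_more_stable(self):
        means = np.array([-6.0, -2.0, 1.0, 4.0, 8.0])
        fits_ref = [self._fit(m) for m in means]
        shrunk = means.mean() + 0.5 * (means - means.mean())
        fits_new = [self._fit(m) for m in shrunk]
        res = peak_stability(fits_new, fits_ref, n_boot=2000, seed=0)
        assert res.mean_diff < 0  # new method has smaller cross-study SD
        assert res.ci95[1] < 0

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            peak_stability([self._fit(0.0)], [self._fit(0.0)])


class TestEmergentClassification:
    def test_crossing_threshold_is_emergent(self):
        out = emergent_classification([0, 2, 5], [10, 12, 31])
        assert out["label"] == "emergent"
        assert out["baseline_bracket"] == (10.0, 15.0)

    def test_staying_low_is_stable_negative(self):
        out = emergent_classification([0, 3, 6], [10, 15, 25])
        assert out["label"] == "stable_negative"

    def test_positive_baseline_ineligible(self):
        assert emergent_classification([0, 5], [35, 50])["label"] == "ineligible"

    def test_short_followup_ineligible(self):
        assert emergent_classification([0, 2], [10, 40])["label"] == "ineligible"
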