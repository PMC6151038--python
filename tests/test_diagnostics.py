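"""RMT diagnostics: residuals, fit statistics, targeting, dependence, PSI."""

import math

import numpy as np
import pytest

import riskscale as rs
from riskscale.diagnostics import _class_intervals

from conftest import make_thresholds


def _persons(thetas, se=0.3):
    return [rs.PersonEstimate(i, float(t), se, "WLE", 0, 10, False)
            for i, t in enumerate(thetas)]


class TestStandardizedResiduals:
    def test_observed_equals_expected_gives_zero(self):
        cals = [rs.ItemCalibration(f"i{k}", np.array([-1.0, 0.0, 1.0])) for k in range(2)]
        # at theta=0 the expected score is exactly 1.5; no integer x gives z=0,
        # so check the definition directly via a degenerate dichotomous case
        data = np.array([[1, 2], [2, 1]])
        persons = _persons([0.0, 0.0])
        rt = rs.standardized_residuals(data, cals, persons, G=2)
        e = rs.pcm_expected_score(0.0, [-1, 0, 1])
        v = rs.pcm_category_probs(0.0, [-1, 0, 1]) @ (np.arange(4) - e) ** 2
        np.testing.assert_allclose(rt.z[0, 0], (1 - e) / math.sqrt(v), atol=1e-10)

    def test_bernoulli_hand_value(self):
        """Dichotomous item with P(1)=0.75: z = 0.25/sqrt(0.1875) = 0.577."""
        tau = np.array([-math.log(3)])  # P(1|theta=0) = 0.75
        cals = [rs.ItemCalibration("a", tau), rs.ItemCalibration("b", tau)]
        rt = rs.standardized_residuals(np.array([[1, 0], [0, 1]]), cals,
                                       _persons([0.0, 0.0]), G=2)
        assert rt.z[0, 0] == pytest.approx(0.25 / math.sqrt(0.1875), abs=1e-9)
        assert rt.z[0, 0] == pytest.approx(0.5773, abs=1e-4)

    def test_mean_residual_near_zero_on_simulated_fit(self, health_calibration):
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"], hc["cals"], hc["persons"])
        n = hc["data"].shape[0]
        means = np.nanmean(rt.z, axis=0)
        assert np.all(np.abs(means) < 3 / math.sqrt(n))

    def test_class_intervals_near_equal_and_ranked(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=101)
        ci = _class_intervals(theta, 10)
        sizes = np.bincount(ci)
        assert sizes.max() - sizes.min() <= 1
        # ranked: every member of interval g sits below every member of g+1
        for g in range(9):
            assert theta[ci == g].max() <= theta[ci == g + 1].min()

    def test_more_intervals_than_persons_rejected(self):
        with pytest.raises(ValueError):
            _class_intervals(np.zeros(5), 6)


class TestItemFit:
    def test_well_fitting_items_mostly_within_bounds(self, health_calibration):
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"], hc["cals"], hc["persons"])
        frs = np.array([rs.item_fit_residual(rt, i) for i in range(18)])
        assert np.isfinite(frs).all()
        assert np.mean(np.abs(frs) <= 2.5) >= 0.9
        assert abs(frs.mean()) < 1.0  # centred under the model

    def test_under_and_over_discrimination_signs(self):
        """Flat items (a<1) inflate residual variance -> positive fit residual;
        steep items (a>1) deflate it -> negative."""
        rng = np.random.default_rng(77)
        taus = make_thresholds(np.linspace(-1, 1, 10))
        for a, sign in ((0.4, 1), (2.0, -1)):
            disc = np.ones(10)
            disc[3] = a
            data = rs.sample_pcm_matrix(rng.normal(0, 2.5, 1000), taus, rng,
                                        discrimination=disc)
            cals, _ = rs.calibrate_items(data, compute_se=False)
            persons = rs.estimate_persons(data, cals)
            rt = rs.standardized_residuals(data, cals, persons)
            fr = rs.item_fit_residual(rt, 3)
            assert sign * fr > 2.5, f"a={a}: fit residual {fr}"

    def test_insufficient_observations_not_evaluable(self, health_calibration):
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"][:20], hc["cals"],
                                       hc["persons"][:20], G=2)
        assert math.isnan(rs.item_fit_residual(rt, 0, min_obs=30))


class TestTraitChiSquare:
    def test_sample_size_adjustment_scales_statistic(self, health_calibration):
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"], hc["cals"], hc["persons"])
        n = hc["data"].shape[0]
        chi2, df, p, chi2_adj = rs.item_trait_chi_square(rt, 0, n_adjust=500)
        assert chi2_adj == pytest.approx(chi2 * 500 / n, rel=1e-12)
        chi2b, _, _, adj_b = rs.item_trait_chi_square(rt, 0, n_adjust=None)
        assert adj_b == chi2b == pytest.approx(chi2, rel=1e-12)

    def test_no_adjustment_at_or_below_target_n(self):
        rng = np.random.default_rng(12)
        taus = make_thresholds([0.0, 0.3, -0.3, 0.2, -0.2])
        data = rs.sample_pcm_matrix(rng.normal(0, 2.5, 500), taus, rng)
        cals, _ = rs.calibrate_items(data, compute_se=False)
        persons = rs.estimate_persons(data, cals)
        rt = rs.standardized_residuals(data, cals, persons)
        chi2, df, p, chi2_adj = rs.item_trait_chi_square(rt, 0, n_adjust=500)
        assert chi2_adj == chi2

    def test_default_ten_class_intervals_give_df_nine(self, health_calibration):
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"], hc["cals"], hc["persons"])
        _, df, _, _ = rs.item_trait_chi_square(rt, 0)
        assert df == 9


class TestThresholdOrderAndTargeting:
    def test_ordered_and_disordered_flags(self):
        cals = [rs.ItemCalibration("ok", np.array([-1.0, 0.0, 1.0])),
                rs.ItemCalibration("bad", np.array([0.0, -0.5, 1.0]))]
        out = rs.threshold_order_check(cals).set_index("item_id")["ordered"]
        assert bool(out["ok"]) and not bool(out["bad"])

    def test_coverage_direct_count(self):
        cals = [rs.ItemCalibration("i", np.array([-0.5, 2.0]))]
        cov = rs.targeting_coverage(_persons([-1.0, 0.0, 1.0]), cals)
        assert cov == pytest.approx(100 * 2 / 3)

    def test_coverage_all_inside_and_translation_invariance(self):
        cals = [rs.ItemCalibration("i", np.array([-3.0, 3.0]))]
        ps = _persons([-1.0, 0.0, 1.0])
        assert rs.targeting_coverage(ps, cals) == 100.0
        shifted = [rs.ItemCalibration("i", np.array([-3.0, 3.0]) + 5)]
        ps5 = _persons([4.0, 5.0, 6.0])
        assert rs.targeting_coverage(ps5, shifted) == 100.0


class TestResidualCorrelations:
    def test_duplicated_item_flagged_by_both_rules(self):
        rng = np.random.default_rng(21)
        taus = make_thresholds([0.0, 0.5, -0.5])
        data = rs.sample_pcm_matrix(rng.normal(0, 2.5, 600), taus, rng)
        data = np.column_stack([data, data[:, 0]])  # exact duplicate
        cals, _ = rs.calibrate_items(data, compute_se=False)
        persons = rs.estimate_persons(data, cals)
        rt = rs.standardized_residuals(data, cals, persons)
        out = rs.residual_correlation_flags(rt)
        pair = out["pairs"].set_index(["item_a", "item_b"]).loc[("item1", "item4")]
        assert pair["r"] > 0.5
        assert bool(pair["flag_abs"]) and bool(pair["flag_rel"])

    def test_mean_residual_correlation_negative_under_independence(self, health_calibration):
        """On locally independent data the average pairwise residual
        correlation is about -1/(L-1), so the mean+0.3 critical value
        sits below 0.3."""
        hc = health_calibration
        rt = rs.standardized_residuals(hc["data"], hc["cals"], hc["persons"])
        out = rs.residual_correlation_flags(rt)
        assert out["mean_r"] < 0
        assert out["mean_r"] == pytest.approx(-1 / 17, abs=0.04)
        assert out["critical_rel"] < 0.3
        assert not out["pairs"]["flag_rel"].any()

    def test_needs_three_items(self):
        cals = [rs.ItemCalibration(f"i{k}", np.array([0.0])) for k in range(2)]
        rt = rs.standardized_residuals(np.array([[1, 0], [0, 1]]), cals,
                                       _persons([0.0, 0.0]), G=2)
        with pytest.raises(ValueError):
            rs.residual_correlation_flags(rt)


class TestPersonSeparationIndex:
    def test_no_error_gives_one(self):
        assert rs.person_separation_index(_persons([-2, 0, 2], se=1e-9)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # var(theta)=4 (ddof=1), mean se^2 = 0.12 -> PSI = 3.88/4 = 0.97
        ps = _persons([-2.0, 0.0, 2.0], se=math.sqrt(0.12))
        assert rs.person_separation_index(ps) == pytest.approx(0.97)

    def test_all_error_floors_at_zero(self):
        assert rs.person_separation_index(_persons([-0.1, 0.0, 0.1], se=3.0)) == 0.0
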