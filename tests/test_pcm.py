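"""Partial credit model core: probabilities, calibration, person measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import riskscale as rs
from riskscale.pcm import pcm_moments

from conftest import make_thresholds


class TestCategoryProbs:
    def test_hand_computed_symmetric_case(self):
        # theta=0, tau=(-1,0,1): weights (1, e, e, 1)
        p = rs.pcm_category_probs(0.0, [-1.0, 0.0, 1.0])
        e = math.e
        denom = 2 + 2 * e
        np.testing.assert_allclose(p, [1 / denom, e / denom, e / denom, 1 / denom],
                                   atol=1e-12)
        np.testing.assert_allclose(p, [0.1345, 0.3655, 0.3655, 0.1345], atol=5e-5)

    def test_all_thresholds_at_theta_gives_uniform(self):
        p = rs.pcm_category_probs(0.7, [0.7, 0.7, 0.7, 0.7])
        np.testing.assert_allclose(p, np.full(5, 0.2), atol=1e-12)

    def test_dichotomous_midpoint(self):
        np.testing.assert_allclose(rs.pcm_category_probs(0.0, [0.0]), [0.5, 0.5])

    @given(theta=st.floats(-6, 6), tau=st.lists(st.floats(-4, 4), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_probabilities_sum_to_one(self, theta, tau):
        p = rs.pcm_category_probs(theta, tau)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    @given(theta=st.floats(-5, 5), c=st.floats(-3, 3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_translation_invariance(self, theta, c):
        tau = np.array([-1.2, -0.3, 0.9, 2.0])
        p0 = rs.pcm_category_probs(theta, tau)
        p1 = rs.pcm_category_probs(theta + c, tau + c)
        np.testing.assert_allclose(p0, p1, atol=1e-10)

    def test_simulated_frequencies_match_probabilities(self):
        rng = np.random.default_rng(7)
        tau = np.array([-1.5, -0.2, 0.4, 1.8])
        p = rs.pcm_category_probs(0.3, tau)
        draws = rs.sample_pcm_matrix(np.full(100_000, 0.3), [tau], rng)[:, 0]
        freq = np.bincount(draws, minlength=5) / draws.size
        # binomial 4-sigma bound at n=1e5
        np.testing.assert_allclose(freq, p, atol=4 * np.sqrt(0.25 / 100_000) + 2e-3)


class TestExpectedScore:
    def test_symmetric_thresholds_midpoint(self):
        assert rs.pcm_expected_score(0.0, [-1, 0, 1]) == pytest.approx(1.5, abs=1e-12)

    def test_saturation(self):
        assert rs.pcm_expected_score(10.0, [-1, 0, 1]) == pytest.approx(3.0, abs=1e-3)

    def test_matches_brute_force_sum(self):
        tau = [-1.0, 0.0, 1.0]
        p = rs.pcm_category_probs(1.0, tau)
        brute = sum(x * p[x] for x in range(4))
        assert rs.pcm_expected_score(1.0, tau) == pytest.approx(brute, abs=1e-12)

    def test_strictly_increasing_in_theta(self):
        tau = np.array([0.4, -0.5, 1.2])  # disordered on purpose
        grid = np.linspace(-8, 8, 200)
        e = rs.pcm_expected_score(grid, tau)
        assert np.all(np.diff(e) > 0)


class TestCalibration:
    def test_parameter_recovery(self, health_calibration):
        """Locations recovered from simulated data (truth from the generator)."""
        hc = health_calibration
        true_loc = np.array([t.mean() for t in hc["taus_true"]])
        true_loc -= true_loc.mean()
        est = np.array([c.location for c in hc["cals"]])
        rmse = np.sqrt(np.mean((est - true_loc) ** 2))
        assert rmse <= 0.1
        assert abs(est.mean()) < 1e-8  # centering convention
        for c in hc["cals"]:
            assert c.location == pytest.approx(np.mean(c.thresholds), abs=1e-10)
            assert len(c.thresholds) == 4

    def test_identical_items_get_equal_locations(self):
        rng = np.random.default_rng(31)
        taus = make_thresholds([0.4, 0.4, -0.2, 0.0, -0.6])
        data = rs.sample_pcm_matrix(rng.normal(0, 2.5, 1500), taus, rng)
        cals, _ = rs.calibrate_items(data)
        joint_se = math.hypot(cals[0].se_location, cals[1].se_location)
        assert abs(cals[0].location - cals[1].location) < 2 * joint_se

    def test_invariance_across_ability_split(self):
        """Item comparisons are sample-free: low- and high-ability halves
        yield the same calibration within sampling error."""
        rng = np.random.default_rng(17)
        taus = make_thresholds([-0.8, -0.3, 0.1, 0.5, 0.9], span=2.5)
        theta = rng.normal(0, 2.5, 3000)
        data = rs.sample_pcm_matrix(theta, taus, rng)
        med = np.median(theta)
        lo, _ = rs.calibrate_items(data[theta <= med])
        hi, _ = rs.calibrate_items(data[theta > med])
        for cl, ch in zip(lo, hi):
            joint = 3 * math.hypot(cl.se_location, ch.se_location)
            assert abs(cl.location - ch.location) < joint

    def test_null_category_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        taus = make_thresholds([0.0, 0.2, -0.2, 0.1])
        data = rs.sample_pcm_matrix(rng.normal(0, 1.5, 400), taus, rng)
        data[:, 0][data[:, 0] == 4] = 3  # kill the top category of item 1
        cals, rep = rs.calibrate_items(data)
        assert cals[0].null_categories == (4,)
        assert any("structural zero" in w for w in rep.warnings)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            rs.calibrate_items(np.zeros((10, 1), dtype=int))


class TestPersonEstimation:
    def test_wle_closed_form_single_dichotomous_item(self):
        """WLE for a single item at delta=0: maximize 1.5 log p + 0.5 log q,
        stationary at p=3/4, i.e. theta = ln 3."""
        cal = [rs.ItemCalibration("i1", np.array([0.0]))]
        up = rs.estimate_person(np.array([1]), cal, method="WLE")
        assert up.theta == pytest.approx(math.log(3), abs=1e-6)
        down = rs.estimate_person(np.array([0]), cal, method="WLE")
        assert down.theta == pytest.approx(-math.log(3), abs=1e-6)
        assert up.extreme_flag and down.extreme_flag
        assert up.se > 0

    def test_half_max_score_on_symmetric_instrument_is_zero(self):
        cals = [rs.ItemCalibration(f"i{k}", np.array([-1.5, -0.5, 0.5, 1.5]))
                for k in range(4)]
        est = rs.estimate_person(np.array([2, 2, 2, 2]), cals, method="WLE")
        assert est.theta == pytest.approx(0.0, abs=1e-6)
        est_m = rs.estimate_person(np.array([2, 2, 2, 2]), cals, method="MLE")
        assert est_m.theta == pytest.approx(0.0, abs=1e-6)

    def test_raw_score_sufficiency(self):
        """All complete response patterns with one raw score share one measure."""
        cals = [rs.ItemCalibration(f"i{k}", t)
                for k, t in enumerate(make_thresholds([-0.5, 0.0, 0.7]))]
        patterns = [(4, 1, 1), (2, 2, 2), (0, 2, 4), (1, 4, 1)]
        thetas = {rs.estimate_person(np.array(p), cals).theta for p in patterns}
        assert max(thetas) - min(thetas) < 1e-8

    def test_all_missing_is_an_error(self):
        cals = [rs.ItemCalibration("i", np.array([0.0]))]
        with pytest.raises(ValueError):
            rs.estimate_person(np.array([-1]), cals)

    @pytest.mark.parametrize("L", [7, 18])
    def test_wle_less_biased_than_mle(self, L):
        """Warm's correction shrinks the outward bias of the MLE (checked at
        theta in {-2, 0, 2}, extreme raw scores excluded from both)."""
        rng = np.random.default_rng(400 + L)
        taus = make_thresholds(np.linspace(-1, 1, L), span=2.5)
        cals = [rs.ItemCalibration(f"i{k}", t) for k, t in enumerate(taus)]
        worse = 0
        for th0 in (-2.0, 0.0, 2.0):
            data = rs.sample_pcm_matrix(np.full(5000, th0), taus, rng)
            wle = rs.estimate_persons(data, cals, method="WLE")
            mle = rs.estimate_persons(data, cals, method="MLE")
            keep = [not p.extreme_flag for p in wle]
            bw = np.mean([p.theta for p, k in zip(wle, keep) if k]) - th0
            bm = np.mean([p.theta for p, k in zip(mle, keep) if k]) - th0
            if abs(bw) > abs(bm) + 0.02:
                worse += 1
        assert worse == 0

    def test_batch_matches_single(self):
        rng = np.random.default_rng(9)
        taus = make_thresholds([-0.3, 0.2, 0.6])
        cals = [rs.ItemCalibration(f"i{k}", t) for k, t in enumerate(taus)]
        data = rs.sample_pcm_matrix(rng.normal(0, 2, 50), taus, rng)
        data[0, 1] = rs.MISSING
        batch = rs.estimate_persons(data, cals)
        for row, est in zip(data, batch):
            single = rs.estimate_person(row, cals)
            assert est.theta == pytest.approx(single.theta, abs=1e-10)
            assert est.se == pytest.approx(single.se, abs=1e-10)
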