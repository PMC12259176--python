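"""RS-MB plane geometry, PQ statistic, behavior prediction, theta sweep."""

import numpy as np
import pytest

from memdecode import classify as cl
from memdecode import plane as pl
from memdecode import syndata as sd
from memdecode.classify import LinearClassifier

from conftest import single_bin_pop


class TestMBWeights:
    def test_prototype_difference(self):
        # high-half mean [10, 2], low-half mean [6, 2] -> w = [4, 0]
        Xn = np.array([[10.0, 2.0], [10.0, 2.0], [6.0, 2.0], [6.0, 2.0]])
        Xr = Xn.copy()
        clf = pl.mb_weights(Xn, Xr, np.array([0.9, 0.8, 0.2, 0.1]))
        np.testing.assert_allclose(clf.w, [4.0, 0.0])

    def test_identical_scores_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            pl.mb_weights(X, X, np.full(4, 0.5))

    def test_null_gain_population_decodes_memorability_at_chance(self):
        rng = np.random.default_rng(0)
        n, u = 200, 30
        m = rng.random(n)
        Xn = rng.poisson(8, (n, u)).astype(float)  # rates independent of m
        Xr = rng.poisson(7, (n, u)).astype(float)
        train = np.arange(n) < n // 2
        clf = pl.mb_weights(Xn[train], Xr[train], m[train])
        med = np.median(m[train])
        pred_high = (Xn[~train] @ clf.w - clf.b) > 0
        acc = np.mean(pred_high == (m[~train] > med))
        assert abs(acc - 0.5) < 3 * 0.5 / np.sqrt((~train).sum())

    def test_itc_population_decodes_memorability(self, itc_pop):
        from memdecode.classify import _window_counts
        r = _window_counts(itc_pop, (100, 500))
        Xn, Xr = r[:, :, 0].T, r[:, :, 1].T
        n = itc_pop.n_pseudoimages
        train = np.arange(n) % 2 == 0
        clf = pl.mb_weights(Xn[train], Xr[train], itc_pop.memorability[train])
        med = np.median(itc_pop.memorability[train])
        pred_high = (Xn[~train] @ clf.w - clf.b) > 0
        acc = np.mean(pred_high == (itc_pop.memorability[~train] > med))
        assert acc - 0.5 > 3 * 0.5 / np.sqrt((~train).sum())


class TestPlaneGeometry:
    def test_hand_angles(self):
        assert pl.plane_gamma([1, 1], [1, 0]).gamma_deg == pytest.approx(45.0)
        assert pl.plane_gamma([1, 0], [0, 1]).gamma_deg == pytest.approx(90.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        g1 = pl.plane_gamma(a, b).gamma_deg
        g2 = pl.plane_gamma(3.7 * a, 0.2 * b).gamma_deg
        assert g1 == pytest.approx(g2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pl.plane_gamma(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            pl.plane_gamma(np.ones(3), 2.0 * np.ones(3))


class TestRotatedWeights:
    @pytest.fixture()
    def geom(self):
        rng = np.random.default_rng(1)
        one = np.ones(40)
        mb = np.ones(40) + rng.normal(0, 0.8, 40)
        return pl.plane_gamma(one, mb)

    def test_theta_zero_returns_rs_axis(self, geom):
        np.testing.assert_allclose(pl.rotated_weights(0.0, geom),
                                   geom.one_hat, atol=1e-12)

    def test_theta_gamma_returns_mb_axis(self, geom):
        np.testing.assert_allclose(pl.rotated_weights(geom.gamma_deg, geom),
                                   geom.mb_hat, atol=1e-10)

    def test_hand_coefficients_at_gamma60_theta90(self):
        one = np.array([1.0, 0.0])
        mb = np.array([np.cos(np.radians(60)), np.sin(np.radians(60))])
        geom = pl.plane_gamma(one, mb)
        w = pl.rotated_weights(90.0, geom)
        # coefficients (-cot 60, csc 60) = (-0.5774, 1.1547); W orthogonal to RS
        expected = -0.57735027 * one + 1.15470054 * mb
        np.testing.assert_allclose(w, expected, atol=1e-7)
        assert abs(w @ one) < 1e-12

    @pytest.mark.parametrize("theta", [-60.0, 0.0, 30.0, 90.0, 150.0])
    def test_unit_norm_and_angle_contract(self, geom, theta):
        w = pl.rotated_weights(theta, geom)
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)
        cosang = np.clip(w @ geom.one_hat, -1, 1)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(abs(theta), abs=1e-8)

    def test_memorability_blind_direction(self, geom):
        w = pl.rotated_weights(geom.gamma_deg + 90.0, geom)
        assert abs(w @ geom.mb_hat) < 1e-10
        # general identity: W(theta) . mb_hat = cos(gamma - theta)
        for theta in (10.0, 45.0, 120.0):
            w = pl.rotated_weights(theta, geom)
            assert w @ geom.mb_hat == pytest.approx(
                np.cos(np.radians(geom.gamma_deg - theta)), abs=1e-10)


class TestProjectPlane:
    def _pop_from_responses(self, Xn, Xr, memorability):
        counts = np.stack([Xn.T, Xr.T], axis=2).astype(int)
        return single_bin_pop(counts, memorability, window=(0, 1000))

    def test_isotropic_cloud_gives_circular_contour(self):
        rng = np.random.default_rng(0)
        n, u = 10_000, 2
        base = rng.normal(100, 1.0, (n, u))
        pop = self._pop_from_responses(np.rint(base), np.rint(base + 0.0),
                                       rng.random(n))
        geom = pl.plane_gamma(np.ones(2), np.array([1.0, 0.2]))
        df, ellipses = pl.project_plane(pop, geom, (0, 1000))
        for e in ellipses:
            ratio = e.axis_lengths[0] / e.axis_lengths[1]
            assert ratio < 1.1

    def test_stretched_cloud_eigenvalue_ratio(self):
        rng = np.random.default_rng(1)
        n = 10_000
        one_hat = np.ones(2) / np.sqrt(2)
        ortho = np.array([1.0, -1.0]) / np.sqrt(2)
        pts = (100 + rng.normal(0, 3.0, n)[:, None] * one_hat
               + rng.normal(0, 1.0, n)[:, None] * ortho)
        pop = self._pop_from_responses(np.rint(pts), np.rint(pts), rng.random(n))
        geom = pl.plane_gamma(np.ones(2), np.array([1.0, 0.0]))
        _, ellipses = pl.project_plane(pop, geom, (0, 1000))
        ratios = [e.axis_lengths[0] / e.axis_lengths[1] for e in ellipses]
        assert np.median(ratios) == pytest.approx(3.0, rel=0.15)

    def test_view_rotation_preserves_eigenvalue_ratios(self):
        rng = np.random.default_rng(2)
        n = 2000
        pts = rng.normal(50, 2.0, (n, 2)) * np.array([1.0, 2.0])
        pop = self._pop_from_responses(np.rint(pts), np.rint(pts), rng.random(n))
        geom = pl.plane_gamma(np.ones(2), np.array([1.0, 0.1]))
        _, e0 = pl.project_plane(pop, geom, (0, 1000), rotate_view=0.0)
        _, e45 = pl.project_plane(pop, geom, (0, 1000), rotate_view=45.0)
        r0 = sorted(e.axis_lengths[0] / e.axis_lengths[1] for e in e0)
        r45 = sorted(e.axis_lengths[0] / e.axis_lengths[1] for e in e45)
        np.testing.assert_allclose(r0, r45, rtol=1e-6)


class TestPredictBehavior:
    def test_perfect_classifier_scores_everywhere(self):
        rng = np.random.default_rng(0)
        n, u = 80, 4
        Xn = rng.normal(30, 1, (n, u))
        Xr = rng.normal(10, 1, (n, u))
        clf = cl.fld_weights(Xn, Xr)
        acc = pl.predict_behavior(Xn, Xr, rng.random(n), clf,
                                  np.array([0.25, 0.5, 0.75]))
        np.testing.assert_allclose(acc, 1.0)

    def test_empty_quartile_raises(self):
        rng = np.random.default_rng(1)
        Xn = rng.normal(10, 1, (8, 3))
        clf = cl.fld_weights(Xn, Xn - 2)
        with pytest.raises(ValueError):
            pl.predict_behavior(Xn, Xn, np.full(8, 0.9), clf,
                                np.array([0.25, 0.5, 0.75]))


class TestPQ:
    centers = np.array([0.125, 0.375, 0.625, 0.875])

    def series(self, slope_n, slope_r, intercept=0.5):
        return np.stack([intercept + slope_n * self.centers,
                         intercept + slope_r * self.centers], axis=1)

    def test_identical_slopes_give_one(self):
        behavior = self.series(0.2, 0.3)
        predicted = self.series(0.2, 0.3, intercept=0.1)
        assert pl.pq(self.centers, behavior, predicted).pq == pytest.approx(1.0)

    def test_perpendicular_slopes_give_zero(self):
        # slope angles 63.43 and -26.57 degrees differ by exactly 90
        behavior = self.series(2.0, 2.0)
        predicted = self.series(-0.5, -0.5)
        assert pl.pq(self.centers, behavior, predicted).pq == pytest.approx(0.0, abs=1e-12)

    def test_reflection_of_obtuse_differences(self):
        # angles +80 and -55 degrees: raw difference 135 -> reflected 45 -> 0.5
        b = self.series(np.tan(np.radians(80)), np.tan(np.radians(80)))
        p = self.series(np.tan(np.radians(-55)), np.tan(np.radians(-55)))
        assert pl.pq(self.centers, b, p).pq == pytest.approx(0.5, abs=1e-9)

    def test_symmetry_in_arguments(self):
        b = self.series(0.4, -0.1)
        p = self.series(0.1, 0.3)
        assert pl.pq(self.centers, b, p).pq == pytest.approx(
            pl.pq(self.centers, p, b).pq)

    def test_condition_exchange_invariance(self):
        b = self.series(0.4, -0.1)
        p = self.series(0.1, 0.3)
        assert pl.pq(self.centers, b, p).pq == pytest.approx(
            pl.pq(self.centers, b[:, ::-1], p[:, ::-1]).pq)

    def test_needs_two_bins(self):
        with pytest.raises(ValueError):
            pl.pq(np.array([0.5]), np.ones((1, 2)), np.ones((1, 2)))


class TestRescalePredictions:
    def test_identity_factor(self):
        b = np.array([80.0, 85.0, 90.0])
        out = pl.rescale_predictions(b, b)
        assert out.factor == pytest.approx(1.0)

    def test_closed_form_factor(self):
        b = np.array([40.0, 50.0, 60.0])
        out = pl.rescale_predictions(2 * b, b)
        assert out.factor == pytest.approx(0.5)

    def test_clamping_above_100(self):
        pred = np.array([60.0, 120.0])
        behavior = np.array([60.0, 120.0])
        out = pl.rescale_predictions(pred, behavior)
        assert out.predicted_pct[1] == 100.0 and out.clamped[1]

    def test_zero_predictions_rejected(self):
        with pytest.raises(ValueError):
            pl.rescale_predictions(np.zeros(3), np.ones(3))


class TestThetaSweep:
    @pytest.fixture(scope="class")
    def sweep_inputs(self, itc_bundle, itc_pop):
        choices = sd.simulate_behavior(itc_bundle["sequence"],
                                       itc_bundle["images"], seed=5)
        qb = np.quantile(itc_pop.memorability, [0.25, 0.5, 0.75])
        behavior = pl.behavior_by_quartile(choices, itc_bundle["sequence"],
                                           itc_bundle["images"], qb)
        return behavior

    def test_theta_zero_matches_rs_cv_performance(self, itc_pop, sweep_inputs):
        res = pl.theta_sweep(itc_pop, sweep_inputs, (100, 500),
                             np.arange(-30.0, 150.0, 10.0), n_folds=5, seed=6)
        cv = cl.cv_performance(itc_pop, "rs", (100, 500), n_folds=5, seed=6)
        tab = res["table"]
        at0 = tab[tab.theta_deg == 0.0].accuracy.iloc[0]
        fold_sizes = np.bincount(cl.make_folds(itc_pop, 5, 6))
        total = 2 * fold_sizes.sum()
        overall_cv = (cv.fold_accuracy * 2 * fold_sizes).sum() / total
        assert at0 == pytest.approx(overall_cv)

    def test_narrow_grid_warns(self, itc_pop, sweep_inputs, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="memdecode.plane"):
            pl.theta_sweep(itc_pop, sweep_inputs, (100, 500),
                           np.arange(0.0, 50.0, 10.0), n_folds=4, seed=0)
        assert any("180" in rec.message for rec in caplog.records)
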