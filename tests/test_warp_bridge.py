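"""Warp bridge sampling: moments, warped densities, iterative scheme."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from mptbridge import (
    WarpMoments,
    bridge_from_draws,
    estimate_moments,
    iterative_bridge,
    proposal_log_terms,
    warped_log_density_terms,
)


class TestEstimateMoments:
    def test_standard_normal_draws(self):
        rng = np.random.default_rng(0)
        m = estimate_moments(rng.standard_normal((100000, 3)))
        assert np.all(np.abs(m.v) < 0.05)
        assert np.all(np.abs(m.R - np.eye(3)) < 0.05)

    def test_hand_covariance_four_points(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        m = estimate_moments(pts)
        np.testing.assert_allclose(m.v, [1.0, 1.0])
        S = np.cov(pts, rowvar=False)
        np.testing.assert_allclose(m.R @ m.R.T, S, atol=1e-12)

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            estimate_moments(rng.standard_normal((3, 5)))
        with pytest.raises(ValueError):
            estimate_moments(np.zeros((50, 2)))


class Test1DNormalCancellation:
    """p~ = c * N(m, s^2) with v=m, R=s: every l1 and l2 term equals c."""

    def setup_method(self):
        self.c = 2.5
        self.m, self.s = 0.7, 1.3
        self.logpost = lambda x: np.log(self.c) + multivariate_normal.logpdf(
            np.atleast_2d(x), [self.m], [[self.s**2]]
        )
        self.moments = WarpMoments(v=np.array([self.m]), R=np.array([[self.s]]))

    def test_l1_constant(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(self.m, self.s, size=(20, 1))
        l1 = warped_log_density_terms(draws, self.moments, self.logpost)
        np.testing.assert_allclose(np.exp(l1), self.c, rtol=1e-10)

    def test_l2_constant(self):
        rng = np.random.default_rng(3)
        eta = rng.standard_normal((20, 1))
        l2 = proposal_log_terms(eta, self.moments, self.logpost)
        np.testing.assert_allclose(np.exp(l2), self.c, rtol=1e-10)

    def test_l2_mirror_symmetry(self):
        lp = lambda x: -0.5 * ((np.atleast_2d(x) - 0.4) ** 2).sum(axis=1) - 0.1 * (
            np.atleast_2d(x) ** 3
        ).sum(axis=1)
        moments = WarpMoments(v=np.array([0.3]), R=np.array([[1.2]]))
        eta = np.array([[0.8], [-0.8]])
        vals = proposal_log_terms(eta, moments, lp)
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_l2_center_point(self):
        eta = np.zeros((1, 1))
        val = proposal_log_terms(eta, self.moments, self.logpost)[0]
        expected = (
            np.log(self.s)
            + float(self.logpost(np.array([[self.m]])))
            + 0.5 * np.log(2 * np.pi)
        )
        assert val == pytest.approx(expected, abs=1e-12)

    def test_symmetric_posterior_mirror_collapse(self):
        """For a posterior symmetric about v, averaging the two mirror terms
        equals either one alone."""
        draws = np.random.default_rng(4).normal(self.m, self.s, size=(10, 1))
        with_mirror = warped_log_density_terms(draws, self.moments, self.logpost)
        without = warped_log_density_terms(
            draws, self.moments, self.logpost, mirror=False
        )
        np.testing.assert_allclose(with_mirror, without, rtol=1e-10)


class TestIterativeBridge:
    def test_constant_fixed_point_single_iteration(self):
        c = 3.7
        est = iterative_bridge(np.full(5, np.log(c)), np.full(4, np.log(c)))
        assert np.exp(est.log_ml) == pytest.approx(c, rel=1e-12)
        assert est.converged

    def test_hand_iterated_example(self):
        """l1 = {1, 3}, l2 = {2, 2}, equal weights, init 1 -> ~1.866."""
        est = iterative_bridge(
            np.log([1.0, 3.0]), np.log([2.0, 2.0]), s1=0.5, s2=0.5, init=0.0, tol=1e-12
        )
        assert np.exp(est.log_ml) == pytest.approx(1.866, abs=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-300.0, 300.0))
    def test_scale_equivariance(self, a):
        log_l1 = np.array([0.2, 1.1, -0.4])
        log_l2 = np.array([0.7, 0.1])
        base = iterative_bridge(log_l1, log_l2, tol=1e-12).log_ml
        shifted = iterative_bridge(log_l1 + a, log_l2 + a, tol=1e-12).log_ml
        assert shifted == pytest.approx(base + a, abs=1e-8)

    def test_all_neg_inf_raises(self):
        with pytest.raises(ValueError):
            iterative_bridge(np.array([-np.inf]), np.array([-np.inf]))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            iterative_bridge(np.zeros(2), np.zeros(2), s1=0.7, s2=0.7)


class TestBridgeFromDraws:
    def _gaussian_target(self, const=7.3):
        mean = np.array([1.0, 2.0])
        cov = np.diag([0.5, 2.0])
        logpost = lambda x: np.log(const) + multivariate_normal.logpdf(
            np.atleast_2d(x), mean, cov
        )
        return mean, cov, logpost

    def test_known_constant_recovery(self):
        mean, cov, logpost = self._gaussian_target()
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(10):
            d1 = rng.multivariate_normal(mean, cov, size=4000)
            dm = rng.multivariate_normal(mean, cov, size=4000)
            est = bridge_from_draws(d1, logpost, method="warp3", moment_draws=dm, rng=rng)
            assert est.converged
            vals.append(est.log_ml)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - np.log(7.3)) < 3 * se + 1e-3

    def test_seed_determinism(self):
        mean, cov, logpost = self._gaussian_target()
        draws = np.random.default_rng(6).multivariate_normal(mean, cov, size=3000)
        a = bridge_from_draws(
            draws[:1500], logpost, moment_draws=draws[1500:],
            rng=np.random.default_rng(77),
        )
        b = bridge_from_draws(
            draws[:1500], logpost, moment_draws=draws[1500:],
            rng=np.random.default_rng(77),
        )
        assert a.log_ml == b.log_ml

    def test_self_consistency_across_seeds(self):
        """Bridging the same model twice with different proposal seeds gives
        a log Bayes factor of ~0."""
        mean, cov, logpost = self._gaussian_target()
        draws = np.random.default_rng(8).multivariate_normal(mean, cov, size=8000)
        ests = [
            bridge_from_draws(
                draws[:4000], logpost, moment_draws=draws[4000:],
                rng=np.random.default_rng(s),
            ).log_ml
            for s in (1, 2)
        ]
        assert abs(ests[0] - ests[1]) < 0.02

    def test_warp0_needs_no_moments(self):
        logpost = lambda x: multivariate_normal.logpdf(np.atleast_2d(x), np.zeros(2), np.eye(2))
        draws = np.random.default_rng(9).standard_normal((2000, 2))
        est = bridge_from_draws(draws, logpost, method="warp0", rng=np.random.default_rng(0))
        assert est.log_ml == pytest.approx(0.0, abs=0.05)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            bridge_from_draws(np.zeros((10, 1)), lambda x: 0.0, method="warp7")


class TestWarpLadder:
    def test_warped_draws_match_standard_normal_moments(self):
        """Warping second-half draws with first-half moments yields mean ~0,
        covariance ~I, and vanishing third central moments even for a skewed
        source distribution."""
        rng = np.random.default_rng(10)
        # strongly skewed 3-d draws (log-gamma marginals, correlated)
        raw = np.log(rng.gamma(shape=[0.8, 1.5, 3.0], size=(60000, 3)))
        raw[:, 1] += 0.4 * raw[:, 0]
        first, second = raw[:30000], raw[30000:]
        moments = estimate_moments(first)
        eta = moments.whiten(second)
        b = rng.choice([-1.0, 1.0], size=(eta.shape[0], 1))
        eta = b * eta
        assert np.all(np.abs(eta.mean(axis=0)) < 0.05)
        assert np.all(np.abs(np.cov(eta, rowvar=False) - np.eye(3)) < 0.05)
        third = ((eta - eta.mean(axis=0)) ** 3).mean(axis=0)
        assert np.all(np.abs(third) < 0.1)

    def test_warp_preserves_normalizing_constant_1d(self):
        """Numerically integrating the warped unnormalized density equals
        integrating the unwarped one."""
        from scipy.integrate import quad

        logpost = lambda x: 1.3 * np.atleast_2d(x).sum(axis=1) - np.exp(
            np.atleast_2d(x).sum(axis=1)
        )
        moments = WarpMoments(v=np.array([0.2]), R=np.array([[1.5]]))
        unwarped, _ = quad(lambda x: np.exp(logpost(np.array([[x]]))[0]), -30, 10)
        # warped density: |R|/2 [p(v - R eta) + p(v + R eta)]
        warped, _ = quad(
            lambda e: 0.5
            * 1.5
            * (
                np.exp(logpost(moments.v - moments.R @ [e]))
                + np.exp(logpost(moments.v + moments.R @ [e]))
            )[0],
            -20,
            20,
        )
        assert warped == pytest.approx(unwarped, rel=1e-6)
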