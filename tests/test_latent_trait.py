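"""Latent-trait hierarchy: transforms, priors, marginalized posterior."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import invwishart, t as student_t

from mptbridge import (
    CountTable,
    DELTA_PRIOR_PRESETS,
    LatentTraitModel,
    ParameterState,
    log_group_level_factor,
    log_unnormalized_posterior,
    make_log_posterior,
    theta_for_participant,
    trans_from_xi,
    xi_from_trans,
)


class TestXiTransform:
    def test_midpoint(self):
        xi, _ = xi_from_trans(np.zeros(3), 10.0)
        np.testing.assert_allclose(xi, 5.0)

    def test_log_jacobian_hand_value(self):
        # per component: log(xi_max * phi(0)) = log(10 * 0.39894...)
        _, lj = xi_from_trans(np.zeros(1), 10.0)
        assert lj == pytest.approx(np.log(10.0 / np.sqrt(2 * np.pi)), abs=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        xt = rng.normal(size=5)
        xi, _ = xi_from_trans(xt, 2.0)
        np.testing.assert_allclose(trans_from_xi(xi, 2.0), xt, atol=1e-12)

    def test_invalid_xi_max(self):
        with pytest.raises(ValueError):
            xi_from_trans(np.zeros(2), -1.0)


class TestModelConfiguration:
    def test_nu_defaults_to_P_plus_one(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=5)
        assert m.nu == pc_spec.P + 1

    def test_delta_prior_presets(self, pc_spec):
        assert DELTA_PRIOR_PRESETS == {"narrow": 0.52, "medium": 0.84, "wide": 1.28}
        for name, sd in DELTA_PRIOR_PRESETS.items():
            m = LatentTraitModel(
                spec=pc_spec, I=4, n_conditions=2, free_delta=("c",), sigma_delta=name
            )
            assert m.sigma_delta == sd

    def test_one_condition_cannot_free_delta(self, pc_spec):
        with pytest.raises(ValueError):
            LatentTraitModel(spec=pc_spec, I=4, n_conditions=1, free_delta=("c",))

    def test_dimension(self, pc_spec):
        m = LatentTraitModel(
            spec=pc_spec, I=7, n_conditions=2, free_delta=("c", "r")
        )
        assert m.dim == pc_spec.P * (7 + 2) + 2
        assert len(m.labels()) == m.dim

    def test_pack_unpack_roundtrip(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=3, n_conditions=2, free_delta=("r",))
        psi = np.random.default_rng(2).normal(size=m.dim)
        np.testing.assert_array_equal(m.pack(m.unpack(psi)), psi)


class TestThetaForParticipant:
    def _state(self, model, **kw):
        P, I = model.P, model.I
        defaults = dict(
            mu=np.zeros(P),
            xi_trans=np.zeros(P),
            delta=np.zeros(model.n_free_delta),
            omega=np.zeros((I, P)),
        )
        defaults.update(kw)
        return ParameterState(**defaults)

    def test_all_zero_gives_half(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=2)
        th = theta_for_participant(self._state(m), m, 0)
        np.testing.assert_allclose(th, 0.5)

    def test_condition_shift(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=2, n_conditions=2, free_delta=("c",))
        st = self._state(m, delta=np.array([1.0]))
        th1 = theta_for_participant(st, m, 0, condition=0)
        th2 = theta_for_participant(st, m, 0, condition=1)
        assert th1[0] == pytest.approx(ndtr(-0.5))  # ~ 0.3085
        assert th2[0] == pytest.approx(ndtr(0.5))  # ~ 0.6915
        np.testing.assert_allclose(th1[1:], 0.5)

    def test_zero_scale_means_homogeneous_participants(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=3)
        rng = np.random.default_rng(3)
        st = self._state(m, xi_trans=np.full(m.P, -30.0), omega=rng.normal(size=(3, m.P)))
        # xi = xi_max * Phi(-30) ~ 0: everyone collapses onto Phi(mu)
        ths = [theta_for_participant(st, m, i) for i in range(3)]
        np.testing.assert_allclose(ths[0], ths[1], atol=1e-12)
        np.testing.assert_allclose(ths[1], ths[2], atol=1e-12)

    def test_index_errors(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=2)
        with pytest.raises(IndexError):
            theta_for_participant(self._state(m), m, 5)
        with pytest.raises(IndexError):
            theta_for_participant(self._state(m), m, 0, condition=1)


class TestGroupLevelFactor:
    def test_exact_value_P1_I1(self):
        # Gamma(1.5) / Gamma(1) * pi^{-1/2} * 1 = 0.5
        assert log_group_level_factor([[0.0]], nu=2) == pytest.approx(np.log(0.5))

    def test_student_t_identity_P1(self):
        """For P = I = 1 the marginalized random-effect density is a scaled
        Student-t: omega ~ t_nu / sqrt(nu)."""
        for nu in (2, 4):
            for w in (-1.3, 0.0, 0.7, 2.5):
                ours = log_group_level_factor([[w]], nu=nu)
                expected = student_t.logpdf(w * np.sqrt(nu), df=nu) + 0.5 * np.log(nu)
                assert ours == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_determinant(self):
        vals = [
            log_group_level_factor(np.full((2, 2), s), nu=3) for s in (0.0, 0.5, 1.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_monte_carlo_oracle_P2_I3(self):
        """Matches the Monte Carlo integral over the inverse Wishart prior."""
        rng = np.random.default_rng(7)
        Om = rng.normal(size=(3, 2)) * 0.8
        nu = 3
        n = 200_000
        Q = invwishart.rvs(df=nu, scale=np.eye(2), size=n, random_state=rng)
        det = Q[:, 0, 0] * Q[:, 1, 1] - Q[:, 0, 1] ** 2
        logp = -3 * np.log(2 * np.pi) - 1.5 * np.log(det)
        for i in range(3):
            w = Om[i]
            quad = (
                Q[:, 1, 1] * w[0] ** 2
                - 2 * Q[:, 0, 1] * w[0] * w[1]
                + Q[:, 0, 0] * w[1] ** 2
            ) / det
            logp = logp - 0.5 * quad
        vals = np.exp(logp)
        mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n)
        exact = np.exp(log_group_level_factor(Om, nu))
        assert abs(mc - exact) < 3 * se


class TestUnnormalizedPosterior:
    def test_no_data_reduces_to_priors(self, pc_spec):
        m = LatentTraitModel(spec=pc_spec, I=2, n_conditions=2, free_delta=("c",))
        counts = np.zeros((2, 2, pc_spec.n_categories), dtype=int)
        table = CountTable.from_spec(pc_spec, counts, J=[0, 0])
        rng = np.random.default_rng(5)
        psi = rng.normal(size=m.dim)
        st = m.unpack(psi)
        got = log_unnormalized_posterior(st, table, m)
        P = m.P
        expected = (
            log_group_level_factor(st.omega, m.nu)
            - 0.5 * (st.mu**2).sum()
            - 0.5 * P * np.log(2 * np.pi)
            - 0.5 * (st.xi_trans**2).sum()
            - 0.5 * P * np.log(2 * np.pi)
            - 0.5 * (st.delta**2).sum() / m.sigma_delta**2
            - 0.5 * np.log(2 * np.pi)
            - np.log(m.sigma_delta)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_participant_permutation_invariance(self, small_pc_dataset):
        spec, model, table, _ = small_pc_dataset
        logpost = make_log_posterior(model, table)
        rng = np.random.default_rng(11)
        psi = rng.normal(size=model.dim) * 0.3
        st = model.unpack(psi)
        perm = rng.permutation(model.I)
        table2 = CountTable.from_spec(spec, table.counts[perm], J=table.J)
        st2 = ParameterState(
            mu=st.mu, xi_trans=st.xi_trans, delta=st.delta, omega=st.omega[perm]
        )
        a = logpost(psi)
        b = log_unnormalized_posterior(st2, table2, model)
        assert a == pytest.approx(b, abs=1e-9)

    def test_batch_matches_scalar(self, small_pc_dataset):
        _, model, table, _ = small_pc_dataset
        logpost = make_log_posterior(model, table)
        rng = np.random.default_rng(13)
        Psi = rng.normal(size=(6, model.dim)) * 0.4
        batch = logpost(Psi)
        scalar = np.array([logpost(psi) for psi in Psi])
        np.testing.assert_allclose(batch, scalar, atol=1e-10)

    def test_marginalized_matches_explicit_Q_integral_toy(self, binomial_spec):
        """P=1, I=1: integrating the explicit-Q joint over Q by quadrature
        recovers the closed-form marginalized density."""
        from scipy.integrate import quad
        from scipy.stats import invgamma, norm

        m = LatentTraitModel(spec=binomial_spec, I=1)
        counts = np.array([[[13, 7]]])
        table = CountTable.from_spec(binomial_spec, counts, J=[20])
        logpost = make_log_posterior(m, table)
        psi = np.array([0.3, -0.2, 0.5])  # mu, xi_trans, omega
        # explicit-Q density: lik * N(omega; 0, q) * InvWishart_1(q; nu, 1) * priors
        mu, xit, om = psi
        xi = 10.0 * ndtr(xit)
        theta = ndtr(mu + xi * om)
        from scipy.stats import binom

        lik = binom.pmf(13, 20, theta)
        nu = m.nu  # = 2
        val, _ = quad(
            lambda q: norm.pdf(om, scale=np.sqrt(q))
            * invgamma.pdf(q, a=nu / 2.0, scale=0.5),
            0,
            np.inf,
        )
        expected = np.log(lik) + np.log(val) + norm.logpdf(mu) + norm.logpdf(xit)
        assert logpost(psi) == pytest.approx(expected, abs=1e-8)

    def test_dimension_mismatch_raises(self, small_pc_dataset):
        _, model, table, _ = small_pc_dataset
        logpost = make_log_posterior(model, table)
        with pytest.raises(ValueError):
            logpost(np.zeros(model.dim + 1))
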