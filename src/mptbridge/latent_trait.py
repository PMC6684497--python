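"""Hierarchical latent-trait MPT model and its unnormalized posterior.

The latent-trait approach places a multivariate normal group distribution on
the probit-transformed participant-level MPT parameters,

    theta'_i = mu + xi (.) omega_i,          omega_i ~ N_P(0, Q),

with a scaled inverse Wishart prior on the covariance: Q ~ InvWishart(nu, I_P)
with nu = P + 1 (uniform priors on correlations) and independent Uniform(0,
xi_max) priors on the scaling parameters xi.  Standard normal priors on the
components of mu correspond to uniform priors on the probability scale for
the group means.

Two-condition designs add a difference vector delta: the group mean becomes
mu - delta/2 in the first and mu + delta/2 in the second condition, with
zero-centered normal priors on the free components of delta; omega_i is
shared across conditions.

The unscaled covariance Q integrates out of the posterior in closed form,
leaving a density over psi = (mu, xi_trans, delta, omega_1..omega_I) that all
sampling and bridge-sampling code in this package targets.  xi is mapped to
the real line by xi_trans = Phi^{-1}(xi / xi_max); the uniform prior times
the Jacobian of that map is exactly a standard normal density on xi_trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, log_ndtr, multigammaln, ndtr, ndtri

from .mpt import CountTable, MptModelSpec

__all__ = [
    "DELTA_PRIOR_PRESETS",
    "LatentTraitModel",
    "ParameterState",
    "xi_from_trans",
    "trans_from_xi",
    "theta_for_participant",
    "log_group_level_factor",
    "log_unnormalized_posterior",
    "make_log_posterior",
]

# Zero-centered normal prior widths for condition differences on the probit
# scale, corresponding to small / medium / large effects on the probability
# scale centered around 0.5.
DELTA_PRIOR_PRESETS = {"narrow": 0.52, "medium": 0.84, "wide": 1.28}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentTraitModel:
    """A latent-trait hierarchical MPT with optional condition differences.

    Parameters
    ----------
    spec : MptModelSpec
        Tree structure (after any equality constraints were applied).
    I : int
        Number of participants.
    n_conditions : int
        1 or 2.  Two-condition designs require the count table to carry a
        condition axis of the same length.
    free_delta : tuple of str
        Names of parameters whose between-condition difference ``delta_p`` is
        free; all other deltas are fixed at zero.
    sigma_delta : float or str
        Prior standard deviation of the free deltas, or one of the preset
        names ``"narrow"`` / ``"medium"`` / ``"wide"``.
    xi_max : float
        Upper bound of the uniform prior on the scaling parameters.
    nu : int or None
        Inverse Wishart degrees of freedom; defaults to ``P + 1``.
    """

    spec: MptModelSpec
    I: int
    n_conditions: int = 1
    free_delta: tuple[str, ...] = ()
    sigma_delta: float | str = "medium"
    xi_max: float = 10.0
    nu: int | None = None
    condition_signs: tuple[float, ...] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        if self.xi_max <= 0:
            raise ValueError("xi_max must be positive")
        if self.nu is None:
            self.nu = self.spec.P + 1
        if isinstance(self.sigma_delta, str):
            try:
                self.sigma_delta = DELTA_PRIOR_PRESETS[self.sigma_delta]
            except KeyError:
                raise ValueError(
                    f"unknown delta prior preset {self.sigma_delta!r}; "
                    f"choose from {sorted(DELTA_PRIOR_PRESETS)}"
                ) from None
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be positive")
        if self.n_conditions not in (1, 2):
            raise ValueError("only one- and two-condition designs are supported")
        if self.n_conditions == 1 and self.free_delta:
            raise ValueError("a one-condition design cannot have free deltas")
        unknown = [p for p in self.free_delta if p not in self.spec.parameters]
        if unknown:
            raise ValueError(f"free_delta references unknown parameters: {unknown}")
        if len(set(self.free_delta)) != len(self.free_delta):
            raise ValueError("duplicate names in free_delta")

    # ------------------------------------------------------------ dimensions
    @property
    def P(self) -> int:
        return self.spec.P

    @property
    def n_free_delta(self) -> int:
        return len(self.free_delta)

    @property
    def dim(self) -> int:
        """Total dimension of psi: P*(I+2) + number of free deltas."""
        return self.P * (self.I + 2) + self.n_free_delta

    @property
    def delta_mask(self) -> np.ndarray:
        """Boolean mask over spec parameters: True where delta_p is free."""
        return np.array([p in self.free_delta for p in self.spec.parameters])

    def labels(self) -> list[str]:
        names = self.spec.parameters
        lab = [f"mu[{p}]" for p in names]
        lab += [f"xi_trans[{p}]" for p in names]
        lab += [f"delta[{p}]" for p in self.free_delta]
        for i in range(self.I):
            lab += [f"omega[{i + 1},{p}]" for p in names]
        return lab

    # ----------------------------------------------------------- state <-> psi
    def unpack(self, psi: np.ndarray) -> "ParameterState":
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (self.dim,):
            raise ValueError(f"psi must have length {self.dim}, got {psi.shape}")
        P, F = self.P, self.n_free_delta
        return ParameterState(
            mu=psi[:P].copy(),
            xi_trans=psi[P : 2 * P].copy(),
            delta=psi[2 * P : 2 * P + F].copy(),
            omega=psi[2 * P + F :].reshape(self.I, P).copy(),
        )

    def pack(self, state: "ParameterState") -> np.ndarray:
        return np.concatenate(
            [state.mu, state.xi_trans, state.delta, state.omega.ravel()]
        )


@dataclass
class ParameterState:
    """One point psi in the unbounded sampling space."""

    mu: np.ndarray
    xi_trans: np.ndarray
    delta: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.xi_trans = np.atleast_1d(np.asarray(self.xi_trans, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float)) if np.size(self.delta) else np.zeros(0)
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        for a in (self.mu, self.xi_trans, self.delta, self.omega):
            if not np.all(np.isfinite(a)):
                raise ValueError("parameter state entries must be finite")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def xi_from_trans(xi_trans, xi_max: float):
    """Map unbounded ``xi_trans`` to ``xi = xi_max * Phi(xi_trans)``.

    Returns ``(xi, log_jacobian)`` where the log-Jacobian of the inverse map
    is ``sum_p [log xi_max + log phi(xi_trans_p)]``.
    """
    if xi_max <= 0:
        raise ValueError("xi_max must be positive")
    xi_trans = np.asarray(xi_trans, dtype=float)
    xi = xi_max * ndtr(xi_trans)
    log_jac = float(
        np.sum(np.log(xi_max) - 0.5 * _LOG_2PI - 0.5 * xi_trans**2)
    )
    return xi, log_jac


def trans_from_xi(xi, xi_max: float) -> np.ndarray:
    """Inverse of :func:`xi_from_trans`: ``xi_trans = Phi^{-1}(xi / xi_max)``."""
    if xi_max <= 0:
        raise ValueError("xi_max must be positive")
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0) or np.any(xi >= xi_max):
        raise ValueError("xi must lie strictly in (0, xi_max)")
    return ndtri(xi / xi_max)


def theta_for_participant(
    state: ParameterState, model: LatentTraitModel, i: int, condition: int = 0
) -> np.ndarray:
    """Probability-scale parameter vector of participant ``i`` in a condition.

    ``theta'_i = mu + sign_c * delta_embedded + xi (.) omega_i`` mapped
    through the standard normal CDF; ``delta_embedded`` carries zeros at
    parameters without a free condition difference.
    """
    if not 0 <= i < model.I:
        raise IndexError(f"participant index {i} out of range")
    if not 0 <= condition < model.n_conditions:
        raise IndexError(f"condition index {condition} out of design")
    xi, _ = xi_from_trans(state.xi_trans, model.xi_max)
    delta_emb = np.zeros(model.P)
    if model.n_free_delta:
        delta_emb[model.delta_mask] = state.delta
    tprime = state.mu + model.condition_signs[condition] * delta_emb + xi * state.omega[i]
    return ndtr(tprime)


# ---------------------------------------------------------------------------
# Posterior density pieces
# ---------------------------------------------------------------------------


def log_group_level_factor(Omega, nu: int) -> float:
    """Log of the group-level factor left after integrating out Q.

    For the I x P random-effect matrix Omega and InvWishart(nu, I_P) prior,
    integrating the product of N(omega_i; 0, Q) densities against the prior
    gives

        Gamma_P((nu+I)/2) / Gamma_P(nu/2) * pi^{-IP/2}
            * |Omega' Omega + I_P|^{-(nu+I)/2}.
    """
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    if not np.all(np.isfinite(Omega)):
        raise ValueError("Omega must be finite")
    I, P = Omega.shape
    sign, logdet = np.linalg.slogdet(Omega.T @ Omega + np.eye(P))
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("non-finite or non-positive determinant")
    return float(
        multigammaln((nu + I) / 2.0, P)
        - multigammaln(nu / 2.0, P)
        - 0.5 * I * P * np.log(np.pi)
        - 0.5 * (nu + I) * logdet
    )


class _Evaluator:
    """Vectorized unnormalized log-posterior over batches of psi vectors.

    Precomputes the flat branch-exponent representation of the tree and the
    count-dependent multinomial coefficients, then evaluates the product-
    multinomial likelihood, the Q-marginalized group factor and the priors
    for a whole (D, dim) batch at once.
    """

    def __init__(self, model: LatentTraitModel, data: CountTable):
        if data.I != model.I:
            raise ValueError(f"data has I={data.I} but model expects I={model.I}")
        if data.n_conditions != model.n_conditions:
            raise ValueError(
                f"data has {data.n_conditions} conditions but model expects "
                f"{model.n_conditions}"
            )
        self.model = model
        self.data = data
        self.V, self.W, self.offsets, cat_off = model.spec.flat_structure()
        if data.counts.shape[-1] != model.spec.n_categories:
            raise ValueError("count table does not match model spec")
        self.counts = data.counts.astype(float)  # (I, C, Ltot)
        # constant: log multinomial coefficients, summed over i, c, k
        J = np.asarray(data.J, dtype=float)
        n_coef = 0.0
        for k in range(model.spec.K):
            blk = data.counts[:, :, cat_off[k] : cat_off[k + 1]]
            n_coef += (gammaln(J[k] + 1) - gammaln(blk + 1.0).sum(axis=-1)).sum()
        self.log_coef = float(n_coef)
        self.delta_mask = model.delta_mask
        self.signs = np.asarray(model.condition_signs[: model.n_conditions])

    def _segment_logsumexp(self, a: np.ndarray) -> np.ndarray:
        """logsumexp over branch segments along the last axis."""
        off = self.offsets
        m = np.maximum.reduceat(a, off, axis=-1)
        safe_m = np.where(np.isfinite(m), m, 0.0)
        expanded = np.repeat(safe_m, np.diff(np.r_[off, a.shape[-1]]), axis=-1)
        s = np.add.reduceat(np.exp(a - expanded), off, axis=-1)
        with np.errstate(divide="ignore"):
            out = np.log(s) + safe_m
        return np.where(np.isfinite(m), out, -np.inf)

    def loglik_by_participant(self, mu, xi_trans, delta, omega) -> np.ndarray:
        """Per-participant product-multinomial log-likelihood, length I.

        Multinomial coefficients are omitted (they are constant in psi and
        cancel in Metropolis ratios); ``__call__`` includes them.
        """
        model = self.model
        xi = model.xi_max * ndtr(np.asarray(xi_trans, dtype=float))
        delta_emb = np.zeros(model.P)
        if model.n_free_delta:
            delta_emb[self.delta_mask] = delta
        base = np.asarray(mu, dtype=float) + xi * np.asarray(omega, dtype=float)
        tprime = base[None, :, :] + self.signs[:, None, None] * delta_emb  # (C, I, P)
        log_branch = log_ndtr(tprime) @ self.V.T + log_ndtr(-tprime) @ self.W.T
        log_cat = self._segment_logsumexp(log_branch)  # (C, I, Ltot)
        counts = np.swapaxes(self.counts, 0, 1)  # (C, I, Ltot)
        with np.errstate(invalid="ignore"):
            ll = np.where(counts > 0, counts * log_cat, 0.0)
        out = ll.sum(axis=(0, 2))
        return np.where(np.isnan(out), -np.inf, out)

    def __call__(self, Psi: np.ndarray) -> np.ndarray:
        model = self.model
        Psi = np.asarray(Psi, dtype=float)
        squeeze = Psi.ndim == 1
        if squeeze:
            Psi = Psi[None, :]
        if Psi.shape[1] != model.dim:
            raise ValueError(f"psi must have dimension {model.dim}")
        D = Psi.shape[0]
        P, I, F = model.P, model.I, model.n_free_delta
        mu = Psi[:, :P]
        xi_trans = Psi[:, P : 2 * P]
        delta = Psi[:, 2 * P : 2 * P + F]
        omega = Psi[:, 2 * P + F :].reshape(D, I, P)

        xi = model.xi_max * ndtr(xi_trans)
        delta_emb = np.zeros((D, P))
        if F:
            delta_emb[:, self.delta_mask] = delta

        # theta' per (draw, condition, participant, parameter)
        base = mu[:, None, :] + xi[:, None, :] * omega  # (D, I, P)
        tprime = (
            base[:, None, :, :]
            + self.signs[None, :, None, None] * delta_emb[:, None, None, :]
        )  # (D, C, I, P)
        log_theta = log_ndtr(tprime)
        log_1mtheta = log_ndtr(-tprime)
        # branch log-probabilities: (D, C, I, B)
        log_branch = log_theta @ self.V.T + log_1mtheta @ self.W.T
        log_cat = self._segment_logsumexp(log_branch)  # (D, C, I, Ltot)
        counts = np.swapaxes(self.counts, 0, 1)  # (C, I, Ltot)
        with np.errstate(invalid="ignore"):
            ll = np.where(counts[None] > 0, counts[None] * log_cat, 0.0)
        loglik = ll.sum(axis=(1, 2, 3)) + self.log_coef

        # group-level factor with Q integrated out
        G = np.einsum("dip,diq->dpq", omega, omega) + np.eye(P)
        sign, logdet = np.linalg.slogdet(G)
        group = (
            multigammaln((model.nu + I) / 2.0, P)
            - multigammaln(model.nu / 2.0, P)
            - 0.5 * I * P * np.log(np.pi)
            - 0.5 * (model.nu + I) * logdet
        )

        prior_mu = -0.5 * (mu**2).sum(axis=1) - 0.5 * P * _LOG_2PI
        prior_xi = -0.5 * (xi_trans**2).sum(axis=1) - 0.5 * P * _LOG_2PI
        prior_delta = np.zeros(D)
        if F:
            sd = model.sigma_delta
            prior_delta = (
                -0.5 * (delta**2).sum(axis=1) / sd**2
                - F * (0.5 * _LOG_2PI + np.log(sd))
            )
        out = loglik + group + prior_mu + prior_xi + prior_delta
        out = np.where(np.isnan(out), -np.inf, out)
        return out[0] if squeeze else out


def make_log_posterior(model: LatentTraitModel, data: CountTable) -> _Evaluator:
    """Build a callable evaluating the unnormalized log posterior.

    The returned object accepts a single psi vector of length ``model.dim``
    or a ``(D, dim)`` batch, and returns the log of the Q-marginalized
    unnormalized posterior density (likelihood including multinomial
    coefficients, group factor, and all priors).  Impossible data yields
    ``-inf``, never NaN.
    """
    return _Evaluator(model, data)


def log_unnormalized_posterior(
    state: ParameterState, data: CountTable, model: LatentTraitModel
) -> float:
    """Unnormalized log posterior density at one parameter state."""
    return float(make_log_posterior(model, data)(model.pack(state)))
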