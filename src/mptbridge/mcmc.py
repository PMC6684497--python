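"""Posterior sampling and MCMC diagnostics.

The sampler is a blocked adaptive random-walk Metropolis algorithm targeting
the Q-marginalized unnormalized posterior directly: one joint block for the
group-level coordinates (mu, xi_trans, delta) and one block per participant
for the unscaled random effects omega_i.  Proposal scales adapt toward a 0.23
acceptance rate during burn-in and are frozen afterwards, so retained draws
form a Markov chain with the correct stationary distribution.

Diagnostics follow the usual MCMC conventions: the potential scale reduction
factor R-hat across chains, and an effective sample size based on the
spectral density at frequency zero estimated by AIC-selected autoregressive
fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr as _ndtr

from .latent_trait import CountTable, LatentTraitModel, make_log_posterior

__all__ = [
    "ChainSet",
    "sample_posterior",
    "sample_generic",
    "update_Q",
    "rhat",
    "effective_sample_size",
    "split_halves",
]


@dataclass
class ChainSet:
    """Posterior draws organized chain x iteration x dimension."""

    draws: np.ndarray
    labels: list[str]
    seed: int | None = None
    acceptance: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, dimensions)")
        if len(self.labels) != self.draws.shape[2]:
            raise ValueError("label count must equal dimension")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    @property
    def dim(self) -> int:
        return self.draws.shape[2]

    def flat(self) -> np.ndarray:
        """All draws pooled across chains, shape (chains*iterations, dim)."""
        return self.draws.reshape(-1, self.dim)

    # -------------------------------------------------------------- export
    def save(self, prefix) -> None:
        """Write draws to ``<prefix>.csv`` and metadata to ``<prefix>.meta.json``."""
        prefix = str(prefix)
        n_ch, n_it, _ = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.labels)
        df.insert(0, "iteration", np.tile(np.arange(1, n_it + 1), n_ch))
        df.insert(0, "chain", np.repeat(np.arange(1, n_ch + 1), n_it))
        df.to_csv(prefix + ".csv", index=False)
        meta = {
            "seed": self.seed,
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
            "settings": self.settings,
            "labels": self.labels,
        }
        with open(prefix + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, prefix) -> "ChainSet":
        prefix = str(prefix)
        df = pd.read_csv(prefix + ".csv")
        with open(prefix + ".meta.json") as fh:
            meta = json.load(fh)
        labels = meta["labels"]
        chains = sorted(df["chain"].unique())
        draws = np.stack(
            [df[df["chain"] == c][labels].to_numpy() for c in chains], axis=0
        )
        return cls(
            draws=draws,
            labels=labels,
            seed=meta.get("seed"),
            acceptance=meta.get("acceptance", {}),
            settings=meta.get("settings", {}),
        )


# ---------------------------------------------------------------------------
# Core sampler
# ---------------------------------------------------------------------------


def _scalar(value) -> float:
    """Accept scalar- or batch-style log-density return values."""
    return float(np.asarray(value).reshape(-1)[0])


def _run_chain(
    logpost,
    x0: np.ndarray,
    blocks: list[np.ndarray],
    n_iter: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    target_accept: float = 0.23,
    adapt_window: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x0, dtype=float).copy()
    lp = _scalar(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("log posterior is non-finite at the initial point")
    d = x.size
    scales = np.array([2.38 / np.sqrt(len(b)) * 0.3 for b in blocks])
    accepted = np.zeros(len(blocks))
    proposed = np.zeros(len(blocks))
    win_acc = np.zeros(len(blocks))
    win_prop = np.zeros(len(blocks))

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, d))
    kept = 0
    for t in range(n_iter):
        for b, idx in enumerate(blocks):
            prop = x.copy()
            prop[idx] = x[idx] + scales[b] * rng.standard_normal(len(idx))
            lp_prop = _scalar(logpost(prop))
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted[b] += 1
                win_acc[b] += 1
            proposed[b] += 1
            win_prop[b] += 1
        if t < burn_in and (t + 1) % adapt_window == 0:
            rate = win_acc / np.maximum(win_prop, 1)
            scales *= np.exp(np.clip(rate - target_accept, -0.5, 0.5))
            win_acc[:] = 0
            win_prop[:] = 0
        if t >= burn_in and (t - burn_in) % thin == 0 and kept < n_keep:
            out[kept] = x
            kept += 1
    return out[:kept], accepted / np.maximum(proposed, 1)


def sample_generic(
    logpost,
    dim: int,
    n_chains: int = 2,
    n_iter: int = 4000,
    burn_in: int = 1000,
    thin: int = 1,
    seed: int = 0,
    init: np.ndarray | None = None,
    init_sd: float = 1.0,
    labels: list[str] | None = None,
    blocks: list[np.ndarray] | None = None,
) -> ChainSet:
    """Blocked adaptive random-walk Metropolis for an arbitrary log density.

    ``logpost`` takes one vector of length ``dim``.  Chains start from
    overdispersed draws ``init + N(0, init_sd^2)`` and are reproducible for a
    given seed.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if (n_iter - burn_in) // thin < 1:
        raise ValueError("no retained iterations with these settings")
    rng = np.random.default_rng(seed)
    if blocks is None:
        blocks = [np.arange(dim)]
    base = np.zeros(dim) if init is None else np.asarray(init, dtype=float)
    chains, rates = [], []
    for c in range(n_chains):
        for attempt in range(100):
            x0 = base + init_sd * rng.standard_normal(dim)
            if np.isfinite(_scalar(logpost(x0))):
                break
        else:
            raise ValueError("could not find a finite-density starting point")
        draws, rate = _run_chain(logpost, x0, blocks, n_iter, burn_in, thin, rng)
        chains.append(draws)
        rates.append(rate)
    draws = np.stack(chains, axis=0)
    acc = {f"block_{b}": float(np.mean([r[b] for r in rates])) for b in range(len(blocks))}
    return ChainSet(
        draws=draws,
        labels=labels or [f"x[{j}]" for j in range(dim)],
        seed=seed,
        acceptance=acc,
        settings={
            "n_chains": n_chains,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
        },
    )


def _run_latent_trait_chain(
    ev,
    model: LatentTraitModel,
    x0: np.ndarray,
    n_iter: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    target_accept: float = 0.23,
    adapt_window: int = 50,
) -> tuple[np.ndarray, dict]:
    """One parameter-expanded chain: Gibbs on Q, Metropolis on the rest.

    Each sweep draws the unscaled covariance Q from its inverse Wishart full
    conditional, updates the group-level block (mu, xi_trans, delta) by a
    joint random walk against the Q-marginalized target, and updates all
    omega_i blocks simultaneously against their conditionally independent
    targets given Q.  Q is discarded before returning: the retained psi
    margins coincide with the Q-marginalized posterior.
    """
    P, F, I = model.P, model.n_free_delta, model.I
    nu = model.nu
    head_dim = 2 * P + F
    x = np.asarray(x0, dtype=float).copy()
    mu, xi_trans = x[:P].copy(), x[P : 2 * P].copy()
    delta = x[2 * P : head_dim].copy()
    omega = x[head_dim:].reshape(I, P).copy()

    sd = model.sigma_delta

    def head_logprior(mu_, xit_, delta_):
        v = -0.5 * (mu_**2).sum() - 0.5 * (xit_**2).sum()
        if F:
            v -= 0.5 * (delta_**2).sum() / sd**2
        return v

    ll_i = ev.loglik_by_participant(mu, xi_trans, delta, omega)
    if not np.all(np.isfinite(ll_i)):
        raise ValueError("log posterior is non-finite at the initial point")

    head_scale = 2.38 / np.sqrt(head_dim) * 0.3
    omega_scales = np.full(I, 2.38 / np.sqrt(P) * 0.3)
    trans_scale = 2.38 / np.sqrt(P) * 0.3
    head_acc = head_prop = 0.0
    omega_acc = np.zeros(I)
    omega_prop = 0.0
    trans_acc = trans_prop = 0.0
    win_head = [0.0, 0.0]
    win_omega = [np.zeros(I), 0.0]
    win_trans = [0.0, 0.0]

    n_keep = (n_iter - burn_in) // thin
    out = np.empty((n_keep, model.dim))
    kept = 0
    for t in range(n_iter):
        # --- Gibbs: Q | Omega ~ InvWishart(nu + I, Omega' Omega + I_P)
        Q = update_Q(omega, nu, rng)
        L = np.linalg.cholesky(Q)

        def omega_logprior(om):
            y = np.linalg.solve(L, om.T)  # (P, I)
            return -0.5 * (y**2).sum(axis=0)

        # --- group-level block (mu, xi_trans, delta)
        eps = head_scale * rng.standard_normal(head_dim)
        mu_p = mu + eps[:P]
        xit_p = xi_trans + eps[P : 2 * P]
        delta_p = delta + eps[2 * P :]
        ll_p = ev.loglik_by_participant(mu_p, xit_p, delta_p, omega)
        lr = ll_p.sum() - ll_i.sum() + head_logprior(mu_p, xit_p, delta_p) - head_logprior(mu, xi_trans, delta)
        head_prop += 1
        win_head[1] += 1
        if np.log(rng.uniform()) < lr:
            mu, xi_trans, delta, ll_i = mu_p, xit_p, delta_p, ll_p
            head_acc += 1
            win_head[0] += 1

        # --- all omega_i blocks, conditionally independent given Q
        om_p = omega + omega_scales[:, None] * rng.standard_normal((I, P))
        ll_om = ev.loglik_by_participant(mu, xi_trans, delta, om_p)
        lr_i = ll_om - ll_i + omega_logprior(om_p) - omega_logprior(omega)
        accept = np.log(rng.uniform(size=I)) < lr_i
        omega[accept] = om_p[accept]
        ll_i = np.where(accept, ll_om, ll_i)
        omega_acc += accept
        omega_prop += 1
        win_omega[0] += accept
        win_omega[1] += 1

        # --- translation move along the weakly identified mu/omega ridge:
        # mu -> mu + eps, omega_i -> omega_i - eps/xi leaves every theta_i
        # (hence the likelihood) unchanged; accept on the prior ratio alone.
        xi = model.xi_max * _ndtr(xi_trans)
        eps = trans_scale * rng.standard_normal(P)
        mu_t = mu + eps
        om_t = omega - eps / xi
        lr = (
            -0.5 * (mu_t**2).sum()
            + 0.5 * (mu**2).sum()
            + omega_logprior(om_t).sum()
            - omega_logprior(omega).sum()
        )
        trans_prop += 1
        win_trans[1] += 1
        if np.log(rng.uniform()) < lr:
            mu, omega = mu_t, om_t
            trans_acc += 1
            win_trans[0] += 1

        if t < burn_in and (t + 1) % adapt_window == 0:
            head_scale *= np.exp(np.clip(win_head[0] / win_head[1] - target_accept, -0.5, 0.5))
            omega_scales *= np.exp(
                np.clip(win_omega[0] / win_omega[1] - target_accept, -0.5, 0.5)
            )
            trans_scale *= np.exp(
                np.clip(win_trans[0] / win_trans[1] - target_accept, -0.5, 0.5)
            )
            win_head = [0.0, 0.0]
            win_omega = [np.zeros(I), 0.0]
            win_trans = [0.0, 0.0]

        if t >= burn_in and (t - burn_in) % thin == 0 and kept < n_keep:
            out[kept, :P] = mu
            out[kept, P : 2 * P] = xi_trans
            out[kept, 2 * P : head_dim] = delta
            out[kept, head_dim:] = omega.ravel()
            kept += 1
    rates = {
        "group_block": head_acc / max(head_prop, 1),
        "omega_blocks": float(omega_acc.mean() / max(omega_prop, 1)),
        "translation": trans_acc / max(trans_prop, 1),
    }
    return out[:kept], rates


def sample_posterior(
    model: LatentTraitModel,
    data: CountTable,
    n_chains: int = 3,
    n_iter: int = 8000,
    burn_in: int = 4000,
    thin: int = 1,
    seed: int = 0,
    init_sd: float = 0.5,
) -> ChainSet:
    """Draw posterior samples of psi = (mu, xi_trans, delta, omega_1..omega_I).

    Uses the parameter-expanded scheme: a conjugate Gibbs draw of the
    unscaled covariance Q each sweep, a joint random-walk block for the
    group-level coordinates, and simultaneous conditionally independent
    random-walk updates of the per-participant random effects.  Q is used
    only for mixing and discarded before the draws are returned, so the
    retained margins target the Q-marginalized posterior that the bridge
    estimator evaluates.  Defaults follow common practice for these models:
    3 chains with overdispersed start values and a 4000-iteration burn-in.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if (n_iter - burn_in) // thin < 1:
        raise ValueError("no retained iterations with these settings")
    ev = make_log_posterior(model, data)
    P, F, I = model.P, model.n_free_delta, model.I
    head_dim = 2 * P + F
    rng = np.random.default_rng(seed)
    chains, rate_list = [], []
    for c in range(n_chains):
        for attempt in range(100):
            x0 = np.zeros(model.dim)
            x0[:head_dim] = init_sd * rng.standard_normal(head_dim)
            x0[head_dim:] = 0.1 * rng.standard_normal(P * I)
            if np.isfinite(ev(x0)):
                break
        else:
            raise ValueError("could not find a finite-density starting point")
        draws, rates = _run_latent_trait_chain(
            ev, model, x0, n_iter, burn_in, thin, rng
        )
        chains.append(draws)
        rate_list.append(rates)
    draws = np.stack(chains, axis=0)
    acc = {
        k: float(np.mean([r[k] for r in rate_list])) for k in rate_list[0]
    }
    return ChainSet(
        draws=draws,
        labels=model.labels(),
        seed=seed,
        acceptance=acc,
        settings={
            "n_chains": n_chains,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
        },
    )


def update_Q(Omega, nu: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the unscaled covariance Q from its conjugate full conditional.

    Given the random-effect matrix Omega (I x P) and an InvWishart(nu, I_P)
    prior, the full conditional is InvWishart(nu + I, Omega' Omega + I_P).
    The draw is not needed by the Q-marginalized sampler or the bridge
    estimator; it is provided for parameter-expanded samplers and posterior
    summaries of the group covariance.
    """
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    if not np.all(np.isfinite(Omega)):
        raise ValueError("Omega must be finite")
    I, P = Omega.shape
    scale = Omega.T @ Omega + np.eye(P)
    assert np.all(np.linalg.eigvalsh(scale) > 0)
    return stats.invwishart.rvs(df=nu + I, scale=scale, random_state=rng).reshape(P, P)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _as_draws(chains) -> np.ndarray:
    if isinstance(chains, ChainSet):
        return chains.draws
    a = np.asarray(chains, dtype=float)
    if a.ndim == 2:
        a = a[None]
    return a


def rhat(chains) -> np.ndarray:
    """Potential scale reduction factor per dimension (Gelman--Rubin).

    Requires at least two chains; values near 1 indicate that the chains have
    mixed.  The usual convergence check requires R-hat < 1.05 for all
    parameters.
    """
    draws = _as_draws(chains)
    m, n, d = draws.shape
    if m < 2:
        raise ValueError("rhat requires at least 2 chains")
    if n < 4:
        raise ValueError("rhat requires at least 4 iterations")
    means = draws.mean(axis=1)  # (m, d)
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    if np.any(W == 0):
        if np.all(B_over_n[W == 0] == 0):
            raise ValueError("zero within-chain variance in all chains")
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return out


def rhat_flags(chains, threshold: float = 1.05) -> np.ndarray:
    """Boolean mask of dimensions whose R-hat is at or above ``threshold``."""
    return rhat(chains) >= threshold


def _spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = x.size
    v = x.var(ddof=1)
    if v == 0:
        raise ValueError("constant chain")
    xc = x - x.mean()
    if max_order is None:
        max_order = int(min(n - 1, 10 * np.log10(n)))
    # autocovariances up to max_order
    acov = np.array(
        [xc[: n - k] @ xc[k:] / n for k in range(max_order + 1)]
    )
    best_aic, best = np.inf, (0, acov[0])
    for p in range(0, max_order + 1):
        if p == 0:
            sigma2 = acov[0]
            phi_sum = 0.0
        else:
            R = np.empty((p, p))
            for i in range(p):
                for j in range(p):
                    R[i, j] = acov[abs(i - j)]
            try:
                phi = np.linalg.solve(R, acov[1 : p + 1])
            except np.linalg.LinAlgError:
                continue
            sigma2 = acov[0] - phi @ acov[1 : p + 1]
            if sigma2 <= 0:
                continue
            phi_sum = phi.sum()
        aic = n * np.log(max(sigma2, 1e-300)) + 2 * p
        if aic < best_aic:
            best_aic = aic
            best = (phi_sum, sigma2)
    phi_sum, sigma2 = best
    denom = (1.0 - phi_sum) ** 2
    if denom <= 0:
        denom = 1e-10
    return float(sigma2 / denom)


def effective_sample_size(chains) -> np.ndarray:
    """Effective sample size per dimension.

    Uses the spectral-density-at-zero estimator: ESS = n * var(x) /
    spectrum0(x), with the spectrum estimated by an AIC-selected
    autoregressive fit per chain; per-chain values are summed over chains.
    """
    draws = _as_draws(chains)
    m, n, d = draws.shape
    if m * n < 100:
        raise ValueError("effective_sample_size requires >= 100 retained draws")
    ess = np.zeros(d)
    for j in range(d):
        for c in range(m):
            x = draws[c, :, j]
            s0 = _spectrum0_ar(x)
            ess[j] += n * x.var(ddof=1) / s0
    return ess


def split_halves(chains: ChainSet) -> tuple[ChainSet, ChainSet]:
    """Split each chain into its first and second half of iterations.

    The first half is used for estimating the warp moments, the second for
    the iterative bridge updating scheme; the two halves are disjoint and
    jointly exhaustive.  An odd iteration count drops the first iteration
    with a warning.
    """
    draws = chains.draws
    n = draws.shape[1]
    if n % 2 == 1:
        import warnings

        warnings.warn("odd iteration count; dropping the first iteration")
        draws = draws[:, 1:]
        n -= 1
    half = n // 2
    mk = lambda d: ChainSet(
        draws=d,
        labels=chains.labels,
        seed=chains.seed,
        acceptance=chains.acceptance,
        settings=chains.settings,
    )
    return mk(draws[:, :half].copy()), mk(draws[:, half:].copy())
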