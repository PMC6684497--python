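"""Bayes factors, posterior model probabilities, and model averaging.

Given log marginal likelihoods for a set of candidate models, this module
computes posterior model probabilities (Bayes' rule over the model set),
pairwise Bayes factors, and — for families of nested models defined by
which between-condition difference parameters are free — model-averaged
inclusion probabilities.  A Savage--Dickey density-ratio estimator provides
an independent cross-check for nested comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gaussian_kde, norm

from .latent_trait import LatentTraitModel

__all__ = [
    "ModelSet",
    "enumerate_nested_models",
    "posterior_model_probabilities",
    "bayes_factor",
    "inclusion_probability",
    "savage_dickey",
    "savage_dickey_joint",
]


@dataclass
class ModelSet:
    """A discrete set of candidate models with prior probabilities.

    ``membership[p]`` is the boolean mask, over models, of those in which the
    difference parameter ``delta_p`` is free.
    """

    labels: list[str]
    models: list[LatentTraitModel]
    prior_probs: np.ndarray
    membership: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.prior_probs = np.asarray(self.prior_probs, dtype=float)
        if np.any(self.prior_probs < 0) or abs(self.prior_probs.sum() - 1) > 1e-12:
            raise ValueError("prior model probabilities must be >= 0 and sum to 1")
        if len(self.labels) != len(self.models) or len(self.labels) != self.prior_probs.size:
            raise ValueError("labels, models, and priors must have equal length")

    def __len__(self) -> int:
        return len(self.models)

    def prior_inclusion(self, parameter: str) -> float:
        """Prior inclusion probability of one difference parameter."""
        return inclusion_probability(self.prior_probs, self.membership[parameter])


def enumerate_nested_models(
    base: LatentTraitModel,
    candidate_deltas: tuple[str, ...],
    prior_probs=None,
) -> ModelSet:
    """All 2^n nested models from freeing/fixing each candidate delta.

    The first model frees every candidate (the full model); the last fixes
    all of them at zero (the null model).  Prior model probabilities default
    to uniform, which makes every parameter's prior inclusion probability
    exactly 0.5.
    """
    candidate_deltas = tuple(candidate_deltas)
    if not candidate_deltas:
        raise ValueError("candidate set must be non-empty")
    if len(set(candidate_deltas)) != len(candidate_deltas):
        raise ValueError("duplicate parameter names in candidate set")
    from itertools import combinations

    n = len(candidate_deltas)
    subsets = [
        sub
        for size in range(n, -1, -1)
        for sub in combinations(candidate_deltas, size)
    ]
    models, labels = [], []
    for sub in subsets:
        models.append(replace(base, free_delta=sub))
        labels.append("-".join(sub) if sub else "none")
    M = len(models)
    if prior_probs is None:
        prior_probs = np.full(M, 1.0 / M)
    membership = {
        p: np.array([p in m.free_delta for m in models]) for p in candidate_deltas
    }
    return ModelSet(
        labels=labels, models=models, prior_probs=np.asarray(prior_probs), membership=membership
    )


def posterior_model_probabilities(log_mls, priors=None) -> np.ndarray:
    """Posterior model probabilities from log marginal likelihoods.

    A numerically stable softmax of ``log_ml + log prior``; invariant to
    shifting all log marginal likelihoods by a constant.
    """
    log_mls = np.asarray(log_mls, dtype=float)
    if priors is None:
        priors = np.full(log_mls.size, 1.0 / log_mls.size)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != log_mls.shape:
        raise ValueError("log_mls and priors must have equal length")
    with np.errstate(divide="ignore"):
        logw = log_mls + np.log(priors)
    if not np.any(np.isfinite(logw)):
        raise ValueError("all models have zero posterior weight")
    return np.exp(logw - logsumexp(logw))


def bayes_factor(log_ml_1: float, log_ml_2: float) -> float:
    """Log Bayes factor of model 1 over model 2: log_ml_1 - log_ml_2."""
    if not (np.isfinite(log_ml_1) and np.isfinite(log_ml_2)):
        raise ValueError("log marginal likelihoods must be finite")
    return float(log_ml_1 - log_ml_2)


def format_bayes_factor(log_bf: float) -> str:
    """Human-readable Bayes factor as m x 10^e, overflow-safe."""
    log10_bf = log_bf / np.log(10.0)
    e = int(np.floor(log10_bf))
    m = 10.0 ** (log10_bf - e)
    return f"{m:.1f}e{e:+d}"


def inclusion_probability(model_probs, member_mask) -> float:
    """Model-averaged probability that a parameter difference is nonzero.

    Sums the model probabilities of the models in which the parameter is
    free; applied to prior probabilities it gives the prior inclusion
    probability.
    """
    model_probs = np.asarray(model_probs, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    if member_mask.shape != model_probs.shape:
        raise ValueError("mask length must match number of models")
    return float(model_probs[member_mask].sum())


def savage_dickey(delta_draws, sigma_delta: float) -> float:
    """Savage--Dickey log Bayes factor for delta = 0 (restricted over free).

    The posterior density of one difference parameter at zero is estimated
    with a Gaussian kernel density (Silverman bandwidth) and divided by the
    N(0, sigma_delta^2) prior density at zero.  This is an approximate
    cross-check, applicable only to nested comparisons.
    """
    delta_draws = np.asarray(delta_draws, dtype=float).ravel()
    if delta_draws.size < 1000:
        raise ValueError("savage_dickey requires at least 1000 draws")
    if np.var(delta_draws) == 0:
        raise ValueError("degenerate draws")
    post_at_zero = float(gaussian_kde(delta_draws)(0.0)[0])
    prior_at_zero = float(norm.pdf(0.0, scale=sigma_delta))
    with np.errstate(divide="ignore"):
        return float(np.log(post_at_zero) - np.log(prior_at_zero))


def savage_dickey_joint(delta_draws_matrix, sigma_delta: float) -> float:
    """Joint Savage--Dickey log BF for a subset of deltas all equal to zero.

    ``delta_draws_matrix`` is (n_draws, n_restricted): the posterior draws,
    under the full model, of the difference parameters that the restricted
    model fixes at zero.  Uses a multivariate Gaussian kernel density at the
    origin over an independent normal prior at the origin.
    """
    X = np.atleast_2d(np.asarray(delta_draws_matrix, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    n, q = X.shape
    if n < 1000:
        raise ValueError("savage_dickey_joint requires at least 1000 draws")
    post_at_zero = float(gaussian_kde(X.T)(np.zeros((q, 1)))[0])
    prior_at_zero = q * float(norm.logpdf(0.0, scale=sigma_delta))
    with np.errstate(divide="ignore"):
        return float(np.log(post_at_zero) - prior_at_zero)
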