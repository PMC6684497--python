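"""Synthetic latent-trait MPT data with known ground truth.

The generator follows the model's own generative chain: unscaled random
effects omega_i are drawn from a multivariate normal with a chosen
correlation matrix, combined with the group means mu, scaling parameters xi,
and optional condition differences delta on the probit scale, mapped through
the standard normal CDF to participant-level probabilities theta_i, and the
counts are drawn from the product-multinomial.

Two fixtures mirror well-known study designs:

* :func:`pair_clustering_fixture` — a pair-clustering memory model
  (cluster storage c, cluster retrieval r, storage-retrieval u, with the
  singleton parameter constrained a = u), measured on two study-test trials
  with 21 participants and 20 word pairs.
* :func:`truth_effect_fixture` — two non-nested five-parameter models of the
  illusory truth effect (knowledge-conditional vs fluency-conditional),
  eight subtrees each, 39 participants and 22 statements per design cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .latent_trait import LatentTraitModel
from .mpt import CountTable, MptModelSpec, parse_eqn

__all__ = [
    "GroundTruth",
    "generate_dataset",
    "pair_clustering_fixture",
    "truth_effect_fixture",
    "PAIR_CLUSTERING_EQN",
]


@dataclass
class GroundTruth:
    """The generating parameter values behind a synthetic count table."""

    mu: np.ndarray
    xi: np.ndarray
    Q_corr: np.ndarray
    delta: np.ndarray
    omega: np.ndarray
    theta: np.ndarray  # (I, n_conditions, P) probability-scale parameters
    seed: int

    @property
    def Sigma(self) -> np.ndarray:
        """Group covariance Diag(xi) Q_corr Diag(xi)."""
        D = np.diag(self.xi)
        return D @ self.Q_corr @ D

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "xi": self.xi.tolist(),
            "Q_corr": self.Q_corr.tolist(),
            "delta": self.delta.tolist(),
            "omega": self.omega.tolist(),
            "theta": self.theta.tolist(),
            "seed": self.seed,
        }


def generate_dataset(
    model: LatentTraitModel,
    mu,
    xi,
    I: int | None = None,
    J=None,
    Q_corr=None,
    delta=None,
    seed: int = 0,
) -> tuple[CountTable, GroundTruth]:
    """Simulate a count table from the latent-trait generative model.

    Parameters
    ----------
    model : LatentTraitModel
        Defines the tree, the number of conditions, and which deltas are free.
    mu, xi : array-like, length P
        Probit-scale group means and random-effect scales.
    I : int
        Number of participants (defaults to ``model.I``).
    J : array-like, length K
        Items per subtree (defaults to 20 per subtree).
    Q_corr : (P, P) array, optional
        Correlation matrix of the unscaled random effects (identity default).
    delta : array-like over ``model.free_delta``, optional
        Probit-scale condition differences for the free parameters.
    """
    spec = model.spec
    P, K = spec.P, spec.K
    I = model.I if I is None else int(I)
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if mu.shape != (P,) or xi.shape != (P,):
        raise ValueError(f"mu and xi must have length P={P}")
    J = np.full(K, 20, dtype=int) if J is None else np.asarray(J, dtype=int)
    if np.any(J < 1):
        raise ValueError("J_k must be >= 1 for every subtree")
    Q_corr = np.eye(P) if Q_corr is None else np.asarray(Q_corr, dtype=float)
    if np.any(np.linalg.eigvalsh(Q_corr) <= 0):
        raise ValueError("correlation matrix must be positive definite")
    F = model.n_free_delta
    delta = np.zeros(F) if delta is None else np.asarray(delta, dtype=float)
    if delta.shape != (F,):
        raise ValueError(f"delta must have length {F} (one per free delta)")

    rng = np.random.default_rng(seed)
    omega = rng.multivariate_normal(np.zeros(P), Q_corr, size=I)
    delta_emb = np.zeros(P)
    if F:
        delta_emb[model.delta_mask] = delta
    C = model.n_conditions
    theta = np.empty((I, C, P))
    for c in range(C):
        tprime = mu + model.condition_signs[c] * delta_emb + xi * omega
        theta[:, c, :] = ndtr(tprime)

    V, W, offsets, cat_offsets = spec.flat_structure()
    counts = np.zeros((I, C, spec.n_categories), dtype=np.int64)
    for i in range(I):
        for c in range(C):
            lt = np.log(np.clip(theta[i, c], 1e-300, 1.0))
            l1t = np.log(np.clip(1.0 - theta[i, c], 1e-300, 1.0))
            branch_p = np.exp(V @ lt + W @ l1t)
            cat_p = np.add.reduceat(branch_p, offsets)
            for k in range(K):
                sl = slice(cat_offsets[k], cat_offsets[k + 1])
                p = cat_p[sl]
                counts[i, c, sl] = rng.multinomial(J[k], p / p.sum())

    table = CountTable.from_spec(spec, counts, J)
    truth = GroundTruth(
        mu=mu, xi=xi, Q_corr=Q_corr, delta=delta, omega=omega, theta=theta, seed=seed
    )
    return table, truth


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

PAIR_CLUSTERING_EQN = """\
# pair-clustering model: word pairs (subtree 1) and singletons (subtree 2)
1 1 c*r
1 2 (1-c)*u*u
1 3 (1-c)*u*(1-u)
1 3 (1-c)*(1-u)*u
1 4 c*(1-r)
1 4 (1-c)*(1-u)*(1-u)
2 5 a
2 6 (1-a)
"""


def pair_clustering_fixture(
    I: int = 21,
    J_pairs: int = 20,
    J_singletons: int = 10,
    sigma_delta: float | str = "medium",
) -> tuple[MptModelSpec, LatentTraitModel, dict]:
    """Pair-clustering model with the a = u constraint, two-trial design.

    Returns the constrained spec (P = 3 free parameters: c, r, u), a
    latent-trait model with all three condition differences free, and a
    dictionary of default generating values.  The pairs subtree has 20 items
    per trial; the number of singleton items is configuration (default 10).
    """
    spec = parse_eqn(PAIR_CLUSTERING_EQN, name="pair_clustering").apply_constraints(
        {"a": "u"}
    )
    model = LatentTraitModel(
        spec=spec,
        I=I,
        n_conditions=2,
        free_delta=tuple(spec.parameters),
        sigma_delta=sigma_delta,
    )
    defaults = {
        "mu": np.array([0.0, -0.3, -0.5]),  # c ~ .5, r ~ .38, u ~ .31
        "xi": np.array([0.6, 0.6, 0.5]),
        "delta": np.array([0.0, 0.8, 0.4]),  # r and u improve across trials
        "J": np.array([J_pairs, J_singletons]),
    }
    return spec, model, defaults


def _truth_effect_eqn(conditional_on: str) -> str:
    """EQN text for the truth-effect models, eight subtrees.

    Replicates the true/false statement subtrees across the four design
    cells: (1) known not-repeated, (2) known repeated, (3) unknown
    not-repeated, (4) unknown repeated.  Knowledge parameters k_k / k_u vary
    with assumed knowledge, fluency parameters f_r / f_n with repetition, and
    the guessing parameter g is shared.

    ``conditional_on`` selects the processing order: ``"knowledge"`` checks
    knowledge first and falls back on fluency, ``"fluency"`` the reverse.
    """
    lines = []
    cells = [("k_k", "f_n"), ("k_k", "f_r"), ("k_u", "f_n"), ("k_u", "f_r")]
    for rep, (k, f) in enumerate(cells, start=1):
        t_true, t_false = f"true{rep}", f"false{rep}"
        if conditional_on == "knowledge":
            # knowledge -> correct; else fluency -> "true"; else guess
            lines += [
                f"{t_true} {t_true}.T {k}",
                f"{t_true} {t_true}.T (1-{k})*{f}",
                f"{t_true} {t_true}.T (1-{k})*(1-{f})*g",
                f"{t_true} {t_true}.F (1-{k})*(1-{f})*(1-g)",
                f"{t_false} {t_false}.T (1-{k})*{f}",
                f"{t_false} {t_false}.T (1-{k})*(1-{f})*g",
                f"{t_false} {t_false}.F {k}",
                f"{t_false} {t_false}.F (1-{k})*(1-{f})*(1-g)",
            ]
        elif conditional_on == "fluency":
            # fluency -> "true"; else knowledge -> correct; else guess
            lines += [
                f"{t_true} {t_true}.T {f}",
                f"{t_true} {t_true}.T (1-{f})*{k}",
                f"{t_true} {t_true}.T (1-{f})*(1-{k})*g",
                f"{t_true} {t_true}.F (1-{f})*(1-{k})*(1-g)",
                f"{t_false} {t_false}.T {f}",
                f"{t_false} {t_false}.T (1-{f})*(1-{k})*g",
                f"{t_false} {t_false}.F (1-{f})*{k}",
                f"{t_false} {t_false}.F (1-{f})*(1-{k})*(1-g)",
            ]
        else:
            raise ValueError("conditional_on must be 'knowledge' or 'fluency'")
    return "\n".join(lines) + "\n"


def truth_effect_fixture(
    I: int = 39, J_cell: int = 22
) -> tuple[MptModelSpec, MptModelSpec, LatentTraitModel, dict]:
    """The two non-nested truth-effect models and shared defaults.

    Returns the knowledge-conditional spec, the fluency-conditional spec, a
    one-condition latent-trait model built on the knowledge-conditional spec
    (both models share P = 5 parameters: k_k, k_u, f_r, f_n, g), and default
    generating values.  Each of the eight subtrees holds 22 statements.
    """
    order = ["k_k", "k_u", "f_r", "f_n", "g"]
    kc = parse_eqn(_truth_effect_eqn("knowledge"), name="knowledge_conditional")
    fc = parse_eqn(_truth_effect_eqn("fluency"), name="fluency_conditional")
    kc = kc.with_parameter_order(order)
    fc = fc.with_parameter_order(order)
    model = LatentTraitModel(spec=kc, I=I, n_conditions=1)
    defaults = {
        "mu": np.array([0.8, -0.8, 0.3, -0.5, 0.0]),  # k_k, k_u, f_r, f_n, g
        "xi": np.array([0.6, 0.6, 0.5, 0.5, 0.4]),
        "J": np.full(kc.K, J_cell),
    }
    return kc, fc, model, defaults
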