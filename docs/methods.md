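# Methods

`mptbridge` computes Bayes factors, posterior model probabilities (PMPs), and
model-averaged inclusion probabilities for hierarchical multinomial
processing tree (MPT) models by estimating each model's log marginal
likelihood with warp bridge sampling. This note documents the model, the
estimators, the numerical choices, and what the synthetic study designs do
and do not establish.

## The latent-trait hierarchical MPT

An MPT reparametrizes the category probabilities of `K` independent
multinomials ("subtrees", one per category system, with `J_k` items each) as
sums of branch probabilities; each branch probability is a product of latent
process probabilities `theta_p` and complements `1 - theta_p`. Branch lists
are read from EQN-style text (one `tree category product` line per branch),
the de-facto community format. Equality constraints such as `a = u` are
applied structurally, so constrained parameters contribute no dimensions.

Participant heterogeneity follows the latent-trait approach: the
probit-transformed participant parameter vectors are multivariate normal,

    theta'_i = mu + xi (.) omega_i,      omega_i ~ N_P(0, Q),

with a scaled inverse Wishart prior on the group covariance
`Sigma = Diag(xi) Q Diag(xi)`:

* `mu_p ~ N(0, 1)` — uniform on the probability scale for the group means;
* `Q ~ InvWishart(nu = P + 1, I_P)` — uniform priors on correlations;
* `xi_p ~ Uniform(0, xi_max)` with `xi_max = 10` by default — a diffuse
  prior on the random-effect scales (a sensitivity alternative is
  `xi_max = 2`; both are one keyword away).

Only `mu`, `Sigma`, and `theta'_i` are interpretable; `xi`, `Q`, and
`omega_i` are a parameter expansion and are identified only jointly. This
matters operationally (see "Mixing" and "Warp ladder" below).

Two-condition designs (e.g. study-test trials) add a difference vector:
condition means are `mu -/+ delta/2`, with `omega_i` shared across
conditions and independent `N(0, sigma_delta^2)` priors on the free
components of `delta`. The presets `narrow/medium/wide` set `sigma_delta`
to 0.52 / 0.84 / 1.28, corresponding to small/medium/large effects on the
probability scale around 0.5. Nested model families arise by freeing or
fixing each candidate `delta_p`, giving `2^n` models with uniform prior
model probabilities by default (so every prior inclusion probability is
exactly 0.5).

## The marginalized posterior

The unscaled covariance `Q` integrates out of the posterior in closed form,
leaving a density over `psi = (mu, xi_trans, delta, omega_1..omega_I)` of
dimension `P(I+2) + #free deltas`. The group-level factor is

    Gamma_P((nu+I)/2) / Gamma_P(nu/2) * pi^{-IP/2}
        * |Omega' Omega + I_P|^{-(nu+I)/2},

computed with the log multivariate gamma function and a log-determinant.
For `P = I = 1` this reduces to a scaled Student-t density — the identity
the unit tests assert against — and in general it is validated against
inverse Wishart Monte Carlo integration. The bounded scales are mapped to
the real line by `xi_trans = Phi^{-1}(xi / xi_max)`; the uniform prior times
the Jacobian of this map is exactly a standard normal density on
`xi_trans`, which is how the prior enters the unnormalized posterior. All
density arithmetic is in log space end to end; impossible data yields
`-inf`, never NaN. Branch products use `log Phi` directly
(`scipy.special.log_ndtr`), so extreme probit values cannot underflow.

## Posterior sampling

The sampler is written for this marginalized target and uses the parameter
expansion for mixing:

1. **Gibbs on Q**: `Q | Omega ~ InvWishart(nu + I, Omega' Omega + I_P)`
   (conjugate full conditional). Given `Q`, the `omega_i` are conditionally
   independent.
2. **Group block**: joint random-walk Metropolis on `(mu, xi_trans, delta)`.
3. **Random effects**: simultaneous random-walk updates of all `omega_i`
   blocks, accepted or rejected per participant (vectorized across `i`).
4. **Translation move**: propose `mu -> mu + eps`,
   `omega_i -> omega_i - eps / xi`. Every `theta_i` — hence the likelihood —
   is unchanged, so the acceptance ratio involves only the priors. This move
   walks along the weakly identified ridge between the group means and the
   random-effect means; without it the `mu` margins mix an order of
   magnitude more slowly.

`Q` is retained only for mixing and discarded before bridging: the stored
`psi` margins coincide with the marginalized posterior that the bridge
estimator evaluates. Proposal scales adapt toward a 0.23 acceptance rate in
windows of 50 sweeps during burn-in and are frozen afterwards, so retained
draws are a valid Markov chain. Defaults are 3 chains, overdispersed start
values, 4000 burn-in sweeps, and optional thinning; all randomness flows
from one seed and reruns are bit-identical.

Diagnostics: classic potential-scale-reduction R-hat across chains (flagging
at 1.05) and an effective sample size (ESS) from the spectral density at
frequency zero, estimated by an AIC-selected autoregressive fit per chain
and summed over chains. **Mixing caveat**: `xi_trans` and `omega` are only
jointly identified; their margins are heavy-tailed and slow. Convergence
checks should be read on the identified margins (`mu`, `delta`, and
functions like `xi (.) omega_i`); the unidentified margins routinely show
R-hat well above 1.05 at desk scale without invalidating the identified
ones. This is inherent to the parameter expansion, not a sampler defect.

## Warp bridge sampling

Bridge sampling estimates a normalizing constant from posterior draws and
proposal draws tied together by the optimal bridge function, iterated to a
fixed point. The warp family transforms the posterior to overlap a standard
normal proposal while preserving the normalizing constant:

* **warp0** — no transformation;
* **warp2** — center by the posterior mean `v` and whiten by a Cholesky
  factor `R` of the posterior covariance (equivalent to a moment-matched
  multivariate normal proposal);
* **warp3** — additionally attach a random sign, symmetrizing the warped
  posterior and matching the third moment. The warped density is a mixture,
  so each term evaluates the unnormalized posterior twice (at `psi` and at
  its mirror image `2v - psi`).

Workflow per estimate: split the retained iterations of each chain into
halves; estimate `v` and `R` from the first half; run the fixed-point
iteration on the second half (`D1` draws) against `D2 = D1` fresh standard
normal proposal draws. Because MCMC draws are autocorrelated, the weight
`s1` uses the ESS of the bridge half (median across dimensions — the
reduction is a package choice, configurable) in place of `D1`. Repetitions
re-draw the proposal sample; optionally the half-split itself can be
re-randomized (`rerandomize_split=True`). Summaries report the median and
range over repetitions; PMPs are computed from the median log marginal
likelihoods.

Numerical choices: the fixed-point iteration runs entirely in log space with
log-sum-exp (Bayes factors here can exceed 10^40, so natural-scale
iteration would overflow); the initial guess is the median of the `log l2`
terms; tolerance `1e-10` on the change of the log estimate; at most 1000
iterations, with non-convergence flagged rather than raised; both mirror
terms `-inf` propagates `-inf` for that term. Moment estimation requires
more draws than dimensions and a positive-definite sample covariance and
fails loudly otherwise.

The estimator is validated three independent ways: recovery of a known 2-D
normalizing constant (7.3) within Monte Carlo error; agreement with 3-D
adaptive quadrature on a single-participant uniform-prior toy model to
better than 0.1% of the log value; and a self-consistency check that
bridging the same model twice gives a log Bayes factor of ~0.

## Model comparison

PMPs are a max-shifted softmax of `log ML + log prior` (invariant to common
shifts, summing to one at 1e-12). Inclusion probabilities sum PMPs over the
models in which a difference parameter is free. Bayes factors are reported
in log and log10; raw ratios are formatted as `m x 10^e` only on demand.
For nested families the Savage–Dickey density ratio provides an independent
cross-check: the posterior density of the restricted `delta` subset at zero
(Gaussian kernel density, Silverman bandwidth, under the full model) over
the prior density at zero. The KDE route is approximate and used only as a
cross-check, never as the primary estimator.

## Synthetic designs

The generator draws `omega_i` from a chosen correlation matrix, forms
`theta_i` per condition, and draws product-multinomial counts — exactly the
model's own generative chain, with the full ground truth recorded. Two
fixtures mirror published study designs:

* **Pair clustering** (storage `c`, retrieval `r`, storage-retrieval `u`,
  with `a = u`): 21 participants, 20 word pairs, two study-test trials, all
  three `delta`s candidates for the 8-model nested family. The singleton
  item count is configuration (default 10). Default generating values
  (probability-scale means ~0.3–0.7, `xi` 0.5–0.6, `delta = (0, 0.8, 0.4)`
  — retrieval improves across trials, storage does not) are configuration,
  not claims about the original data.
* **Truth effect**: two non-nested five-parameter models (knowledge
  retrieval `k_k`/`k_u`, fluency reliance `f_r`/`f_n`, guessing `g`, shared
  across the four design-cell replicates; 8 subtrees; 39 participants; 22
  statements per cell) that differ only in conditional order: knowledge
  first vs fluency first. They coincide exactly when `f = 0` (no fluency
  reliance) — the structural identity the tests assert. `g` receives a full
  latent-trait random effect, a modeling choice.

What the synthetic designs do **not** emulate: item-level effects, response
times, real-data misfit (the generating model is always in the candidate
set), and full-scale chain lengths. Passing tests therefore establish
correctness of the machinery and internal consistency of the estimators at
the stated problem sizes, not conclusions about any real dataset.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so the whole battery
completes in minutes on one core: the nested cross-validation uses 15
participants, 20 pairs/10 singletons, 3 chains of 20,000 sweeps (4,000
burn-in, thin 4), and 5 bridge repetitions per model; the non-nested
comparison uses the full 39-participant design with 2 chains of 7,000
sweeps. At these sizes the bridge repetition spread is a few tenths of a
log unit — small relative to the Bayes factors involved but visible in
PMPs, which is why medians over repetitions are used. The Savage–Dickey
and Warp-III routes agree to within 0.04 in PMP at these settings and
converge to the same Bayes factors as chains lengthen.

One property is checked on independent draws rather than MCMC output: the
warp "ladder" (warped draws having mean ~0, covariance ~I, vanishing third
moments at tolerances 0.05/0.1). Sample moments of the latent-trait
posterior's unidentified `xi`/`omega` margins drift between chain halves by
more than those tolerances at any feasible desk-scale chain length, which
would measure sampler noise, not the transformation. A strongly skewed
correlated fixture distribution isolates the property the ladder is about.

## Known limitations

* Unimodal posteriors are assumed; warp bridging is not designed for
  multimodal targets.
* Two conditions at most; no item-level (crossed) random effects; no
  beta-MPT group distribution; no order constraints on parameters.
* The Savage–Dickey KDE degrades with the number of jointly restricted
  parameters; beyond ~3 it should not be trusted as a cross-check.
* The random-walk sampler is adequate at desk scale but is the bottleneck
  for large `I`; gradient-based samplers are out of scope.
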