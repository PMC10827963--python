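# Methods

This note documents the statistical machinery implemented in `dualrec`: the
measurement model, the population model behind the synthetic-data generator,
both estimation routes, the fit diagnostics, and the Bayes-factor tests —
together with the numerical choices and their rationale.

## The dual-recollection measurement model

Responses in the conjoint-recognition paradigm are yes/no decisions to three
probe questions (class 1?, class 2?, either?) crossed with item classes
(targets per feature configuration, distractors). Each (probe, item class)
pair has a processing tree whose branches are ordered success/failure factors
over four latent processes: context recollection `RC_k`, target recollection
`RT_k`, familiarity `F_k` (per target class `k`) and a response bias `b_q`
per question. The canonical factor order is RC → RT → (F) → b; only branch
products enter the likelihood, but the order is fixed so serialisation and
enumeration tests are reproducible.

Category probabilities:

| tree | P(yes) |
|---|---|
| congruent target | `RC + (1−RC)RT + (1−RC)(1−RT)b` |
| incongruent target | `(1−RC)[RT + (1−RT)b]` |
| either-question target | `RC + (1−RC)RT + (1−RC)(1−RT)F + (1−RC)(1−RT)(1−F)b` |
| distractor | `b` |

Two readings of the incongruent tree are possible: the bias could apply
unconditionally, or only after context recollection fails. This package
implements the conditional reading — successful context recollection of the
*other* context is a terminal reject — which is the normative narration of
the model; the alternative is a one-line change to `_incongruent_tree` if a
user ever needs it. Familiarity enters only either-question trees and is
indexed by target class.

**Bias sharing.** Which bias parameters are shared is a design-level choice:
the built-in defaults equate biases across font sizes in the exp1 neutral arm
(the distractors appear in a single new font), split them by font size in the
reinstated arm, equate the two colour-question biases in the exp2 neutral
arms, and use one bias per question elsewhere. Any scheme can be overridden
by passing an explicit (probe, item class) → parameter-name map.

**Identifiability.** `check_identifiability` evaluates the Jacobian of the
stacked category probabilities numerically (central differences, step 1e−6)
at five random interior points and reports its maximal rank. All preset
models are full-rank. Note that full rank does not mean the model is
saturated even when parameters equal categories: the dual-recollection map is
not surjective (e.g. a congruent target's P(yes) can never fall below the
bias), so a 9-parameter/9-category layout can still misfit data.

## Synthetic populations

Individual parameter vectors follow the latent-trait population model:
`theta_i = Phi(mu + delta_i)` with `delta_i ~ MVN(0, Sigma)` on the probit
scale (probit, not logit, to match the latent-trait MPT literature).
Responses are per-cell binomials — items within a (probe, item class) cell
are exchangeable under the model, and no item-level random effects are
simulated because the measurement model has none.

Defaults are anchored to the magnitude of published group-level estimates for
each paradigm: context recollection around 0.15 for the arbitrary colour×size
materials, around 0.35–0.5 for integrated colour–object–location triplets;
target recollection 0.3–0.45; familiarity 0.15–0.2; biases matching observed
false-alarm rates (≈0.4/0.26/0.22 for exp1, below 0.1 for exp2, ≈0.1–0.16 for
exp3). The probit-scale SD defaults to 0.5 per parameter (independent), a
moderate heterogeneity typical of latent-trait applications. These choices
were fixed once, before any test was run against them.

What a green simulation-based test establishes: that the pipeline recovers
the parameters and power structure of data generated *by its own model
class* — binomial noise, probit-normal heterogeneity, no item effects, no
response omissions, no serial-position or fatigue structure. Real data can
violate all of these; T1/T2 checks exist precisely to flag that.

## Maximum-likelihood estimation

Per-participant (or aggregated) counts are product-binomial. The likelihood
is maximised over an unconstrained probit transform of the parameters with
L-BFGS-B from 10 seeded starts (one at the centre of the parameter space,
nine standard-normal), because MPT likelihoods with sparse cells are
multimodal near the boundary. The best optimum is then polished at tight
tolerances (ftol 1e−15, three-point gradients) so that expected-frequency
inputs reproduce the generating parameters to ~1e−5 and G² to below 1e−6.
Estimates are clipped into [1e−6, 1−1e−6] and flagged when at that guard.

Standard errors come from the inverse observed information on the
probability scale (finite-difference Hessian); a singular Hessian — typical
at boundary estimates — is flagged rather than silently dropped. The G²
deviance uses `2·Σ obs·log(obs/exp)` over yes- and no-cells with `0·log 0 =
0`; degrees of freedom are free categories minus free parameters, and the
p-value is reported as undefined when df ≤ 0.

Per-participant estimates are intentionally noisy (few trials per cell) and
are *never* shrunk toward group means: the Bayes-factor tests downstream
require independent observations per participant, which posterior means from
the hierarchical model would violate (shrinkage makes them dependent on the
group-level estimate).

## Hierarchical latent-trait estimation

The hierarchical model places the binomial likelihood on `theta_i =
Phi(z_i)` with `z_i ~ MVN(mu, Sigma)`. Priors: `mu_p ~ Normal(0, 1)` on the
probit scale (weakly informative over the full probability range) and `Sigma
~ Inverse-Wishart(k+1, I)`. The Inverse-Wishart was chosen over a
half-Cauchy/LKJ decomposition because (a) it is the conjugate analogue of
the Wishart-precision prior used by the standard latent-trait MPT tooling,
and (b) conjugacy yields an exact Gibbs step for `Sigma`, which keeps the
sampler simple and robust on a single CPU. Both priors are arguments of
`_run_chain` level defaults and can be revisited.

**Sampler.** Metropolis-within-Gibbs with four move types per sweep:

1. componentwise random-walk Metropolis on every `z_ij`, vectorised across
   participants, with per-(participant, parameter) scales adapted toward 44%
   acceptance during warm-up;
2. a componentwise *translation* move that shifts `mu_j` and all `z_ij`
   jointly (deviations fixed) — without it the group location mixes only
   through the individuals and effectively stalls when per-participant
   information is weak;
3. a *joint* translation with proposal covariance adapted from the warm-up
   draws of `mu`, which handles posterior correlations such as familiarity
   trading off against the either-question bias;
4. a componentwise *rescale* move multiplying all deviations of one
   parameter by `exp(s)` (Jacobian `P·s` in the acceptance ratio), which
   traverses the funnel between the group-level spread and the individual
   displacements of weakly identified parameters.

`mu | z, Sigma` (multivariate normal) and `Sigma | z, mu` (inverse-Wishart)
are exact conjugate draws. The sampler was validated against the analytic
prior by running it on a dataset with zero trials, where the posterior must
equal the prior.

Defaults are 4 chains × (1000 warm-up + 1000 retained); the test suite and
the simulation studies run reduced (2 chains, 800 + 1500). Convergence is
summarised by split-R-hat and bulk ESS (ArviZ) on the group locations; a fit
with any R-hat above 1.05 is returned with `converged=False` and an explicit
flag, never silently. Familiarity parameters of small item classes routinely
show the lowest ESS — they are weakly identified by design (only
either-probes inform them), and their wide intervals are the honest answer.

**Posterior-predictive checks.** The exact statistics used by the original
latent-trait analyses are unpublished tool internals, so the implementations
here are documented and calibration-tested rather than value-matched. T1 is
a Pearson chi-square distance between observed and expected category *mean
frequencies* (averaged over participants; yes- and no-cells both included).
T2 compares the across-participant covariance matrix of category frequencies
with its model expectation, `Cov(y) = Cov_i(n∘p_i) + diag(mean_i n p_i
(1−p_i))`, by the summed squared deviation over the upper triangle. For each
of 500 retained draws a replicate dataset is simulated from the
individual-level parameters; the p-value is the fraction of draws whose
replicate statistic is at least the observed one. Fewer than 500 available
draws triggers a recorded warning. On model-generated data both p-values are
calibrated away from the tails; an injected shift of 0.4 in one category's
rate drives T1 below 0.05.

**Contrasts.** Group-level contrasts are per-draw differences of
`Phi(mu_p)`; within one fit draws are differenced index-by-index, across two
independent fits (between-subject conditions) draws are paired by index,
which requires equal retained draw counts. A contrast is *substantial* when
the central 95% credible interval of the differences excludes zero.

## Bayes factors

**JZS t test.** The standardised effect gets a Cauchy(0, r) prior with
`r = 1/√2`. BF₁₀ is the ratio of the marginal likelihood of the observed t
(non-central-t integrated over the prior, adaptive quadrature at relative
tolerance 1e−8, integrand rescaled by its peak log-likelihood to stay in
floating-point range) to the central-t density. One-sided variants (BF₊₀,
BF₋₀) truncate the prior to a half-line, so `(BF₊₀ + BF₋₀)/2 = BF₁₀` holds
by construction. The implementation is cross-checked in tests against an
independent implementation (pingouin) and a 10⁶-draw Monte-Carlo
integration oracle.

**Rank-based tests.** The Wilcoxon signed-rank and Mann–Whitney analogues
use latent-normal data augmentation: latent values consistent with the
observed ranks (signs plus |·|-order for the signed-rank case; pooled order
for the rank-sum case) are Gibbs-sampled as truncated normals between their
rank neighbours, alternating odd/even positions so the updates vectorise.
The effect-size conditional is conjugate up to the Cauchy prior and is
sampled by inverse-CDF on a dense grid; the Bayes factor is the
Savage–Dickey density ratio at zero, Rao-Blackwellised over the Gibbs draws
(the conditional density at zero is averaged, which is far more stable than
a kernel estimate). Directional factors multiply by the posterior odds of
the effect sign. Conventions: zero differences dropped, ties mid-ranked in
the reported W statistic and broken stably in the augmentation ordering;
all-tied data are rejected. Defaults: 2000 retained sweeps after 500
burn-in.

**Evidence labels.** BF > 10 strong and 3–10 moderate evidence for the
alternative; symmetrically below 0.1 strong and 0.1–1/3 moderate for the
null. Boundary conventions (the stated ranges are open/closed as
implemented: `(1,3)` weak-H1, `[1/3,1]` weak-H0, etc.) are a documented
choice; a BF of exactly 1 is labelled weak-H0 so that the partition of
(0, ∞) is total and monotone.

## Pipeline

`run_pipeline` executes design → (simulate | ingest + validate) → ML and/or
hierarchical fit → PPC → contrasts → BF tests, writing every artifact (data
CSV + JSON sidecar, estimate CSVs, posterior summary and flat draws, PPC and
contrast JSON, Markdown report) and a manifest with SHA-256 hashes and
per-stage seeds split from the single root seed. Re-running the same
configuration reproduces the artifacts byte-identically. Input validation
reports machine-readable errors (column schema, count ranges by row,
per-participant cell completeness and allocation against the named design)
and never drops rows silently.

## Known limitations

- The sampler is random-walk based; very large designs (hundreds of
  categories) would favour a gradient-based sampler instead.
- T1/T2 are this package's documented formulations; numerical p-values are
  not comparable to other tools' beyond calibration behaviour.
- The rank-based BF treats tied observations by a fixed stable ordering in
  the augmentation; heavy ties (coarse scales) deserve a dedicated treatment.
- Simulation realism: no item effects, omissions, or sequential dependencies.
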