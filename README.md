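# dualrec

Dual-recollection multinomial processing tree (MPT) analysis of
conjoint-recognition context-memory experiments.

## The problem

In a conjoint-recognition experiment, participants study items carrying
correlated contextual features (for example, a font colour that co-occurs
more often with one font size or location than another) and are then probed
with three question types per item: *was it in class 1?*, *was it in class
2?*, *was it in either class?* The scientific question is whether memory for
context tracks the experienced base-rates of feature configurations
(base-rate dependency) or ignores them (base-rate neglect) — and whether any
base-rate sensitivity lives in memory itself or only in response guessing.

Raw yes/no rates cannot separate those explanations. The dual-recollection
MPT measurement model does: it decomposes acceptance probabilities into

- **RC** — context recollection: conscious reinstatement of the probed
  contextual feature,
- **RT** — target recollection: vivid reinstatement of the item's own
  presentation,
- **F** — familiarity, contributing only to the either-question,
- **b** — response bias per question type.

For a target whose context matches the probe,
`P(yes) = RC + (1−RC)·RT + (1−RC)(1−RT)·b`; for a mismatching probe,
context recollection is a terminal rejection,
`P(yes) = (1−RC)·[RT + (1−RT)·b]`; for the either-question,
`P(yes) = RC + (1−RC)RT + (1−RC)(1−RT)F + (1−RC)(1−RT)(1−F)·b`; distractors
are accepted only through the bias, `P(yes) = b`.

`dualrec` implements the complete analysis pipeline around this model:

- `dualrec.design` — the three experiments' base-rate layouts (item counts
  per feature-configuration cell, probe counterbalancing, conditional
  base-rate arithmetic),
- `dualrec.model` — the processing trees, category probabilities,
  identifiability diagnostics, JSON/EQN export,
- `dualrec.simulate` — synthetic populations (probit-scale latent traits,
  `theta_i = Phi(mu + delta_i)`, `delta_i ~ MVN(0, Sigma)`) and response
  datasets,
- `dualrec.ml` — per-participant maximum-likelihood fits (multi-start,
  probit-transformed, G² goodness of fit),
- `dualrec.hierarchical` — hierarchical Bayesian latent-trait estimation
  (custom Metropolis-within-Gibbs sampler), T1/T2 posterior-predictive
  checks, posterior contrasts,
- `dualrec.stats` — corrected acceptance rates, credible-interval contrast
  decisions, default-prior (JZS, Cauchy `r = 1/√2`) Bayes-factor t tests and
  rank-based Bayes factors (latent-normal augmentation, Savage–Dickey),
- `dualrec.pipeline` / `dualrec.cli` — a configuration-driven pipeline with
  seeded stages, manifests and a `dualrec` command-line interface.

## Worked example

Simulate an experiment with 60 targets split 48:12 over frequent/infrequent
colour–location configurations plus 30 distractors (the high-disproportion
arm), fit the hierarchical model, and test the base-rate question:

```python
from dualrec import (
    build_design, build_dual_recollection_model, make_experiment_dataset,
    fit_latent_trait, group_contrast_draws, contrast_decision,
    fit_dataset, rank_bf,
)

design = build_design("exp3-high")
model = build_dual_recollection_model(design)
data = make_experiment_dataset("exp3-high", seed=11, n_participants=32)

posterior = fit_latent_trait(data, model, seed=5, n_chains=2,
                             n_warmup=800, n_draws=1500)
print(posterior.summary_frame().round(3).to_string(index=False))
```

```
    parameter  mean    sd  bci_lower  bci_upper  rhat     ess
  RC_frequent 0.296 0.045      0.206      0.384 1.008 403.151
  RT_frequent 0.436 0.043      0.350      0.518 1.002 833.443
         b_Cf 0.203 0.035      0.139      0.274 1.005 594.621
RC_infrequent 0.300 0.074      0.151      0.441 1.019 289.892
RT_infrequent 0.476 0.070      0.340      0.610 1.004 271.678
         b_Ci 0.158 0.030      0.104      0.221 1.005 713.038
   F_frequent 0.110 0.067      0.008      0.255 1.027 170.047
     b_either 0.112 0.029      0.059      0.174 1.011 234.444
 F_infrequent 0.441 0.158      0.103      0.716 1.020 175.239
```

Each row is a group-level posterior mean (SD) with its central 95% Bayesian
credible interval on the probability scale, plus split-R-hat and effective
sample size. The generating population here has *equal* context recollection
for both configurations (base-rate neglect), and the analysis agrees:

```python
diff = group_contrast_draws(posterior, "RC_frequent", "RC_infrequent")
res = contrast_decision(diff)
# delta RC = -0.004, 95% BCI [-0.165, 0.162], substantial: False

estimates = fit_dataset(data, model, seed=0)      # independent ML fits per participant
bf = rank_bf(estimates["est_RC_frequent"], estimates["est_RC_infrequent"],
             paired=True, direction="greater", seed=3)
# BF+0 = 0.127 (moderate H0), W = 214.0
```

The contrast interval covers zero (no substantial RC difference) and the
one-sided rank-based Bayes factor of 0.127 is moderate evidence *for* the
null — the package's inferential chain reproduces the logic of a base-rate
neglect conclusion on data where that is the truth. The familiarity
parameter of the infrequent class is estimated with very wide uncertainty
(only 4 either-probes inform it), which is the expected behaviour, not a
defect.

The same analysis is available from the shell:

```bash
dualrec simulate --preset exp3-high --n 32 --seed 11 --out data.csv
dualrec fit-hier --data data.csv --out summary.csv --draws-out draws.csv --seed 5
dualrec contrast --draws draws.csv --a RC_frequent --b RC_infrequent
dualrec run --config config.yaml      # full pipeline with manifest + report
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it simulates a
32-participant high-disproportion experiment from the seeded generator, runs
maximum-likelihood and hierarchical fits, posterior-predictive checks,
posterior contrasts and a rank-based Bayes-factor test, and writes the
results JSON to `--out`.
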