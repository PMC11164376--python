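# tonelearn

Longitudinal drift-diffusion analysis of non-native speech category learning.

`tonelearn` implements the full computational pipeline of a three-session
Mandarin tone category-learning study: adults learn to assign 80 natural
speech stimuli (4 lexical tones × 4 speakers × 5 syllables) to four response
keys across three sessions separated by one and two months, with six 40-trial
feedback training blocks plus one feedback-free generalization block (held-out
speakers) per session, and an operation-span (OSPAN) measure of working-memory
capacity. The package provides

- **a synthetic-cohort generator** that emulates the study design exactly
  (stimulus grid, block structure, learner/non-learner mixture, OSPAN task)
  and produces trial-level choice/response-time data from the generative
  decision model, so every downstream stage is testable without any data
  download;
- **a hierarchical Bayesian multi-alternative race model** of choice and RT:
  on each trial four evidence accumulators race, one per response option
  *d*. Accumulator *d* is a unit-diffusion Wiener process with drift
  μ<sub>d,s</sub> (stimulus category *s*) and boundary b<sub>d</sub>; its
  first-passage time is inverse-Gaussian with density
  f(t; μ, b) = b (2πt³)<sup>−1/2</sup> exp(−(b − μt)²/(2t)),
  and the joint density of (choice d, RT τ) is
  f(τ−δ<sub>s</sub>; μ<sub>d,s</sub>, b<sub>d</sub>) · ∏<sub>d′≠d</sub>
  S(τ−δ<sub>s</sub>; μ<sub>d′,s</sub>, b<sub>d′</sub>),
  with δ<sub>s</sub> a non-decision offset. Log-drift and log-boundary
  trajectories over the six training blocks are B-spline curves with
  population-level coefficients plus participant-level deviations
  (Gaussian shrinkage), fitted per session by adaptive
  Metropolis-within-Gibbs MCMC (default 6,000 iterations, 2,000 burn-in,
  thinning 5 → 800 retained draws) with Geweke diagnostics and posterior
  predictive checks;
- **behavioral scoring**: pooled 1%-per-tail RT trimming, block accuracy,
  chance-based learner classification (final-block accuracy ≤ 35% →
  non-learner), OSPAN scoring (summed length of perfectly recalled spans,
  maximum 75), maintenance deltas (adjacent blocks with vs without a
  month-scale delay), generalization scores (test minus final-block
  accuracy), and the median-split WM grouping used for visualization;
- **association models**: random-intercept linear mixed models (profiled
  REML, written against a closed-form Woodbury GLS solve) regressing
  accuracy, maintenance, generalization, and posterior drift/boundary
  summaries on raw OSPAN × block × session with participant intercepts.

The model-fitting components are scikit-learn-style estimators (`RaceDDM`,
`RandomInterceptLMM`) with `fit`, `get_params`/`set_params` and fitted
attributes, so they compose with sklearn tooling; module-level functions
(`fit_session`, `fit_random_intercept_lmm`, …) are thin wrappers.

## Worked example

```python
from tonelearn.synthetic_cohort import sample_cohort, simulate_experiment, simulate_cohort_ospan
from tonelearn.behavior_metrics import metrics_table, trim_rt
from tonelearn.race_ddm import RaceDDM, correct_drift_summary
from tonelearn.wm_association import ddm_parameter_model

cohort = sample_cohort(20, rng_seed=1)            # latent WM, learner flags, trajectories
trials = simulate_experiment(cohort, rng_seed=2)  # 20 x 3 x 280 = 16,800 trials
_, ospan = simulate_cohort_ospan(cohort, rng_seed=3)

tables = metrics_table(trials, ospan)             # trim -> accuracy -> classify -> score
model = RaceDDM(n_iter=1500, burn_in=500, thin=2, random_state=4)
model.fit(trim_rt(trials[trials.session == 1]))   # session-1 hierarchical race fit
summ = correct_drift_summary(model.fit_)          # posterior-mean drift per participant x block
summ["session"] = 1
print(ddm_parameter_model(summ, ospan, "drift").to_frame().round(4))
```

Output (reduced-length MCMC; ~25 s on one CPU):

```
       term    beta     se      p
  Intercept  0.8918 0.1792 0.0000
      OSPAN -0.0035 0.0047 0.4499
      Block  0.0396 0.0260 0.1287
OSPAN:Block  0.0024 0.0007 0.0004
```

The positive `OSPAN:Block` coefficient (0.0024 evidence-units per OSPAN
point per block, z ≈ 3.5) recovers the working-memory → learning-slope
coupling that the cohort was generated with: participants with higher
working-memory capacity speed up their correct-response evidence
accumulation faster across training blocks. In the same run, 12 of 20
simulated participants were classified as learners and mean training
accuracy rose from 33.3% (session 1, block 1) to 40.3% (block 6).

A full run — simulate, trim, score, fit each session, fit all association
models, with a checksummed manifest — is one command:

```bash
tonelearn run-all --seed 11 --n-participants 10 --out demo_run
```

Subcommands `simulate`, `metrics`, `fit-ddm`, `associate` and
`make-fixtures` expose the individual stages; see `tonelearn --help`.

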