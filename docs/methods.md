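# Methods

This note documents the generative model, the inference machinery, the
synthetic-data conditions, and the numerical choices behind `tonelearn`.
Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is quoted from external data.

## 1. The decision model

Each categorization trial is a race between four independent evidence
accumulators, one per response option. For a stimulus of tone category
*s* ∈ {1..4}, accumulator *d* is a Wiener process with unit diffusion
coefficient and drift μ_{d,s} > 0 toward an absorbing boundary b_d > 0.
The first accumulator to reach its boundary determines the response, and
the observed response time is the crossing time plus a non-decision offset
δ_s > 0 (stimulus encoding, key press). The first-passage time of a single
accumulator is inverse-Gaussian,

    f(t; μ, b) = b (2π t³)^{−1/2} exp(−(b − μt)² / (2t)),
    S(t; μ, b) = 1 − [Φ((μt − b)/√t) + e^{2μb} Φ(−(μt + b)/√t)],

and the joint density of (choice d, RT τ) is the winner's density times the
losers' survival functions at τ − δ_s. Units: drift in evidence·s⁻¹,
boundary in evidence units, times in seconds; the unit diffusion
coefficient is the identifiability convention for this model class.
Boundaries are indexed by response only — response caution is not allowed
to depend on the true stimulus — while drifts vary over the full
response × stimulus grid.

Consequences the test-suite verifies by simulation and quadrature:

- choice probabilities equal ∫ f_d ∏_{d′≠d} S_{d′}, and total probability
  is 1;
- raising **all** boundaries jointly slows responses and raises accuracy
  (the speed–accuracy tradeoff); raising a **single** accumulator's
  boundary handicaps that accumulator (it wins less often) — response
  caution is a property of the whole response set, not of one option;
- raising the correct-response drift speeds responses and raises accuracy.

## 2. Longitudinal hierarchy

Within one session, log μ_{i,d,s}(block) and log b_{i,d}(block) evolve
smoothly over the six training blocks:

- **population level**: cubic B-spline curves on the block axis with
  interior knots at blocks 2–5 (8 basis functions; degree and knots are
  configurable), under a second-difference Gaussian smoothing prior
  (precision `smooth_tau`, default 4) plus a small ridge;
- **participant level**: zero-mean Gaussian deviations from the population
  curve on a **level + slope** basis (intercept and a linearly scaled block
  term). A full-spline deviation per participant per cell is not
  identifiable from the ~60 trials a participant contributes per stimulus
  category and mixes poorly; level and slope carry the participant
  variation that the downstream analyses consume (who is faster, who
  learns faster). One deviation variance per drift cell (d, s) and per
  boundary response, with inverse-gamma hyperpriors (a₀ = 2, b₀ = 0.05)
  **truncated below at 0.1**. The truncation is a deliberate
  weakly-informative choice: with 10–20 participants the cell-level
  variance is itself poorly identified, and an untruncated hierarchy can
  collapse into the funnel neck (all deviations shrunk to zero) from which
  random-walk samplers do not escape;
- **offsets**: δ_{i,s} per participant × stimulus category, constant over
  blocks and sessions, uniform prior on (0, 0.995 × smallest observed
  adjusted RT in the cell) so decision times stay positive;
- sessions are fitted separately (no between-session smoothness), with all
  participants — learners and non-learners — together; group contrasts are
  post hoc. Feedback-free generalization trials are excluded from fitting
  by default (`include_generalization=True` maps them onto the final
  block's parameters instead).

## 3. MCMC

Adaptive random-walk Metropolis-within-Gibbs on log-scale coefficients:

- population drift/boundary curves: per-curve K-vector proposals;
- participant deviations: proposals executed **in parallel across
  participants** (their full conditionals are independent given the
  population level, so the compound kernel is a composition of valid MH
  kernels), with both a 2-vector move and a pure level-shift move;
- offsets: reflective random walk inside the prior box;
- deviation variances: conjugate inverse-gamma Gibbs (truncated), plus an
  interweaved joint rescaling move (dev, σ²) → (c·dev, c²σ²) that travels
  along the funnel axis;
- proposal scales adapt per parameter toward acceptance 0.3 during
  burn-in only (observed rates 0.25–0.35 across update families); the
  variance Gibbs starts halfway through burn-in.

Initialization is method-of-moments: boundaries from the IG mean/variance
relation of pooled winner RTs (λ = m³/v, b = √λ), the overall drift level
from b / (mean adjusted RT), the correct-to-incorrect drift ratio from
cell accuracy, and δ at half the cell's minimum RT. This places disengaged
participants (fast but at chance) at low boundaries and flat drifts rather
than learner-like ones, and cuts the burn-in needed by an order of
magnitude.

Defaults: 6,000 iterations, 2,000 burn-in, thinning 5 → 800 retained draws
per scalar. Retained draws of all participant-level and population-level
curves are stored (float32). Diagnostics: Geweke z-scores (first 10% vs
last 50%, Bartlett-windowed spectral variance; |z| < 2 is a pass) on all
population chains plus a random 10% of participant drift chains, and
posterior predictive checks on per-block accuracy and RT quantiles
(0.1/0.5/0.9) with a configurable replicate count (default 200). At the
heavily reduced schedules used in the test suite (800–1,500 iterations)
individual-level chains still show trending (pass fractions well below 1);
population-level summaries and the recovery targets are insensitive to
this, but production analyses should use the default schedule.

The likelihood kernel (log-pdf / log-sf per accumulator) is numba-compiled
when numba is importable, with an identical numpy fallback; the log-sf uses
log-space guards so e^{2μb} never overflows. A cached per-cell
log-likelihood table makes each proposal touch only the trials it affects.

## 4. Synthetic cohort: the study conditions

The generator reproduces the experiment structure exactly: 80 stimuli
(20 per tone), 40 training + 40 generalization split by speaker, three
sessions of 6 × 40 training trials plus 40 feedback-free generalization
trials, uniformly shuffled per block per participant (the presentation
order of the original procedure is unstated; uniform shuffling is assumed),
and a 15-trial OSPAN task with spans 3–7 (three of each).

Participant latents (defaults, chosen once to echo the published cohort's
descriptive statistics and kept fixed):

- working memory: truncated normal on the 0–75 OSPAN scale, mean 45,
  SD 15 (study median 46);
- learner mixture: marginal learner rate 0.68 (73/107 in the study), with
  logit slope 0.03 per OSPAN point (learners had numerically higher WM);
  the intercept is solved by quadrature so the marginal rate is exact;
- learner trajectories: correct-accumulator log drift = base + slope ×
  progress − 0.22 × (session − 1), with progress counting five block steps
  per session; base ~ N(0.05, 0.15²), slope ~ N(0.13, 0.025²) **plus
  0.003 × (WM − 45)** — the WM → learning-slope coupling the association
  stage is designed to detect; incorrect drifts flat at log 0.7;
  boundaries flat near log 1.4. These values put learner block-6 accuracy
  near 55% / 72% / 82% across sessions and delay drops of 8–10 points, the
  magnitudes the published learning curves show;
- non-learners: flat drifts near log 0.7 with a +0.06 correct bonus and
  low boundaries (log 0.85), WM-independent — the "disengaged" regime
  (fast, at-chance responding);
- offsets: log-normal, median 0.33 s, σ 0.22, per participant × category;
- OSPAN recall: a span of length L is recalled perfectly with probability
  logistic(0.15 × (WM − c_L)) with thresholds c ∈ {4.5, 15, 28.5, 45,
  64.5}; these midpoint thresholds make the expected score track the
  latent WM across the whole range (measured correlation ≈ 0.92 at
  n = 500). Arithmetic accuracy is simulated at 90% (learners) / 79%
  (non-learners) and never filters scores. Letters come from a fixed
  12-consonant pool, drawn without replacement within a trial.

Sampling uses numpy's `Generator.wald` — the exact transform-method
inverse-Gaussian sampler — and every stage is reproducible from
(config, seed) via `SeedSequence` spawning. Trial-level RTs always exceed
the participant's δ by construction.

**What the generator does not emulate**: within-block trial-by-trial
learning or feedback-driven updates (trajectories are block-resolution,
matching the fitted model), acoustic stimulus structure (the
two-dimensional pitch space is not modelled; duration/level normalization
is metadata), session-gap jitter, attrition, and any dependence of
generalization-block parameters on novel-speaker difficulty
(generalization trials reuse the final training block's parameters, so the
generative generalization score is zero in expectation). Passing tests
therefore demonstrate that the pipeline recovers what this generative
family encodes — not that real data satisfy the model.

## 5. Behavioral scoring conventions

- RT trimming pools **all** trials (participants, sessions, blocks) and
  removes the top and bottom 1% by linear-interpolation sample quantiles;
  rows exactly at a quantile are kept, so an all-ties table loses nothing.
- Learner classification uses the stored constant 35% (the chance-based
  cutoff for 40 trials at p = 0.25 as the study states it). The exact
  Binomial(40, 0.25) 95th percentile under the smallest-k convention would
  be 15/40 = 37.5%; the printed rule is treated as authoritative, and
  accuracy exactly at the cutoff is non-learner.
- OSPAN scoring is order-sensitive exact matching; partial recalls add 0.
- Maintenance deltas: block 6 − block 5 within a session (no delay) and
  next-session block 1 − block 6 (delay), in percentage points.
- Generalization score: generalization-block accuracy − block-6 accuracy.
- Median split: ties at the median go to the high group; used for
  grouping/plotting only — every model uses raw OSPAN.

## 6. Mixed models

`RandomInterceptLMM` fits y = Xβ + u_participant + e by profiled REML: for
a fixed variance ratio λ = σ²_u/σ²_e the per-group covariance I + λJ
inverts in closed form, and the REML deviance is minimized over log λ by
bounded scalar search (boundary λ = 0 checked explicitly; `fix_lambda=0`
reproduces OLS to machine precision). Standard errors come from the GLS
information matrix; p-values use the normal approximation to the t
statistic — at a dozen participants this is anti-conservative relative to
Satterthwaite-style degrees of freedom, which is visible as a mildly
elevated false-positive rate in the null-configuration checks and is noted
in each result (`pvalue_method`). statsmodels' MixedLM serves as an
independent cross-check in the tests, never as the implementation.

Model structures: session is treatment-coded with session 1 baseline,
block is numeric 1–6 and uncentered, OSPAN is the raw score, and each
model includes all interactions of its stated factors (accuracy and DDM
parameter models: OSPAN × block × session; maintenance: OSPAN × time ×
delay with the delay condition as baseline; generalization: OSPAN ×
session). Dummies of the same factor are never multiplied together. The
DDM-parameter models take the per-participant × block posterior-mean
summaries: drift = the plain average of the four correct-accumulator
(d = s) drifts, boundary = the average over the four responses.

## 7. Problem sizes in the tests and acceptance script

The suites run the generator at 5–107 participants, recovery at
20 participants × 240 session-1 trials with MCMC 1,500/500/2 (posterior
mean vs truth correlation for correct-accumulator log drifts across
participants × blocks ≈ 0.89), and the end-to-end coupling check at
12 participants with MCMC 800/300/2 over 10 seeds per arm. These sizes
keep a full suite run inside a few minutes on a single CPU while leaving
every stage's logic identical to a full-scale run; the default MCMC
schedule is used whenever a human analysis is the goal.

## 8. Known limitations

- No starting-point bias, no inter-trial drift variability, no
  between-session smoothness, and no full nonparametric prior machinery —
  the hierarchy here is a deliberately simplified (spline + Gaussian
  shrinkage) variant of the semiparametric family it follows.
- Per-participant drift gaps are weakly identified at low boundaries
  (choice probabilities flatten as b decreases), which bounds individual
  recovery at small trial counts regardless of sampler quality.
- The truncated variance hyperprior trades a small amount of shrinkage
  optimality for robustness against hierarchical collapse; analyses that
  need fully adaptive shrinkage should raise the floor-free iteration
  budget substantially and check the σ² traces.
- δ is assumed constant across blocks and sessions within participant ×
  stimulus; whether the original design warrants per-session offsets is
  untested here.
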