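# Methods

This note documents the models, conventions and design choices behind
`rebl`, in the spirit of a model-documentation page: what is computed, under
which assumptions, with which defaults, and where the edges are.

## Task model

The task is a two-block probabilistic instrumental design. Per trial the
participant chooses between two shapes; the *advantageous* shape delivers
the favourable outcome with the block contingency (default 0.75), the other
with its complement. In the reward block the outcome dimension is reward
(high = puppy image, low = dog image) and effort is fixed at its high level
(60 presses); in the effort block the outcome dimension is effort (low = 35
presses is favourable) and reward is fixed high. Outcomes are drawn
i.i.d. Bernoulli per trial conditioned on the chosen shape — with 25 trials
per block an exact-count 75% schedule is impossible (18.75 trials), so
independent draws are the only faithful reading of the design. Outcome
coding is unified: `o = 1` means "favourable" in both blocks, letting one
likelihood serve reward and effort learning.

Choices are recorded against the latent advantageous/disadvantageous role;
left/right screen position and its counterbalancing are presentation-layer
and not modelled. Four practice trials are generated (first block's
mechanics) but never analysed. The 30 s inter-block break is metadata only.

Defaults: contingencies 0.75/0.75, presses 60/35, 25 trials per block, 4
practice trials. Contingencies are validated to lie strictly inside
(0.5, 1.0): at 0.5 no shape is advantageous, at 1.0 the task is
deterministic.

## Q-learning family

State is one value per shape plus a choice trace. Updates after choosing
*c* with outcome *o*:

* factual: `Q(c) ← Q(c) + α (ρ·o − Q(c))`
* counterfactual variants additionally: `Q(u) ← Q(u) + α (ρ·(1−o) − Q(u))`
  for the unchosen *u* — the task's contingencies are anticorrelated, so
  the unchosen shape's hypothetical outcome is the complement.
* choice trace: `C(a) ← γ·C(a) + 1[a = choice]` for both shapes.

Choice probabilities are a softmax over `U(a) = Q(a)/τ + φ·C(a)`. The
temperature divides the values, so higher τ means flatter probabilities and
more exploration; this direction matters for interpreting symptom
correlations (more anhedonia → higher τ → more undirected choices).

Conventions, chosen where the functional form was genuinely open:

* **Initialisation** `Q = ρ·0.5` per shape (the midpoint of the scaled
  binary outcome range) and `C = 0`: an unbiased start. A consequence worth
  knowing: under counterfactual updating with a symmetric start,
  `Q(c) + Q(u) = ρ` after every trial, which the property suite asserts.
* **Bias-trace decay when γ is not free**: γ = 0, reducing `C` to the
  previous-choice indicator — standard one-trial-back choice stickiness.
  The alternative (γ = 1, a cumulative choice count) makes `φ·C` an
  unbounded trend term that can mimic value learning itself and lets the
  φ-model absorb variance from any autocorrelated choice sequence; we
  consider that a degenerate operationalisation of "choice bias" and do not
  use it as the fixed value (it remains reachable as the γ → 1 corner of
  the four-parameter model).
* **ρ/τ identifiability.** With binary outcomes, scaling both update
  targets by ρ multiplies every Q — and hence every utility — by ρ, exactly
  as 1/τ does. The two-parameter ρ model (τ fixed to 1) is therefore an
  exact reparameterisation of the α+τ model wherever their bounds overlap:
  the two are observationally equivalent, and no data from this task can
  separate them. They are both kept in the registry because each is a
  conventional parameterisation, but model comparison can only distinguish
  this equivalence *class* from the other family members. ρ and τ are never
  both free in one model for the same reason.

Registry: `{f,cf}_alpha_tau`, `{f,cf}_alpha_rho`, `{f,cf}_alpha_tau_phi`,
`{f,cf}_alpha_tau_phi_gamma` — eight models, 2–4 free parameters per block.
The reference model is `cf_alpha_tau` (counterfactual, learning rate +
temperature).

## Fitting and model comparison

Per participant and per block (blocks are fitted independently, with
separate parameter sets for reward and effort learning), the negative log
likelihood is minimised by L-BFGS-B from multiple starting points within
bounds α ∈ [0, 1], τ ∈ [0.01, 20], ρ ∈ [0, 10], φ ∈ [−5, 5], γ ∈ [0, 1].
τ is optimised on the log scale — it is a scale parameter and the surface
is far better conditioned in log τ — and its random starts are drawn
log-uniformly for the same reason. Two deterministic starts are always
included: a near-random point (τ at its upper bound), which guarantees the
fitted negative log-likelihood never exceeds the random-choice bound
`n·ln 2`, and a near-greedy point (τ = 0.1), which covers the
steep-softmax regime where choice sequences are almost deterministic.
Default `n_starts = 20` random starts for production fits; the validation
suites use 8–20 depending on problem size. Fitting is deterministic given
the seed.

AIC = 2k + 2·NLL per fit. For cohort-level comparison AICs are summed
across participants within a block before computing Akaike weights
`w_i ∝ exp(−Δ_i/2)`; a per-participant winner tally is reported alongside,
since no aggregation rule is canonical.

`QLearningMLE` exposes the fitter as a scikit-learn style estimator
(`fit(choices, outcomes)`, `get_params`/`set_params`, fitted attributes
`params_`, `negloglik_`, `aic_`): the MLE step is genuinely
estimator-shaped and this surface lets it plug into generic tooling, while
the rest of the package keeps its pipeline shape.

### Validation

*Parameter recovery* simulates agents at known parameters, refits, and
reports per-parameter Spearman rank correlations and mean signed bias
(undefined spreads are flagged as NaN rather than erroring). *Model
recovery* generates sessions from the reference model and checks that the
AIC-weight comparison concentrates on the counterfactual two-parameter
equivalence class. *Posterior-predictive checks* compare observed and
model-simulated binned accuracy curves (default bins of five trials) with
standard errors.

A known limitation, quantified by the recovery suite: at the study's
25-trial blocks, maximum-likelihood temperature estimates are noisy.
Sessions that happen to be nearly choice-consistent drive τ̂ to its lower
bound and near-random sessions drive it to its upper bound, and the rank
correlation between generating (τ ~ U(0.5, 4)) and recovered temperatures
sits near 0.3. This is an information ceiling of 25 binary trials, not an
optimiser artefact — an exhaustive grid-search MLE does no better, and the
same estimator recovers parameters consistently at several hundred trials.
Longer sessions, not more optimisation, are what recovery needs here.

## Questionnaires

* **BDI-II**: 21 items coded 0–3, total 0–63; severity bands 0–13 (low),
  14–28 (mild/moderate), 29–63 (severe). The reduced total removes the four
  anhedonia items — loss of pleasure (4), loss of interest (12), loss of
  energy (15), loss of interest in sex (21) — and is used as the depression
  covariate whenever anhedonia is the predictor of interest.
* **TEPS**: 18 items on 1–6; anticipatory subscale of 10 items (1, 4, 6, 8,
  10, 11, 13, 15, 16, 18), consummatory of 8 (2, 3, 5, 7, 9, 12, 14, 17);
  lower = more anhedonia. Reverse coding for effect-size comparisons is
  7 − response per item, equivalently max+min − total at scale level.
* **SHAPS**: 14 four-level agree/disagree items; each disagree-type answer
  scores 1 (total 0–14, higher = more anhedonia); the scoring is invariant
  to which of the two agree (or disagree) levels was endorsed.
* **STAI trait**: 20 items on 1–4 with the nine anxiety-absent items (1, 3,
  6, 7, 10, 13, 14, 16, 19) reverse-keyed; total 20–80, severe iff strictly
  above 60.

Item keys follow the original published instruments. Missing items are
rejected, not imputed: the scales were administered as complete online
forms and no imputation rule is defensible post hoc.

## Statistical battery

* **Effort modulation**: mean press speed on high-reward/high-effort trials
  minus low-reward/high-effort trials, across the whole task. Effort-block
  high-effort trials count toward the high-reward class because reward is
  fixed high there; low-reward/high-effort trials exist only in the reward
  block, so a participant who never drew a low-reward outcome has an
  undefined difference and is flagged rather than imputed.
* **Outlier screen**: a single pass removing values at least k (default 2)
  sample standard deviations (ddof = 1, matching R's `sd()`) from the mean,
  both computed once on the full vector — the rule is deliberately not
  iterated. Zero-variance input removes nothing.
* **One-tailed one-sample t**: upper-tail p, testing whether mean effort
  modulation exceeds zero.
* **Spearman / partial Spearman**: partials are Pearson partial
  correlations on rank-transformed variables (residualising both variables
  on the ranked covariates), with t-approximate p-values on
  n − 2 − #covariates degrees of freedom; with no covariates the plain
  Spearman coefficient and p are returned unchanged. Anhedonia scales are
  controlled for depression with anhedonia items removed; anxiety for
  full-scale depression; effort-modulation correlations additionally for
  block order.
* **Benjamini–Hochberg**: standard step-up FDR adjustment, applied within
  symptom families (one family per scale) rather than globally; the family
  map is configurable.
* **Pearson–Filon z** for two dependent correlations sharing one variable:
  `z = (r_jk − r_jh)·√n / √((1−r_jk²)² + (1−r_jh²)² − 2k)` with
  `k = r_kh(1 − r_jk² − r_jh²) − ½ r_jk r_jh (1 − r_jk² − r_jh² − r_kh²)`,
  two-sided p from the standard normal. Inputs are validated against the
  implied 3×3 correlation matrix being positive semidefinite. Monte-Carlo
  calibration at n = 155 puts the null rejection rate at ≈ 0.05. In the
  pipeline the test compares the liking–depression and liking–consummatory
  anhedonia correlations, with TEPS-C reverse coded so both correlations
  point the same way.
* **Rating ANOVA** (rating type × time on high-minus-low rating
  differences): implemented as a fixed-effects two-way ANOVA on the pooled
  long-format observations. With N participants this yields error df
  6N − 6 (924 at N = 155), which is the layout consistent with the degrees
  of freedom such analyses report; a true within-subject variant is
  available behind `within_subject=True`.
* **Block-order ANOVA**: mixed design, block type within, block order
  between (within-effect df (1, N − 2)), via pingouin.
* **Power**: the minimum n for the two-sided test of zero correlation is
  found from the exact sampling distribution of r under a bivariate-normal
  model (Hotelling's hypergeometric density, integrated numerically), which
  gives n = 84 for ρ = 0.3, 80% power, α = 0.05; the Fisher-z approximation
  (n = 85 for the same inputs) is available as `method="fisher"`. Power is
  monotone in n; the search verifies minimality explicitly.

## Synthetic cohort generator

The generator produces the data structures the pipeline consumes — item
level questionnaires, 0–100 pre/post ratings (liking, wanting, willingness
to exert effort × high/low stimulus), and full two-block sessions with per
trial press speeds — under the statistical structure the study design
assumes, with configurable planted effects.

* **Latent structure.** One standard-normal severity factor per participant
  induces the symptom intercorrelations through loadings (defaults: BDI
  0.90, TEPS-A −0.55, TEPS-C −0.55, SHAPS 0.60, STAI 0.70; TEPS loads
  negatively because lower TEPS means more anhedonia). No covariance matrix
  is published for these scales in this population; a single-factor model
  is the simplest structure consistent with "the scales are correlated".
* **BDI strata.** The severity percentile is mapped piecewise-linearly
  through the three severity bands with breakpoints at the design strata
  proportions 72/65/18 (low / mild-moderate / severe out of 155), so the
  expected stratum mix matches the target cohort and BDI is monotone in the
  latent severity.
* **Items top-down.** A target total is drawn for each scale, then
  distributed randomly across items within item bounds (TEPS subscale
  totals are drawn and distributed separately; STAI items are stored with
  reverse-keyed items inverted so that scoring recovers the intended
  total exactly; SHAPS draws the intended number of disagree-type codes).
  Only totals enter the downstream analyses, so item-level psychometric
  realism (factor structure, item difficulty) is deliberately not
  modelled.
* **Planted effects.** Each behavioural target (block temperatures, effort
  modulation slope, the three rating levels) gets a unit-variance latent
  built from its symptom drivers, `T = Σ r_j L_j + √(1 − rᵀΣr)·ε`, with an
  error raised if the requested map implies variance above 1. Defaults
  (magnitudes near |ρ| ≈ 0.2, the scale realistically detectable at
  N = 155): τ-reward ~ −0.20 with TEPS-C, τ-effort ~ +0.20 with SHAPS,
  effort modulation ~ +0.20 with TEPS-A, liking ~ +0.30 TEPS-A and −0.15
  BDI, wanting ~ +0.30 TEPS-A, effort willingness ~ +0.20 TEPS-A. Because a
  target can have several correlated drivers, the audit compares estimates
  against the *implied marginal* correlation `corr(T, L_s) = Σ_j r_j·
  Corr(L_j, L_s)`, not the raw coefficient.
* **Agents.** Learning rates are logit-normal around 0.44 (no symptom
  effect is planted on α); temperatures are log-normal with means 2.05
  (reward) and 1.55 (effort) and log-SD 0.4, tied to their planted latents.
  Sessions are simulated closed-loop from the counterfactual α+τ model with
  per-block parameters and randomised block order.
* **Press speeds.** Per trial: participant baseline (normal, mean 4.0
  presses/s, SD 0.8) + modulation·1[high reward] + Gaussian noise (SD 0.4),
  truncated at a physiologic floor of 0.5 presses/s. The modulation slope
  is normal with mean 0.10 and SD 0.25 around its planted latent, making
  the cohort-mean effort-modulation difference positive. No published
  distribution exists for press speeds in this task; these are declared
  conventions at plausible magnitudes.
* **Ratings.** High-stimulus ratings centre at 70 (12 points per SD of the
  planted latent, noise SD 8), low-stimulus at 45; post-task ratings are
  pre plus retest noise (SD 5) with no systematic shift, so the habituation
  ANOVA is null by construction. Values are rounded and clipped to 0–100.

Everything is reproducible bit-for-bit from the generator seed (stage
specific child seeds are derived from it), and every cohort carries a
ground-truth table plus a cohort identifier that the audit verifies before
comparing pipeline estimates to planted effects.

**What passing on synthetic cohorts does and does not show.** The generator
reproduces totals, ranges, strata, monotone planted associations and the
session-generating model, so green end-to-end tests demonstrate that the
pipeline's machinery (scoring, fitting, screening, correlation, correction)
recovers known structure at realistic N. It does not emulate item-level
psychometrics, response times, fatigue or habituation dynamics, model
misspecification of real choice behaviour, or missing data — so passing
tests say nothing about those aspects of real datasets.

## Pipeline

Stages run in order (cohort → scores → behavioural measures → fits →
comparison → recovery/PPC → statistics), each seeded by a fixed offset from
the master seed so stages can be re-run in isolation. All inputs are schema
validated on read and fail loudly naming the offending column; a failing
stage removes its partial outputs. The manifest records the config
snapshot, stage seeds, SHA-256 of every output and library versions; a run
is regenerable from its manifest. Every number in `stats_report.json` is a
plain re-application of a module operation to the intermediate CSVs — the
test suite re-derives representative values from the files to enforce
this.

Default problem sizes in the validation suites — 200 sessions for model
recovery, 155 agents for parameter recovery, 10,000 replicates for type-I
calibration, three replicate cohorts for end-to-end sign recovery — were
chosen as the smallest sizes at which the quantities of interest are stable
(binomial/correlation standard errors small relative to the asserted
margins).

## Known limitations

* Temperature recovery at 25-trial blocks is weak (see Fitting); inference
  on individual-participant τ from a single block should be treated as
  ordinal at best.
* The counterfactual ρ model and the counterfactual α+τ model cannot be
  distinguished by this task's data (exact reparameterisation); model
  comparison treats them as an equivalence class.
* Partial Spearman p-values (Pearson on ranks with a t approximation) are
  exact-rate under an independent-y null but mildly anticonservative when x
  and y are conditionally independent given a *strong* shared driver — rank
  transformation leaves a residual of the nonlinear confounding that linear
  partialling cannot remove. The calibration suite measures both regimes.
* The rating ANOVA's default layout treats repeated observations as
  exchangeable across participants; use the within-subject variant when the
  participant covariance matters.
* The generator plants monotone linear-latent effects only; nonlinear or
  interaction structure in real symptom-behaviour relationships is out of
  scope.
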