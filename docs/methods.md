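# Methods

## Setting and estimands

The package analyses a pair-matched community-randomised trial: eight
communities in four matched pairs, one community per pair assigned to a
community-mobilisation intervention.  Outcomes (women's past-year
experience of physical IPV; men's past-year perpetration, disclosed by
anonymous card) and candidate mediators are measured in cross-sectional
surveys of residents aged 18–49, sampled within single-sex census
enumeration areas (EAs, ~28 respondents each).  Three estimand families
are produced:

* the **intention-to-treat risk ratio** for each binary outcome,
  estimated at the cluster level;
* **mediator–outcome associations** (adjusted risk ratios from
  individual-level models);
* **percent attenuation** of the intervention effect after adjusting the
  individual-level model for one mediator at a time — the
  difference-method mediation ledger.

The analysis deliberately avoids counterfactual mediation estimands
(natural direct/indirect effects) and joint multi-mediator
decompositions: with a web of closely interrelated social variables
measured cross-sectionally, the ledger identifies which factors *play a
role*, not a causal decomposition.

## Cluster-level ITT estimator

With so few randomisation units, individual-level models cannot carry
the arm inference.  The estimator is the classic two-stage
cluster-summary device:

1. A logistic model of the outcome on covariates only (no arm term) is
   fitted to all respondents, pooled over arms.  The default covariate
   set is decade age group, marital status and the baseline EA-level
   outcome prevalence; because the expected-events model excludes arm,
   the cluster residuals carry the whole intervention contrast.
2. Per community `j`: observed events `O_j`, expected events
   `E_j = Σ fitted probabilities`, ratio residual `R_j = O_j/E_j`.  At
   the maximum-likelihood solution `Σ_j E_j = Σ_j O_j` (score identity,
   asserted in tests).
3. Pair log ratios `ℓ_p = log R_int,p − log R_ctl,p` are combined by a
   weighted mean with weights proportional to pair sample size
   (an unweighted option exists).  The CI uses the weighted one-sample
   variance of the `ℓ_p` and a t quantile on `P − 1 = 3` degrees of
   freedom.

Numerical policies: a zero-event cluster gets +0.5 added to both `O_j`
and `E_j` (flagged); `E_j = 0` is an error; with a single pair only the
point estimate is returned.  Combination on the log scale keeps the
ratio estimand symmetric and matches the t-based interval; the estimator
is invariant to pair relabelling and cluster order, and scales linearly
in the intervention-arm event counts (both properties are tested).

## Individual-level models

Both model families are fitted by IRLS on dense design matrices
(categorical covariates expanded against the lowest-sorted reference
level; site-pair as fixed-effect indicators; convergence when the
relative coefficient change falls below 1e-8, at most 100 iterations;
non-convergence raises with the step-norm trace, which in practice
catches separation).

* **Logistic** — expected events for the cluster-level estimator.
* **Modified Poisson** — log-link Poisson on the 0/1 outcome.  Point
  estimates are risk ratios; fitted means above 1 are permitted but
  counted and surfaced.

Inference uses the cluster-robust sandwich `A⁻¹BA⁻¹`, where `A` is the
Fisher information at convergence and `B` the outer-product sum of
per-cluster score vectors (`x_i(y_i − μ_i)` summed within EA — the
canonical-link score), multiplied by `G/(G−1)`; the uncorrected form is
retained alongside.  Wald CIs use normal quantiles: with the ~190 EAs of
a full survey the difference from a t reference is negligible, and the
choice is recorded here rather than hidden.  An external-library fit
(statsmodels with its Stata-style correction disabled) serves as the
independent oracle in the test suite; it is never used in the pipeline.

The **interaction screen** adds an arm × risk-factor product term and
tests it with the robust Wald statistic at α = 0.05.  A product that is
collinear with the main effects (e.g. a risk factor identical to arm) is
reported as untestable rather than tested badly.  Under a null
data-generating process its type-I error is calibrated (~5%, asserted
over 400 replicate trials).

## Attenuation ledger

For mediator `M`: base model = arm + site-pair + age group + marital
status + baseline EA prevalence of the outcome, EA-clustered modified
Poisson; adjusted model = base + `M`.  Percent attenuation is computed
on the **excess-risk-ratio scale**,

    A = 100 · (RR_M − RR_base) / (1 − RR_base),

rounded half-away-from-zero to integers for display.  The scale choice
is pinned by a falsification test: for the anchor pair (0.44 → 0.83) the
excess-RR scale gives 70% while a log-scale variant gives 77%; the
excess-RR scale reproduces every published integer percentage the ledger
emulates to ±1, the log scale does not.  Attenuation is undefined when
the base RR is exactly 1 (reported as not applicable); positive values
mean movement toward the null.  No CI is attached by default (a
cluster-bootstrap percentile CI exists behind a flag, as an extension).
Community-level mediators enter the models as the respondent's own EA
prevalence divided by 10 (per-10-point RRs; a leave-one-out variant is
available — the difference is O(1/n) at EA size 28).

## Synthetic trial generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated under.

Structure: 4 pairs × 2 communities; 12 EAs per community at follow-up
and 8 at baseline (half female, half male — EAs are single-sex by
design, and the published EA counts per arm and sex match this layout);
EA sizes are a discretised truncated normal with mean 28 on [18, 35]
(the location parameter is solved so the truncated mean equals 28).

Data-generating process, per wave:

* pair effect `u_p ~ N(0, σ_pair²)` and community effect
  `v_c ~ N(0, σ_comm²)` on the logit scale, shared across waves so the
  baseline covariate is informative when the norm pathway is active;
* community norm propensity
  `π_c = expit(b₀ + δ·arm + u_p + v_c)` (δ applies at follow-up only);
* EA propensity `π_ea = expit(logit(π_c) + jitter)`,
  `jitter ~ N(0, σ_jit²)`;
* individual violence-accepting attitude `a_i ~ Bernoulli(π_ea)`;
* realized EA norm level `P_ea = mean(a_i)` over the EA roster;
* outcome risk (log link, clamped to (0, 1)):

      log p_i = log p₀ + β_age(age−30) + β_marital + β_edu
                + β_abuse·abuse + β_att·a_i
                + (1−λ)·β·arm + θ·(P_ea − m₀)

  with `β = log 0.45` the total target arm effect and `m₀` the expected
  control-arm norm level.

The *realized* EA attitude prevalence — not the latent propensity — is
the exposure in the risk model.  This is a deliberate design decision:
the social exposure a respondent experiences is the actual attitudes of
the people around them, and it makes the survey-measured mediator equal
to the true exposure, so the mediated fraction λ maps cleanly onto the
attenuation recoverable downstream.  With a latent-propensity exposure,
EA-level binomial measurement error (sd ≈ √(p(1−p)/28) ≈ 0.09) would cap
attainable attenuation well below 100% at any realistic
between-community variance.

**Calibration.**  `θ` is solved by bisection (brentq, 0.5% relative
tolerance on the marginal log-RR) against a 200,000-draw Monte-Carlo
estimate of the marginal arm risk ratio, so the TOTAL marginal RR equals
`exp(β)` for every λ; at λ = 0 (and no attitude→outcome effect) θ is
exactly 0.  The calibration Monte Carlo uses a fixed internal seed, so θ
is a pure function of the DGP parameters and is cached across replicate
runs.  `true_marginal_rr` re-estimates the marginal RR with ≥10⁶ draws
as the recovery target; at default settings it is within 0.005 of 0.45
for λ ∈ {0, 0.5, 1}.

**Other mediators** are drawn conditional on the individual attitude
(logit shifts of ±0.3–0.6 around base prevalences chosen to resemble
mid-prevalence survey indicators), so the intervention reaches them only
through the norm pathway.  Survey items are then materialised to be
exactly consistent with the latent indicator truths (for an "any of"
rule, at least one qualifying response is forced for true cases); an
integration test asserts that indicators recomputed from items equal the
latent columns.  `items=False` skips materialisation for replicate
studies.

**Randomness** is organised as one counter-based stream per (seed, wave,
community, EA, variable), so enlarging an EA extends but never shifts
earlier draws; all streams derive from the single config seed.

Default parameters and their provenance:

| parameter | default | rationale |
|---|---|---|
| `arm_log_rr` | log 0.45 | total effect between the two published outcome aRRs (0.48, 0.39) |
| `mediated_fraction` λ | 0.7 | headline share attributed to community norms |
| `norm_shift` δ | −1.0 logit | reproduces a ~51% → ~28% norm contrast |
| `norm_intercept` | 0.0 | control-arm norm level ≈ 50% |
| `σ_pair`, `σ_comm`, `σ_jit` | 0.25, 0.35, 0.30 | artifact choices — no between-community variances are published; chosen to give EA-level prevalence sds of roughly 6–13 points, the order of the published EA summaries |
| `baseline_prevalence` | 0.30 | between the published control-arm outcome prevalences |
| covariate effects | ±0.1–0.35 log scale | modest, keep the clamp rate low |

The clamp rate (risks truncated at 1) is reported per wave and warned
about above 1%; at λ = 0 it is ~0%, at λ = 1 it can reach a few percent
in norm-extreme communities — the warning is the designed surface for
that diagnostic.

## Simulation studies and their sizes

All replicate studies in the test suite and acceptance script use the
default trial size (8 communities × 12 EAs × ~28 respondents, both
waves, ~4,500 respondents per replicate):

* ITT recovery at λ = 0: 500 replicates; the estimator mean is within
  2 Monte-Carlo SEs of 0.45 and 95% CI coverage is ~95% (bounds
  [90%, 99%] asserted).  The simulation-study ITT adjusts for age group
  and marital status.  The baseline-prevalence covariate is *excluded
  there by design*: at λ = 0 the DGP has no between-community outcome
  heterogeneity for it to explain, and with 8 clusters a pure-noise
  community-level covariate in the expected-events model absorbs part of
  the within-pair arm contrast (measured bias ~ +0.03 toward the null).
  The pipeline's default outcome analysis keeps the full covariate set,
  which mirrors the emulated procedure, and coverage remains nominal
  either way.
* Mediation recovery: 500 replicates each at λ = 1 (mean community-norm
  attenuation ≈ 100%, ≥ 80% asserted) and λ = 0 (mean ≈ 1%, within ±15
  asserted).
* Interaction-screen null calibration: 400 replicates, rejection rate
  within 0.05 ± 0.02.

What passing these does and does not show: the generator reproduces the
design geometry, effect sizes and the ecological norm pathway, but not
survey non-response, informative missingness, reporting bias (the
motivation for the anonymous-card measure), EA re-drawing between waves
beyond community-level carryover, or mediator-specific intervention
effects outside the attitude pathway.  Estimator performance under those
features is not certified by this suite.

## Degenerate inputs and numerical choices

* Eligibility predicates are conjunctions of (possibly negated) roster
  flags or previously computed indicators; circular references are
  rejected.
* Missing items: "any of" treats missing as non-qualifying unless every
  item is missing (indicator missing, excluded from numerator and
  denominator); "all of"/composites are missing when any needed item is
  missing, except a determinate false short-circuits.  This follows the
  conservative convention for act-list violence measures; whether the
  original instrument excluded partially missing act lists is not
  published, so the policy is a documented choice.
* Baseline EA summaries are carried at (community × sex) level because
  EAs are re-drawn between waves.
* Degenerate CIs (zero robust variance, exact-fit EA models) are flagged
  rather than silently reported.
* Complete-case covariate handling throughout, with dropped-row counts
  on every fit.

## Known limitations

* Wald-normal intervals for the individual-level robust models (no
  small-G t correction beyond `G/(G−1)`); fine at G ≈ 190 EAs, not
  intended for few-cluster inference — that is what the cluster-level
  estimator is for.
* The attenuation ledger inherits the difference method's limits: single
  mediator at a time, no confounding control beyond the base covariates,
  cross-sectional mediators.
* The generator's single outcome model is shared by both sexes; the
  published sex-specific prevalence difference is not emulated.
* Permutation inference and non-paired designs are out of scope.
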