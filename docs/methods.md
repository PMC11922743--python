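# Methods

## Setting and causal structure

One row per screened woman. Exposure `Z`: the examination was read in
the AI group (at least one of the two radiologists submitted the report
from the AI-supported viewer). Outcomes `Y`: consensus conference,
recall, preoperative biopsy, screen-detected cancer — a monotone
cascade. The assignment is behavioral, not randomized: each reader
chooses a viewer per examination, and the choice depends on the AI
prediction already visible in the worklist (normal-tagged examinations
are preferentially read in the AI viewer). Since the AI prediction
tracks the latent cancer status, this self-selection induces
confounding between group and cancer prevalence ("reading behavior
bias") that biases the crude AI-vs-control comparison downward.

The causal graph (`dag.build_screening_dag`) encodes: age → density,
round, cancer; density, round → cancer; reader set → density
classification, viewer adoption, outcome; latent cancer → AI
prediction, outcome; AI prediction → viewer adoption; supervision →
outcome; latent unknown risk factors → cancer; AI use → outcome (the
effect under study). Under the backdoor criterion the unique minimal
observed adjustment set is **{reader set, AI prediction}**: the AI
prediction is the observable proxy that blocks the path through the
latent cancer status, and the reader set blocks the adoption/competence
paths. The graph implies 12 conditional independences among observed
variables (pairwise-Markov basis: non-adjacent observed pairs given
their observed parents, kept only when the separator actually
d-separates), which `hsic.test_all_implications` tests on data.

## Estimator

Propensity scores `e_i = P(Z=1 | reader set, AI tag)` are fit by
maximum-likelihood logistic regression. Records are first collapsed to
unique covariate patterns (≤ ~1,100 cells for 547 reader sets × 2 tag
values), so Newton iteration operates on cell counts and is exact and
fast at any cohort size; convergence is a relative log-likelihood
change below 1e−8 (max 100 iterations) followed by a guarded polish
phase that drives the score equations toward zero. Completely separated
reader sets (never/always used the AI viewer) are handled by clipping
fitted values away from {0, 1} (bound 1e−9) and surfacing a count —
records are never dropped, and overlap weights send their influence to
zero anyway. A Firth-type penalized fit is available but off by
default. The reference level of every categorical covariate is its
highest-volume category (deterministic).

Overlap (ATO) weights `w_i = z_i(1−e_i) + (1−z_i)e_i` target the
population of clinical equipoise and, at an exact MLE logistic
solution, balance every propensity-model covariate mean exactly between
groups — the package verifies residuals ~1e−9. Group rates are weighted
means, identical (to 1e−10, checked against statsmodels' weighted
quasi-binomial GLM) to the fitted rates of the group-only outcome
regression; the quasi-binomial Pearson dispersion is reported but
inference uses the **stacked sandwich**: estimating equations for the
PS coefficients plus the two weighted moment equations, `V = A⁻¹BA⁻ᵀ`
assembled on (pattern × group × outcome) cells. A fixed-PS variant
(weights treated as known) reduces to the classic two-sample binomial
variance when `e ≡ 0.5`. Alternatives: trimmed IPW (`1/e`, `1/(1−e)`,
records with `e ∉ [α, 1−α]` excluded) and reader-set × tag
stratification with size-weighted combination (precision weighting was
considered; size weighting is the transparent default).

The relative difference `ρ = 100(μ1/μ0 − 1)` takes its CI from the
delta method on `log(μ1/μ0)`, back-transformed — ratio-scale CIs are
asymmetric, matching how screening-rate comparisons are reported; the
exact transform used by comparable published analyses is typically
unstated, so CI widths may differ slightly from other software in the
second decimal. `ρ` is flagged undefined when `μ0 = 0` (then no
noninferiority verdict is issued). Noninferiority margin: ±10%
relative; detection (higher is better) is noninferior iff the CI lower
bound exceeds −10 and superior iff it exceeds 0, recall mirrored.
Model-based PPVs are ratios of model-based rates with a woman-level
bootstrap CI (the two endpoints share weights, so they are resampled
jointly with the PS refit per replicate). Subgroup analyses refit the
propensity model within each level (the stricter reading; reusing the
full-cohort fit is available via `refit_ps=False`). Category
decompositions (invasiveness, stage, grade, size) treat each category
as its own binary detection outcome under shared weights, so the
per-category rates sum exactly to the total.

## Synthetic-data generator

Generative order (matching the causal arrows): covariates → latent
cancer → AI score → worklist tags → per-reader viewer adoption → group
derivation → reading outcomes. One master seed; every stage draws from
an independently spawned substream, so adding a stage never perturbs
earlier draws.

- **Cohort structure.** 547 reader sets drawn from a log-normal volume
  distribution (σ = 1.2, truncated at 9,000; mean volume ≈ 844) over
  119 readers; 5% of examinations supervised. Age is two bands
  (50–59: 43.8%, uniform within band — the published age summaries are
  internally inconsistent (median 58 with only 43.8% under 60), so the
  band fraction used by the subgroup analyses is matched and the
  within-band shape kept flat); density (dense: 42%/28% by band,
  overall ≈34%) and first-round probability (30%/7%, overall ≈17%)
  depend on the band.
- **Latent cancer.** Screen-detectable prevalence 0.0067 at the
  reference cell with rate ratios 1.35 (age 60–69), 1.25 (dense), 1.40
  (first round); marginal prevalence ≈0.0079.
- **AI score.** Non-cancer scores Beta(2, 40); cancer scores a 97/3
  mixture of Beta(8, 3) and the non-cancer component (the "AI miss"
  fraction — without it no cancer could ever be normal-tagged, contradicting
  observed screening AI behavior where ~1.5% of detected cancers carry
  the normal tag). Thresholds are the empirical 60% and upper-1.5%
  quantiles of the cohort's own scores, so realized tag rates equal the
  targets by construction; `expected_marginals` solves the same
  thresholds on the analytic mixture CDF.
- **Reading behavior.** Reader `j` of set `k` opens the AI viewer with
  probability `expit(α_k + β·normal_tag)`, `α_k ~ N(−0.80, 1.5²)`,
  `β = 0.326`; the two readers decide independently and the group is
  "AI" if either used it. This reproduces an AI-group share ≈56.5% and
  the normal-tag split ≈59%/53% (AI/control) — the bias mechanism.
- **Reading cascade.** Per-reader flag probabilities 0.45 (cancer) and
  0.121 (benign), the benign rate multiplied by 0.188 in the low-score
  (normal-tag) region — reader false-positives concentrate on
  ambiguous, higher-score examinations, which is what makes triage
  automation cheap in recalls; supervision multiplies flag rates by
  1.1. Consensus retention to recall: 0.95 (cancer) / 0.316 (benign);
  biopsy 0.97/0.110; histological confirmation 0.95.
- **The intervention (mechanistic mode).** Safety net: triggered
  examinations in the AI group whose readers flagged nothing are shown
  an alert with probability 0.85 and accepted with probability 0.51,
  escalating to consensus (retention 0.95 cancer / 0.45 benign).
  Normal-tag suppression: AI-using readers multiply their benign flag
  rate by a further 0.388 on normal-tagged examinations (automation
  bias reducing false recalls). These two mechanisms produce a true
  ATO detection ratio of 1.18 and recall ratio of 0.975.
- **Ratio mode.** For the simulation study the mechanism is replaced by
  a uniform multiplicative scaling of the cancer cascade
  (`detection_ratio`) and benign cascade (`recall_ratio`) for AI-group
  examinations via a nested-uniform construction, making the true
  causal rate ratio a configured constant.
- **Placebo.** `placebo_config` nulls the acceptance probability, the
  suppression and the ratio multipliers while preserving the adoption
  model: the crude comparison stays biased (≈−13.7% analytically) while
  the true effect is exactly zero.

All defaults were calibrated once, by coordinate-wise root-finding on
the analytic `expected_marginals` composition (Gauss–Hermite quadrature
over `α`, exact enumeration of the discrete states), against the
published program marginals: crude detection 6.2/1,000, recall
41.9/1,000, consensus 11.8%, biopsy 10.4/1,000, group normal-tag split,
and the automation-scenario recall ratio 0.85.

**What the generator does not emulate:** per-lesion and image-level
structure, reader learning over time, inter-reader correlation beyond
the shared reader-set intercept, covariate-dependent reading
performance, interval cancers and next-round outcomes, and the
real study's exact joint distribution of covariates and outcomes.
Passing tests therefore show that the estimator machinery is correct
under the assumed mechanism, not that the mechanism captures every
feature of real screening data.

## Numerical and design choices

- Weighted-rate/GLM equivalence is exact because the outcome model is
  saturated in the group indicator; the package computes weighted means
  and reserves the GLM for cross-checks.
- The sandwich solve falls back to a pseudoinverse when the stacked `A`
  matrix is exactly singular (redundant indicator directions, e.g.
  constant covariates); non-finite results raise.
- Conditional independence tests stratify on discrete conditioning
  variables only (all conditioning variables in the screening graph are
  discrete; age enters as yearly values), sum per-stratum biased HSIC
  statistics weighted by 1/n_s, permute within strata, and skip strata
  below 10 records; marginal tests subsample to 2,000 records to keep
  kernel matrices small. Permutation p-values use (1 + #{≥ obs})/(B+1);
  a moment-matched gamma null is the fast option.
- Display rounding (one decimal, half away from zero) is applied only
  at presentation; all computation keeps full precision.
- Simulation-study and coverage checks run at n = 20,000 with 40 reader
  sets and 150–500 replicates; the pipeline checks at n = 400,000 —
  problem sizes chosen so the full suite completes in minutes while MC
  error stays well below the tolerances tested.
- Coverage is evaluated where the true estimand is known exactly:
  ratio-mode cohorts (configured ratio) and the placebo null.

## Known limitations

- With per-reader adoption the true group propensity
  `1 − (1 − expit(α_k + βt))²` is not exactly additive-logistic in
  (set, tag); the main-effects PS model is therefore mildly
  misspecified by construction. The residual bias is far below sampling
  noise at the sizes used (coverage stays in the nominal band), and a
  saturated set × tag interaction fit is available.
- The automation scenario transforms AI-group records only, keeping the
  observed control group as comparator (a both-groups option is easy to
  add but changes the comparator's meaning).
- The placebo analysis on observed data is a within-stratum label
  permutation — a construction that provably preserves the propensity
  structure while nulling the effect; other placebo constructions are
  possible.
- PPV-of-biopsy values published for the modeled study are not exactly
  reproducible from its own counts (numerator definition unstated); the
  package computes detected cancers / biopsies recommended and does not
  force agreement.
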