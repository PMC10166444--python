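# Methods

`promort` implements a mortality-risk analysis for oncology cohorts in which
structured EHR data exist for every patient but patient-reported outcomes
(PROs) exist only for the subset who completed an assessment — a two-phase
sampling structure with informative (non-representative) completion.  This
note documents the statistical procedures, the synthetic-data generator that
stands in for the (non-deposited) clinical data, the default parameters, and
the limits of what the simulations demonstrate.

## Outcome and data structure

One row per patient at an index encounter.  The outcome is death within 180
days (binary).  Phase-1 covariates are ~200 EHR features: binary
demographic/comorbidity indicators and continuous laboratory values.
Phase-2 covariates are 12 PRO items: 11 symptom/function items coded 1–5
(higher = worse) and a 0/1 rash item, present only when `pro_complete = 1`.

## The three risk models

**EHR model — adaptive-LASSO logistic regression.**  On a 70/30
outcome-stratified split, the training part is fitted in two stages:

1. a ridge-stabilized logistic fit on standardized features (per-sample L2
   penalty `stage1_alpha = 1e-3`) yields initial coefficients β̃;
2. an L1-penalized logistic fit with per-feature penalty weights
   w_j = 1/|β̃_j|^γ (γ = 1 by default), implemented by rescaling column j by
   |β̃_j|^γ and fitting a plain LASSO.  Features with w_j above `weight_cap`
   (default 1e8) are excluded outright; the intercept is never penalized.

λ is chosen by 5-fold outcome-stratified cross-validated log-loss over a
log-spaced grid (1e-4.5 … 1e-1.5, 8 points), with the one-standard-error
rule (largest λ within one SE of the CV minimum — the parsimonious glmnet
convention; `lambda_rule="min"` is available).  Coefficients below 1e-8 on
the standardized scale are snapped to zero, and reported coefficients are
de-standardized to the original feature scale.  Stratification of the split
guarantees cases in both parts at ~5.7% prevalence; `split_cohort` refuses
splits that would leave a part without cases or controls.

**PRO model.**  Unpenalized logistic regression of the outcome on all 12
PRO items as linear covariates, fitted on training completers (Newton via
statsmodels).  With 12 covariates and thousands of completers no penalty is
needed; a separation fallback (`ridge=1e-6`) is available.

**EHR+PRO model — two-phase IPW.**  Because completion is informative, the
combined model is fitted and evaluated with inverse-probability weights:

1. *Selection model*: logistic regression of `pro_complete` on the EHR
   model's linear predictor (logit risk) plus a configurable covariate list
   (default: the first demographic indicator), fitted on the same cohort the
   weights will be applied to.
2. *Weights*: w_i = 1/p̂_i for completers, truncated at the 1st/99th
   percentiles of the completer weight distribution.  The weight sum
   estimates the full-cohort size (Horvitz–Thompson).
3. *Model*: weighted logistic regression of the outcome on the EHR logit
   (coefficient estimated, not fixed at 1) plus a PRO subset chosen by
   weighted backward elimination at α = 0.05 using robust (HC1 sandwich)
   Wald tests; the EHR logit is never eliminated.  Fitting uses training
   completers only, preserving the holdout.
4. *Evaluation*: weighted AUC/AUPRC/TPR/FPR over test completers with
   weights from a selection model refitted on the test cohort, so the
   estimates represent the complete test set.  The bootstrap resamples test
   patients (completers and non-completers) and re-estimates the selection
   model and weights inside each resample, so weight-estimation uncertainty
   is inside the intervals.

IPW is the classical two-phase design estimator; the selection model,
weights and weighted fits are separate small functions so an augmented or
calibration estimator could replace the weighting without touching the rest.
With completely-at-random completion the weights are constant and every
estimate reduces exactly to its unweighted complete-case counterpart (tested
to 1e-8 against an unweighted statsmodels fit).

## Association analyses

Inter-PRO correlations are Spearman rank correlations over completers
(items are ordinal; any strictly monotone recoding leaves the matrix
unchanged).  A constant item yields NaN, not 0.  Univariable odds ratios
come from a logistic fit of the outcome on one PRO (per-Likert-step OR,
95% Wald CI).  Adjusted odds ratios add the EHR-predicted risk **on the
log-odds scale**: on that scale a correctly specified EHR model is exactly
linear, so a PRO that carries no information beyond EHR risk has a null
adjusted effect; adjusting for the probability instead leaves residual
nonlinearity that a correlated PRO would spuriously absorb.

## Performance metrics

All metrics take optional per-patient weights and reduce exactly to the
unweighted definitions for constant weights.

- **AUC**: weighted Mann–Whitney concordance, ties credited ½, computed in
  O(n log n); invariant to strictly increasing score transforms (tested to
  1e-12) and equal to an O(n²) pairwise oracle on random instances.
- **AUPRC**: area under the weighted precision–recall step curve, precision
  evaluated at each distinct score cut, no interpolation (interpolation
  conventions materially change AUPRC at ~6% prevalence).  Constant scores
  give exactly the weighted prevalence.
- **TPR/FPR**: flag rule `score >= t`, closed on the left, default
  t = 0.10 — the pre-specified clinical threshold for triggering
  serious-illness conversations.
- **Bootstrap CIs**: percentile 2.5/97.5 over 1,000 seeded patient-level
  resamples by default; weights travel with their patient; resamples
  lacking a class are redrawn (counted); all four metrics share resamples
  within a report.  Percentile bounds are expanded, if needed, to contain
  the point estimate so reported intervals always bracket reported values.

## Decision curves

Standardized net benefit at risk threshold t with prevalence π:

    sNB(t) = TPR(t) − [t/(1−t)]·[(1−π)/π]·FPR(t)

sNB ≤ 1 with equality only at (TPR, FPR) = (1, 0), and sNB(t=π) = TPR − FPR.
The default grid is 0.01–0.50 in steps of 0.01; prevalence defaults to the
weighted prevalence of the evaluation population and can be overridden.  In
the pipeline all three models' curves are computed on the same population —
test completers with IPW weights — so the comparison is apples-to-apples and
representative of the full test set; the dominance summary reports, per
threshold, which model attains the maximal sNB (ties reported, not broken).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes; it is the study
environment for every test.

- **EHR features**: independent Bernoulli indicators (first two default to
  p = 0.67 and 0.31 — a White/managed-care-like pair) and standard-normal
  labs.  The mortality contribution is sparse: four comorbidity indicators
  (log-odds 0.625–1.0) and twelve labs (0.19–0.875).
- **PRO items**: a Gaussian copula.  Item j's latent value is
  l_j·z + √(1−l_j²)·u_j where z is the standardized EHR mortality score and
  u has its correlation adjusted so the total latent correlation equals the
  configured target exactly (named pairs from observed clinical data, e.g.
  performance status–fatigue 0.69, anxiety–sadness 0.72; other symptom pairs
  0.30; rash 0.10).  Likert items are the latent values cut at per-item
  thresholds (default cell masses 0.40/0.25/0.18/0.10/0.07, skewed toward
  mild, clinically typical); rash is cut at ~15% prevalence.  Discretization
  attenuates the observed Spearman correlation below the latent target; the
  attenuation is pinned by a brute-force Monte-Carlo oracle in the tests.
- **Mortality**: Bernoulli with logit = baseline + X·β_EHR + codes·β_PRO.
  Conditional per-step PRO effects are nonzero for exactly four items
  (performance status OR 1.53, quality of life 1.45, numbness/tingling
  1.30, nausea 1.25 — the adjusted-OR range reported for real cohorts), and
  the risk loadings (l = 0.12 for symptom items, 0.05 for rash) generate the
  larger *marginal* univariable ORs (≈1.5–2.0) plus the positive
  PRO–EHR-risk association seen clinically.  Setting conditional effects to
  the marginal OR magnitudes instead would make the joint PRO signal
  overwhelm the EHR signal and invert the observed model ordering, which is
  why marginal associations are generated rather than assumed.
- **Completion**: Bernoulli with logit = intercept + 0.5·(White-like
  indicator) − 0.35·z, i.e. completers are enriched for the demographic
  indicator and for *lower* EHR risk — informative selection, the condition
  the two-phase machinery exists to correct.
- **Calibration**: the baseline log-odds and selection intercept are solved
  by Brent's method against one Monte-Carlo draw of 200,000 patients so the
  expected prevalence and completion rate hit their targets (tertiary 5.7%
  and 54.7%; community 3.2% and 31.4%) to within Monte-Carlo error;
  unattainable targets raise an error reporting the achievable range.
- **Determinism**: one `numpy` Generator drives everything; identical
  (config, seed) gives bit-identical cohorts.

`complete_data` carries every patient's PRO items and true linear
predictors.  It exists only because the simulation knows them; it is the
full-information oracle against which the two-phase estimator's bias is
measured and never feeds any fitting path.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: longitudinal encounters and PRO trends,
item-level missingness among completers (completers answer all 12 items),
realistic lab distributions or coded comorbidity ontologies, measurement
error in death ascertainment, and site differences beyond
prevalence/completion levels.  Selection depends only on phase-1 variables
(missing-at-random given the EHR); if real completion depended on the PRO
values themselves, no phase-1 selection model — ours included — would remove
the bias.

## Default problem sizes

Defaults mirror the emulated study: tertiary n = 8,555 with a 70/30 split,
community n = 3,795 evaluated in-sample (too few cases to split, flagged as
in-sample in the report), risk threshold 0.10, 1,000 bootstrap resamples.
Replicate studies in the test suite run at the sizes stated with each
property (50–300 replicates; reduced EHR feature counts where the property
does not depend on feature dimension); `scripts/acceptance.py` runs both
sites at full size with 200 bootstrap resamples.

## Numerical choices

- Logistic solvers: liblinear (L1), lbfgs (ridge/unpenalized), statsmodels
  Newton (inference fits); tolerances 1e-8–1e-10.  Divergent L1 fits
  (|coef| > 1e6 or non-finite) raise with advice to raise the λ floor.
- Risks are clipped to the open interval (0, 1) before use.
- p̂ in weighting is floored at 1e-12; the truncation ceiling then bounds
  the weight.
- TPR/FPR sums are clipped to [0, 1] against float summation noise.
- Ties: AUC groups tied scores and credits ½; dominance ties are reported
  as joint winners with tolerance 1e-12.
- Degenerate inputs: completion rate 0 or 1 yields a degenerate selection
  model with unit weights and a warning; constant features are dropped from
  the adaptive LASSO with a warning and recorded in metadata; fewer than 20
  completer cases aborts the combined fit.

## Known limitations

- The IPW estimator is unstable when some completion probabilities approach
  0; truncation bounds the variance at the cost of a small bias (visible as
  a ≲0.01 negative AUC bias in the correction studies).
- Backward elimination at α = 0.05 is a pragmatic subset rule; it inherits
  the usual instability of stepwise selection in small completer samples
  (the selected PRO subset varies across replicates around the four
  truly-informative items).
- The community-site analysis is in-sample and optimistically biased by
  construction; it is flagged as such rather than corrected.
- No calibration assessment (slope, Hosmer–Lemeshow) and no survival-time
  modeling; the outcome is fixed-horizon binary by design.
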