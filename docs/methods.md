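# Methods

## Model and estimation

The measurement model is the saturated G-DINA: item *j*'s success
probability depends on the respondent's latent attribute profile only
through the reduced pattern over the K\*ⱼ attributes the Q-matrix assigns to
the item, and the mapping from reduced pattern to probability is fully
saturated (intercept, main effects, all interactions under an identity,
logit or log link).  Internally each item is parameterized directly by its
2^K\*ⱼ reduced-class success probabilities P\_j; delta coefficients under any
link are recovered exactly as δ = M⁻¹ g(P), where M is the full-factorial
design matrix.  Because the saturated model makes every link a bijective
reparameterization of the same probabilities, link-specific quantities
(e.g. the log-link deltas needed for a RRUM Wald test) never require a
refit — they are obtained by transformation, with covariances mapped by the
delta method.

The attribute distribution is either

- **saturated**: a free probability vector over the 2^K latent classes
  (closed-form M-step), or
- **higher-order 2PL**: attributes conditionally independent given a single
  normal trait θ, P(αₖ=1|θ) = logistic(aₖθ + dₖ), integrated over 19 equally
  spaced quadrature nodes on [−4, 4] with normalized normal weights
  (configurable).  The M-step solves one two-parameter weighted logistic
  likelihood per attribute (L-BFGS-B, slope bounded to [0, 25]).

EM alternates exact-enumeration posteriors over the 2^K classes with these
M-steps.  Monotonicity ("an added mastered attribute never lowers success")
is imposed *inside* the M-step as the order-constrained binomial MLE.  By
the generalized pool-adjacent-violators equivalence this equals the
count-weighted least-squares isotonic projection of the raw conditional
proportions over the subset-inclusion partial order (solved by SLSQP on at
most 2^K\* variables, only when the unconstrained update violates a cover
relation).  Solving the constrained M-step — rather than projecting after
the fact — preserves the EM ascent property, and the stored log-likelihood
trace is checked to be nondecreasing in the tests.

Numerical choices: probabilities clipped to [1e-10, 1−1e-10] inside
likelihoods; convergence when the largest absolute parameter change falls
below 1e-4 (at most 2000 iterations, flagged rather than raised on
non-convergence); starting values spread the observed item mean
monotonically over reduced classes with a small seeded jitter, which fixes
the mastery orientation and makes fits reproducible given a seed.  The free
parameter count used by all fit indices is Σⱼ 2^K\*ⱼ item parameters plus
2K (higher-order) or 2^K − 1 (saturated) structural parameters.

## Standard errors

All covariances come from the marginal likelihood: per-person scores with
respect to every item probability and every structural parameter are
assembled jointly, and the reported covariance is the sandwich A⁻¹BA⁻¹ with
B the outer product of scores and A the observed information (numerical
Hessian of the analytic score).  The joint treatment matters: inverting
per-item OPG blocks in isolation understates variance noticeably for
designs whose latent classes are weakly separated, and the item-level Wald
tests then over-reject.  With the sandwich, the additive-model Wald test
holds its nominal 5% size (measured ≈3-9% across designs in the acceptance
suite).  Items with boundary probabilities get NaN markers instead of SEs.

## Q-matrix validation (PVAF)

For each item, class weights and per-class success probabilities are
estimated non-iteratively from the fitted posterior (expected counts and
successes per latent class).  For a candidate q-vector the discrimination
index ζ²(q) is the weight-weighted variance of the class success
probabilities collapsed to the candidate's reduced classes, and
PVAF = ζ²(q)/ζ²(full).  This construction makes PVAF exactly 1 for the full
vector and monotone under candidate supersets (collapsing is a coarsening,
checked by a property test).  The mesa suggestion is the simplest candidate
reaching the cutoff (default 0.95); ties at equal simplicity go to the
larger PVAF, then lexicographic order.  Flat items raise an explicit
undefined-PVAF error.

## Absolute fit

SRMSR is the root mean squared difference between observed and model-implied
item-pair Pearson correlations (implied moments by exact class
enumeration).  The residual table reports per-pair Fisher-z residuals with
Holm-adjusted two-sided p-values.  M2 is the limited-information quadratic
form on first- and second-order margins with the model-implied multinomial
covariance and the margin Jacobian with respect to all free parameters.
One subtlety: for Q-matrices without single-attribute anchor items the
margin Jacobian is rank-deficient (some parameter directions do not move
any univariate or bivariate margin), so the degrees of freedom are
s − rank(Jacobian), not s − #parameters; with nominal counting the
statistic is materially over-sized, with the rank-based df it calibrates at
the nominal level (checked at 200 replicates in the acceptance suite).
RMSEA2 = sqrt(max(M2 − df, 0)/(N df)) with a noncentrality-inversion 90% CI.

## Reduced item models

DINA (intercept + top interaction only), DINO (all non-intercept terms the
alternating-sign multiple of the first main effect, i.e. two success
levels), and the additive models ACDM/LLM/RRUM (no interactions under
identity/logit/log) are expressed as linear restrictions Rδ = 0 in the
link each model implies.  The item-level Wald statistic is
(Rδ̂)ᵀ(RΣ̂Rᵀ)⁻¹(Rδ̂) with Σ̂ from the sandwich covariance; a singular
restriction covariance falls back to a pseudo-inverse with a flag.  The
recommendation per item is the model with the largest p among those not
rejected at α (default 0.05), with the saturated G-DINA as fallback;
single-attribute items are marked not applicable since every reduced model
coincides there.

## Outcome rule and incremental prediction

The binary outcome is "decreased quality of life": change = T1 − T0 of the
0-144 instrument total, outcome 1 iff change ≤ −(0.5 × SD of change), SD
with the n−1 denominator, computed per cohort by default (pooled
optionally).  Model 1 (TNM + total score) and Model 2 (TNM + the K mastery
probabilities) are maximum-likelihood logistic fits (statsmodels Newton,
separation detected and flagged).  AUC uses the tie-aware rank formula;
the paired AUC test uses DeLong placement values; NRI is the category-free
version (no risk categories exist for this outcome) with a multinomial
variance for its z; IDI is the discrimination-slope difference with the
usual two-group SE; the Brier score is reported ×100.  Decision curves use
net benefit TP/N − (FP/N)·t/(1−t) on a 0.01-0.99 grid with treat-all /
treat-none references, and the clinical impact curve re-expresses the
high-risk count and the true events among them per 1000 patients.
Performance is apparent (in-sample) per cohort, matching the single-sample
presentation the pipeline emulates; CDPs come from the pooled measurement
fit by default.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not any real dataset:

- **Design**: four cohorts of 151/95/111/135 (defaults), one shared seed
  expanded into per-cohort, per-stage substreams.
- **Attributes**: higher-order 2PL with slopes 1.5 and intercepts
  (0.98, −0.47, −0.24), giving mastery prevalences near 68/41/46%.
- **Items**: 10 bifactor items (each one specific attribute + the general
  factor).  Default reduced-class success probabilities have guessing
  floors 0.05-0.12, ceilings 0.92-0.97, and a general-factor main effect
  clearly larger than the specific one.  The separation is deliberate: an
  all-two-attribute bifactor Q-matrix has no single-attribute anchors, and
  when the two intermediate reduced classes have similar success
  probabilities the latent structure is nearly unidentified at realistic
  sample sizes.
- **Likert layer**: binary responses are emitted as 5-point categories
  (1→{4,5}, 0→{1,2,3}) so that dichotomizing at ≥4 recovers the binary
  data exactly; the real instrument's dichotomization rule is not public,
  so this layer is a stand-in that lets the pipeline exercise the step.
- **Outcome**: baseline total ~ N(98, 14) clipped to [0, 144]; change =
  10 − 40·logistic(η) + N(0, 5) with η = −0.3 + 0.55·(TNM − 2) +
  (0.8, −1.0, −3.0)·α, then clipped and re-differenced so the stored
  outcome always satisfies the SD rule bit-for-bit.  The mixed-sign
  attribute coefficients are the package's design choice for the
  demonstration: a profile pattern with opposing effects is exactly the
  signal an equally weighted total score cannot express, so the mastery
  probabilities carry incremental predictive value.  Outcome prevalence is
  ≈35-40%.

What the generator does **not** emulate: item wording or real item
difficulty estimates, attrition/missingness (cohorts are complete),
DIF across cohorts, and any association between the latent trait and TNM
stage.  Passing tests therefore demonstrate the correctness and calibration
of the methods under the assumed data-generating structure, not the
clinical findings themselves.

## Simulation sizes used in tests

The acceptance suite uses: brute-force oracle checks at 5 persons (exact to
1e-10); parameter recovery at n=2000, 100 replicates, with homogeneous
high-quality recovery items (reduced-class probabilities 0.02/0.25/0.75/0.98
and a uniform attribute population — chosen a priori so the weakly anchored
bifactor design is strongly identified, see above); Q-validation recovery
at n=2000, 60 replicates; M2 and Wald size at n=1000/2000, 200 replicates;
and the prediction-direction check on 25 four-cohort replicates.  The whole
suite runs in a few minutes on one CPU.

## Known limitations

- The bifactor Q-matrix without anchor items is weakly identified; at small
  n the higher-order slopes and the rare "(specific mastered, general not)"
  class probabilities carry large sampling variance.  This is a property of
  the design, not the estimator (recovery is clean with complete Q-matrices
  or at large n).
- The LR degrees of freedom between the bifactor and non-bifactor
  specifications depend on the structural parameter-counting convention
  (24 under saturated structural, 22 under higher-order 2PL); both are
  implemented and reported as counted.
- Plots (mesa, heatmap, ROC/DCA images) are not produced; every figure's
  underlying table is written as delimited text or JSON instead.
- Polytomous CDMs, missing-response weighting, DIF detection and CDM-based
  adaptive testing are out of scope.
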