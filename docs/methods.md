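# Methods

## Estimands and models

The target quantities are the counterfactual 5-year diabetes risks
Pr(Y^a = 1) under each blood-pressure category *a*, their difference (ATE)
and their ratio (RR). Identification assumes no unmeasured confounding given
the baseline covariate set L = {age, sex, marital status, education,
economic status, smoking, BMI}, positivity, consistency, and censoring that
is ignorable given L.

Weights are stabilized: SW_i = Pr(A = A_i) / Pr(A = A_i | L_i) for
treatment, times Pr(C = 0) / Pr(C = 0 | L_i) for censoring. The generic
marginal(level)/conditional(own level) form covers the binary (JNC-7) and
three-level (JNC-6) analyses uniformly and reduces algebraically to the
familiar exposed/unexposed two-branch formula in the binary case (property
tested). The censoring-weight numerator is the overall marginal probability
of remaining under observation; conditioning it on exposure is available via
`censor_numerator="exposure"` but is not the default. Weights are not
truncated by default; percentile winsorization is available for robustness
studies and records how many weights it touches.

Per-level risks use the Hajek (ratio) estimator, which is invariant to
weight rescaling and the natural companion of stabilized weights. The ATE's
standard error comes from the influence functions of the two Hajek means,
summed within sampling clusters (weights treated as fixed). The RR comes
from a weighted log-link binomial GLM containing only exposure indicators —
a marginal structural model; confounders act exclusively through the
weights — with a cluster-robust sandwich variance. For the saturated
(indicator-only) model the GLM RR equals the ratio of Hajek risks to
numerical precision, which the tests assert; the two routes are kept
separate deliberately, mirroring common practice of estimating the RD and RR
with different estimators.

Treating the estimated weights as fixed ignores propensity-estimation
uncertainty; for treatment-effect contrasts this is conservative. A cluster
bootstrap (whole clusters resampled with replacement, seeded, default 999
replicates) is provided as an alternative interval method. Cluster-robust
covariances apply no small-sample correction factor; with hundreds of
clusters the G/(G−1) factor is ~1.003 and the omission makes the
record-level-cluster case coincide exactly with HC0. The two-sided
significance level is fixed at 0.05 throughout; no multiplicity adjustment
is applied to the two prespecified JNC-6 contrasts.

## Numerical choices

* **Spline basis.** Age enters the exposure model through a 3-knot
  restricted cubic spline in Harrell's truncated-power form, normalized by
  (k₃−k₁)²; knots default to the 0.10/0.50/0.90 quantiles. Any full-rank
  reparameterization yields identical fitted probabilities, so tests assert
  on predictions, not coefficients.
* **Design matrices.** Built directly (no formula language): intercept
  first, main terms in spec order, then interaction columns as elementwise
  products; dummy coding drops a named reference level (economic status:
  high). The fitting-time design info (knots, levels) is reused at predict
  time; unseen categorical levels raise.
* **GLM fitting.** Logistic, multinomial-logit and log-binomial models are
  maximized by IRLS/Newton (statsmodels) with tolerance 1e-8 (1e-10 for the
  log-binomial) and a 100-iteration cap; hitting the cap sets a
  `converged=False` flag rather than raising. Rank-deficient designs raise
  naming the collinear columns; |coefficient| > 30 on the logit scale is
  flagged as likely separation. Predicted probabilities are clipped to
  [1e-6, 1−1e-6] (configurable) before weight division, with clipping
  events counted.
* **Log-binomial boundary failures.** The log link does not respect the
  binomial domain; the fit starts at the weighted marginal risk and, on
  non-convergence or fitted risks reaching 1, falls back to a log-link
  Poisson working model ("modified Poisson") with the same cluster sandwich,
  tagging the estimate's method string. With indicator-only marginal
  structural models the primary path essentially always converges.
* **Degenerate inputs.** Constant outcomes, empty exposure levels, single
  clusters, zero cells in crude 2×2 tables, and all-missing glucose data
  raise informative errors rather than returning silently defaulted values.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with the
published baseline table as its default marginals:

| quantity | default | source/rationale |
|---|---|---|
| n, clusters | 2,941 / 300 | cohort size; cluster sampling design |
| age | truncated normal, observed mean 49.6, SD 5.9, range 40–64 | published marginals |
| BMI | truncated normal 27.4 ± 4.7, range 15–50 kg/m² | published marginals |
| male / smoking / married | 0.428 / 0.137 / 0.90 | published marginals; marital share not published, set to a realistic 0.90 |
| education | truncated normal 7.6 ± 4.6 y, ≥ 0 | published marginals |
| economic status | high/medium/low 0.474/0.278/0.248 | published marginals |
| exposure prevalence | 0.536 | 1,577/2,941 exposed |
| exposure slopes | age 0.03/y, BMI 0.07 per kg/m², male 0.43, smoking −0.20, education 0.005 (logit) | chosen so the exposed-unexposed contrasts match the published ones (≈ +1.1 y, +1.4 kg/m², +10 pp male) |
| cluster effect | SD 0.15 on the exposure logit | mild within-cluster correlation |
| outcome | log-risk model, baseline risk 0.10, slopes age 0.02, BMI 0.05, male 0.15 | ~10% 5-year incidence |
| exposure effect | log RR = log 1.30 (three-level: 0 and log 1.30) | near the published high-normal estimate scale |
| censoring | logistic, marginal 0.10, slopes age 0.05, BMI 0.04, smoking 0.15 | 295/2,941 lost; informative in age/BMI |

Because truncation on [40, 64] (and at 0 for education) is asymmetric, the
parent location of each truncated normal is solved so the *realized* mean
hits the published value. All intercepts are calibrated numerically (brentq
/ closed form) against the target marginals on a fixed 200,000-draw
covariate sample, so they are deterministic functions of the configuration,
not tuning knobs. Configurations whose log-risk model implies a risk ≥ 1
anywhere in the generated sample are rejected with an error.

Potential outcomes for every exposure level are drawn with a shared uniform
per subject (common random numbers), so each cohort carries a sharp
finite-sample truth; the cohort's causal truth averages the risk functions
over the covariate draw and is independent of any fitted model.
`true_marginal_effects` evaluates the generating law itself by Monte Carlo
(n ≥ 10⁶ by default) with reported MC error. Under the log link with a
covariate-constant effect the marginal RR equals exp(coefficient) exactly
(ratio-scale collapsibility), which the recovery experiments use as the
analytic truth. SBP/DBP readings and baseline labs are back-constructed to
be consistent with the assigned category and non-diabetic baseline; the
analysis uses only the category, so this is cosmetic fidelity to the CSV
schema.

What the generator does *not* emulate: the real joint dependence structure
beyond these marginals and the specified confounding paths, measurement
error in BP or labs, competing mortality as a distinct outcome (deaths are
folded into censoring, as in the source analysis), and exposure-dependent
censoring. Passing recovery tests therefore demonstrates estimator
correctness under the assumed data-generating law, not robustness to
violations of it.

## Validation experiments

* **Parameter recovery** (default conditions: true marginal RR 1.30,
  n = 3,000, 500 replicates): mean IPTW log-RR bias, empirical 95% CI
  coverage, crude-estimator bias (which shows the built-in confounding,
  ~0.10 on the log scale), and the mean stabilized weight. The replicate
  size n = 3,000 matches the cohort scale; 500 replicates put the MC error
  of the mean bias near 0.005.
* **Censoring robustness** (200 replicates, censoring slopes amplified to
  age 0.12, BMI 0.10 at the same 10% rate): compares, on the same cohorts,
  counterfactual risk estimates with the combined weight versus the
  treatment weight alone. The comparison targets the *risks* rather than
  the RR because, with a ratio-constant effect, covariate-driven selection
  scales both arms' risks almost equally and largely cancels in the ratio —
  informative censoring bites the risks and the ATE.
* **Oracle equivalence**: on fully enumerated discrete populations with
  exact propensities, Hajek IPTW risks equal g-formula standardized risks to
  1e-12, and the saturated weighted log-binomial RR equals the Hajek risk
  ratio to 1e-10.

## Known limitations

* Propensity and censoring models must be correctly specified; no doubly
  robust estimator is provided.
* Weight uncertainty is not propagated into the intervals (conservative for
  effect contrasts); the cluster bootstrap is the available alternative.
* The analysis is a single-time-point design: one baseline exposure, one
  follow-up, binary cumulative incidence. No time-varying treatments,
  no survival modelling, no competing risks.
* The JNC-6 multinomial analysis shares one censoring model across levels.
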