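# Methods

## The problem

Two-sample Mendelian randomization (MR) estimates the causal effect of an
exposure E₁ on an outcome D from GWAS summary statistics, using genetic
variants as instruments. Because genotype is fixed at conception but GWAS
participants are recruited decades later, everyone who died before
recruitment — from their genetic endowment, the exposure, the outcome
itself, or a competing risk — is missing. Analysing survivors conditions
on a collider (survival), which re-opens a backdoor path from the
instruments to the outcome, violates the exclusion restriction, and can
attenuate, erase, or reverse MR estimates. `selectmr` implements (i) a
generative model of this survival selection, (ii) the standard two-sample
MR estimation stack, (iii) a hazard-ratio grid experiment quantifying the
induced bias, and (iv) a control-exposure audit that flags result
patterns diagnostic of selection bias.

## Data-generating process

For each of `n` individuals:

* **Genotypes.** `m` independent SNPs, counts `G_j ~ Binomial(2, maf_j)`
  under Hardy–Weinberg; MAFs default to Uniform(0.1, 0.5) draws. No
  linkage disequilibrium is simulated, so the r² < 0.01 independence
  criterion of instrument selection holds by construction.
* **Confounders.** A measured confounder `C ~ N(0,1)` of the
  exposure–outcome relation and an unmeasured confounder `U ~ N(0,1)`
  shared between the outcome and a competing-risk liability
  `CR = psi_u_cr·U + noise` (unit variance; default `psi_u_cr = 0.5`).
* **Exposures.** Up to three standardized exposures,
  `E_k = Σ_j γ_jk G_j + phi_c_e·C + ε_k`. The per-allele effects are
  rescaled so the instruments explain exactly `r2_ge` of each
  instrumented exposure's variance (default 0.1, a typical aggregate
  instrument strength for a molecular trait) and the residual variance
  makes Var(E_k) = 1, so causal effects are per exposure SD. The e1/e2
  residuals can be correlated (`antagonist_rho`, negative for a
  biochemical antagonist); a configuration whose residual variance would
  be negative (r2_ge + phi_c_e² > 1) is rejected with the offending
  exposure named.
* **Outcome.** Linear predictor
  `lp = β₁E₁ + β₂E₂ + β₃E₃ + phi_c_d·C + psi_u_d·U`. Continuous D adds
  N(0,1) noise. Binary D is Bernoulli with a logistic link whose
  intercept is solved numerically so the sample prevalence equals
  `d_prevalence`; disease is realized *before* selection, reflecting that
  people diagnosed with or dead from the outcome are never recruited.
* **Survival to recruitment.** Death times are exponential with rate
  `λ₀·exp(η)`, recruitment horizon fixed at one time unit, and
  `λ₀ = −ln(p_sel)`, so with null hazards each individual survives with
  probability exactly `p_sel` (default 0.7). The log relative hazard is

  `η = ln(hr_gs)·(ΣG − mean) + ln(hr_e1s)·(E₁ − mean) + ln(hr_cs)·(C − mean) + ln(hr_ds)·(D − mean) + ln(hr_us)·(U − mean)`

  with each `hr_*` an exact per-unit hazard ratio. The genotype term uses
  the total allele count across the whole panel: in a multi-exposure
  audit design the control's instruments must share the primary's
  selection pressure, which is exactly what a single score over all
  instruments encodes. Covariates are mean-centered so `p_sel` stays the
  approximate marginal survivor fraction away from the null; by Jensen's
  inequality the realized fraction falls below `p_sel` as hazards grow,
  and exact calibration is guaranteed only at the null. The exponential
  form is the simplest model in which the `hr_*` are exact per-unit
  hazard ratios; only the null-selection and hazard-monotonicity
  behaviours (not the particular survival family) carry scientific
  weight, and the tests assert exactly those.

Recruitment keeps individuals whose death time exceeds the horizon; an
empty survivor set raises a dedicated degenerate-selection error.

## GWAS engine

Summary statistics are univariable per-SNP regressions with no covariate
adjustment — deliberately, since published GWAS summary statistics are
unadjusted for the confounders through which the bias mechanisms act.
Continuous traits use closed-form simple linear regression (residual
SE, two-sided normal p); binary traits use per-SNP logistic regression
fitted by IRLS vectorized across SNPs (tolerance 1e-8, at most 50
iterations), with non-converged or quasi-separated fits (|log-OR| > 20)
flagged and excluded and monomorphic SNPs dropped with a logged reason.
The two-sample design simulates two independent cohorts from derived
sub-seeds — exposure GWASs from one, the outcome GWAS from the other —
so there is no sample overlap.

A caveat for binary outcomes: marginal per-allele log-odds ratios are
non-collapsible, so even without selection the IVW estimate of a binary
outcome is mildly attenuated relative to the conditional log-odds
parameter. For this reason the bias-grid experiment defaults to a
continuous outcome, where "bias" is cleanly `β̂ − β`; the binary pathway
is fully supported and tested for the estimation stack itself.

## Estimators

Given screened (p < 5×10⁻⁸, F = (β/se)² ≥ 10) and allele-harmonized
instruments (palindromic variants dropped when either allele frequency
lies in [0.42, 0.58], otherwise aligned by frequency):

* **Wald ratio** `θ = β_out/β_exp` with the second-order delta-method SE.
* **IVW**: weighted mean of ratios with first-order weights
  `w_j = β_exp,j²/se_out,j²` — identical to WLS of β_out on β_exp through
  the origin. Fixed-effect SE `1/√Σw`; the default multiplicative
  random-effects model inflates it by `√max(1, Q/(k−1))`. With the floor
  at 1 this makes the test slightly conservative under homogeneity
  (measured type-I error ≈ 0.04 at nominal 0.05). First-order weights
  keep the k = 1 case exactly equal to the Wald ratio.
* **Cochran's Q** against any pooled value, χ²(k−1) reference.
* **Weighted median**: ordered ratios interpolated at cumulative
  normalized weight 0.5 on the midpoint grid `p_j − w_j/2`; SE from a
  seeded parametric bootstrap (default 1000 draws) redrawing both betas
  from normals at their reported SEs. Consistent while valid instruments
  hold > 50% of the weight.
* **MR-Egger**: instruments oriented to β_exp ≥ 0 (pairwise sign flips —
  this fixes the intercept's sign convention), weighted regression with
  intercept, weights `1/se_out²`, SEs inflated by `√max(1, Q_E/(k−2))`,
  t(k−2) inference (the field's convention for Egger; IVW and Wald use
  the normal).

Minimum instrument counts (k ≥ 3 for median and Egger, k ≥ 2 for Q) are
enforced with not-estimable errors rather than silent output. All three
multi-instrument estimators are verified against brute-force oracles
(weighted normal equations, direct interpolation) to 1e-10 and are
scale-equivariant in the exposure units by construction.

## Bias grid

For each (hr_gs, hr_ds) cell the experiment runs independent two-sample
replicates, tracks the IVW (multiplicative random effects) estimate, and
reports mean bias, Monte Carlo SE, 95%-CI coverage of the true effect,
and mean instrument F. Replicate sub-seeds derive from
(master seed, hr_gs, hr_ds, replicate index), so results are invariant
to grid iteration order. Degenerate replicates are skipped and counted;
a cell with more than 20% skipped is marked not-ok. Defaults —
hr_gs ∈ {1.0, 1.2, 1.5}, hr_ds ∈ {1.0, 1.5, 2.0}, 200 replicates of
20,000 individuals per cohort, true effect 0.3 SD — complete in a few
minutes on one CPU and are all overridable. Under these conditions the
null cell is unbiased within Monte Carlo error, while hr_gs = 1.5 with
hr_ds = 2.0 biases the estimate by ≈ −0.7 SD units: selection must act
through *both* the instruments and the outcome for the collider path to
open, and then the distortion dwarfs the true effect. No closed-form
bias correction is attempted — given only selected-sample summary
statistics the truth is not recoverable, which is the point of
diagnosing rather than correcting.

## Control-exposure audit

The audit encodes the validation logic as five rules over (estimate, CI,
p) triples at a per-exposure significance level alpha (default
0.05/3 = 0.017 for the three-exposure design): an antagonist control
significant in the *same* direction as the primary (R1), or a
similar-activity control significant in the *opposite* direction (R2),
flags selection bias; a validated control whose CI covers zero (R3) or
that is significant opposite to its established direction (R4) flags
*systematic* selection bias; otherwise the pattern is labelled robust
(R5). "Consistent effects" is operationalized as both estimates
significant at alpha with the stated sign pattern, so near-null controls
fire nothing. When the primary and all controls share a source GWAS the
verdict carries a warning that systematic bias is undetectable by R1/R2
alone. The companion scatter plot shades, for each (primary, control)
pair, the sign quadrants whose occupancy would fire the pair's rule —
an interpretation of the "grey region" idea, since no exact geometry is
prescribed anywhere. Verdicts are advisory labels with one-sentence
rationales: the audit detects potential selection bias; it neither
quantifies nor corrects it, and with very small bias relative to
sampling error it will (correctly) stay silent.

The end-to-end validation scenario pairs a primary (β₁ = +0.3) with a
biochemical antagonist (β₂ = −0.3, residual correlation −0.5) and a
validated positive control, instruments split 11/7/5 across the three
exposures as in the worked iron-traits example, all loading on the shared
survival score. With strong selection (hr_gs = hr_ds = 2, cohorts of
20,000) both the primary and antagonist estimates are dragged negative —
the same-sign signature — and R1 fires in a clear majority of
replicates, while with null hazards it essentially never fires.

## What the synthetic data do and do not emulate

The generator reproduces the features the diagnostics depend on:
independent instruments of realistic aggregate strength, confounding of
the exposure–outcome relation, competing-risk pathways, and
survival-dependent recruitment. It does not emulate linkage
disequilibrium, population structure, age-structured or time-varying
hazards, assortative mating, winner's-curse instrument selection, or
sample overlap between the two GWASs. Passing tests therefore show the
estimators and audit behave correctly under the modelled selection
mechanism — not that real GWAS consortia data are free of the unmodelled
complications.

## Numerical and design choices

* All randomness flows through explicit integer seeds via numpy
  `SeedSequence`; identical (config, seed) give bitwise-identical output.
* Binary-outcome intercept calibration uses Brent root-finding on the
  realized linear predictor, making the sample prevalence match the
  target to Monte Carlo accuracy.
* p-values are floored at the smallest positive float so they stay in
  (0, 1] even for extreme z-scores.
* The summary-statistics file reader validates row-by-row (se > 0,
  eaf ∈ (0,1), p ∈ (0,1]) and rejects offending lines individually with
  line numbers, rather than failing whole files.
* Ties in harmonization (palindromic variants with frequency near 0.5)
  are dropped, never guessed.
* Default cohort sizes (20,000 per sample for the grid, 5,000 for the
  packaged miniature fixtures) keep each full experiment in the
  minutes-on-one-CPU range while leaving per-replicate instrument F
  statistics comfortably above the screening threshold.

## Known limitations

* The exponential survival model is one concrete instantiation of
  "hazard ratio per unit change"; other monotone survival families would
  give qualitatively identical but numerically different bias surfaces.
* Whether the per-allele hazard should attach to each SNP separately or
  to the aggregate score is a modelling choice; the aggregate-score form
  matches a single instrument-strength dial but cannot express
  heterogeneous per-SNP survival effects.
* The audit inherits the power of its inputs: with weak instruments or
  small cohorts, genuinely biased configurations may fail to reach
  significance and thus escape flagging.
* Recovery of the unbiased estimate from selected-sample summary
  statistics is out of scope by design.
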