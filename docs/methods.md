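# Methods

This note documents the models implemented in `upfmed`, the calibration
of the synthetic-cohort generator, the scoring conventions, and the
numerical choices — in enough detail to re-derive every default.

## 1. Estimand and estimator

The analysis is cross-sectional mediation with linear models. With
exposure X (ultraprocessed / NOVA 4 share of dietary energy, %kcal),
mediator M (DASH diet-quality score), outcome Y (0–5 CMR score, treated
as continuous) and covariates C:

* mediator model: M = α₀ + a·X + γᵀC + ε_M
* outcome model:  Y = β₀ + c′·X + b·M + δᵀC + ε_Y

The average causal mediation effect is ACME = a·b, the average direct
effect ADE = c′, and the total effect a·b + c′. For linear models the
product of coefficients is identical to the counterfactual definition
(predict M at X and X+1, push both through the outcome model at the
observed X, average the difference); the package implements both routes
and tests their agreement to 1e-10. The identity also links the models:
refitting the outcome model without M changes the exposure coefficient
by exactly a·b on the same sample, which the suite asserts to 1e-10.

Uncertainty: nonparametric **pairs bootstrap**. Whole participant rows
are resampled with replacement (robust to heteroscedasticity, unlike a
residual bootstrap); both models are refitted per replicate and
(ACME, ADE, total) recorded. Intervals are percentile by default —
consistent with the asymmetric interval the analysis is designed to
reproduce — with BCa (jackknife acceleration) behind a flag; BCa costs
n extra refits and is intended for small n. Two-sided bootstrap
p-values use the continuity-corrected form
p = 2·min[(#{θ*≤0}+1)/(B+1), (#{θ*≥0}+1)/(B+1)], hence are floored at
2/(B+1); summaries print the floor explicitly rather than "p < 0.001".
A replicate whose resample produces a rank-deficient design (e.g. a
rare covariate level absent from the resample) is redrawn and counted;
more than 5% such redraws aborts the fit, which in practice means the
sample is too small for the covariate set rather than a numerical
accident.

Proportion mediated (ACME/total) is reported only when ACME and the
total effect share a sign; otherwise it is undefined and a warning is
emitted.

### Bootstrap CI coverage and the degenerate null

Percentile CIs for a·b attain nominal coverage at regular parameter
points, including the no-mediation null with a ≠ 0, b = 0 (measured
94.5% over 200 simulated datasets at n = 2000, B = 500). At the
**joint null** a = b = 0 the estimator â·b̂ is quadratically
degenerate: its bootstrap distribution concentrates around 0 from both
sides and percentile intervals provably over-cover (measured ≈ 100%).
The coverage test therefore targets the regular null and checks the
joint null only for conservatism. This is a property of all
product-of-coefficients interval methods, not of this implementation.

## 2. Synthetic-cohort generator

The generator emulates the *statistical structure* of a large
occupational cohort with 7-day diet diaries; its defaults are the
study conditions, not free dials.

### 2.1 Covariates

n = 9009 by default; age ~ N(40.9, 9.2²) clipped to [18, 75]; 60.8%
male; BMI ~ N(27.3, 4.3²); five income bands (15/25/30/20/10%), four
education bands (10/30/35/25%), three physical-activity levels
(25/50/25%), 15% current smokers; misreporting categories
under/acceptable/over with probabilities 38.4/59.7/1.9%. Category
effect sizes on the mediator and outcome are small, plausible and
explicitly *unanchored* (no printed values exist for them); they are
applied centred, so they perturb neither the configured means nor the
structural slopes.

### 2.2 Exposure: misreporting as the built-in confounder

X is a mixture over misreporting categories with per-category means
(57.2, 58.9, 61.2) and SDs (12.2, 11.2, 11.1) %kcal. Means are shifted
by a common constant so the mixture mean is exactly 58.3 and the
within-category SDs are scaled by a common factor so the mixture SD is
exactly 11.6. This reproduces, in one construction, the overall
exposure moments, the ordering of intake across reporting categories,
and a genuine confounding path for the crude-versus-adjusted slope
contrast.

### 2.3 Mediator and the closed-form calibration

M = 38.5 + a·(X − 58.3) + centred covariate effects + ε, clipped to the
DASH range [0, 80], with a = −0.197 (the adjusted slope). Two further
defaults are solved in closed form rather than guessed:

* **Under-reporting effect on DASH (δᵤ = +4.818).** The crude slope is
  a + cov(δ(G), X)/var(X), where G is the misreporting category (the
  only covariate correlated with X). With only the under-reporter
  effect non-zero, δᵤ = (crude − a)·var(X) / (pᵤ·(μᵤ − μ̄))
  = (−0.212 + 0.197)·134.56 / (0.384·(−1.0909)) = 4.818, making the
  crude slope land on −0.212 exactly in expectation.
* **Residual SD (σ_ε = 6.844).** The crude correlation is
  r = crude·var(X) / (sd(X)·sd(M)); requiring r = −0.32 fixes
  sd(M) = 0.212·11.6/0.32 = 7.685 and hence
  σ_ε² = var(M) − a²var(X) − 2a·cov(δ,X) − var(δ) − var(other
  covariate effects) = 46.84. A naive solution that ignores the
  confounding-path variance gives ≈ 7.2; the value used here is the one
  under which both the crude slope (−0.212) and the crude correlation
  (−0.32) hold simultaneously.

### 2.4 Outcome: five-component CMR

A latent risk η = s_c·c′·(X − 58.3) + s_b·b·(M − 38.5) + centred
covariate effects, with b = −0.008 and c′ = 0.001, maps to component
probabilities p_j = clip(p0_j + η/5, 0.02, 0.98) over baselines
(0.35, 0.30, 0.30, 0.10, 0.15) — central obesity, dyslipidaemia,
hypertension, inflammation, dysglycaemia (mean CMR ≈ 1.2). Because the
conditional mean of the component sum is linear in η wherever the clip
does not bind, OLS on the generated table recovers b and c′; under the
default effect sizes the clip band is essentially never active
(attenuation < 1%, far inside Monte-Carlo error at any tested n), so
the calibration scales s_b, s_c ship at 1.0. `calibrate_generator`
implements the iterative pilot-fit procedure (multiply each scale by
target/fitted until both slopes are within 2 SE) for configurations
whose effect sizes do push into the clip band.

The structural total effect is c′ + a·b = 0.001 + 0.001576 = 0.002576
CMR units per %kcal; the headline tables round this to 0.003.

### 2.5 Clinical markers

Rather than drawing component indicators directly, the generator draws
*markers* and lets the scoring module reproduce the probabilities:
each marker comes from a sex-specific Gaussian whose mean is placed at
threshold + σ·Φ⁻¹(p), so its threshold exceedance is exactly the
target probability. Composite components discount fixed secondary
paths first (non-HDL exceedance 3%, DBP exceedance 5%, medication
flags 2/3/1%), solving
p_primary = 1 − (1 − p_component)/Π(1 − p_secondary). hs-CRP is
log-normal (log-SD 0.6) with its log-mean solved by bisection so that
P(3 ≤ CRP < 10) matches the inflammation target; log-SD 0.6 keeps the
band probability attainable up to ≈ 0.68. Marker floors (waist ≥ 50 cm
etc.) are several SDs from the operating range and do not perturb the
calibration measurably.

### 2.6 Diary mode

Diary mode emits the raw artifacts from which every analysis column
can be re-derived: a 16-code food catalogue (synthetic, standing in
for a national food-composition database; descriptors are constructed
so the rule-based NOVA classification reproduces each code's latent
group, and each code's energy equals 9·fat + 4·protein +
3.75·carbohydrate exactly), 7-day diaries, clinical markers, and
reported energy intakes.

Diaries are built to be *consistent*: DASH anchor foods carry the
food-group amounts implied by the participant's assigned score
(component scores are water-filled to sum to the assigned total, then
inverted through the scoring rule), and two filler staples — one
ultraprocessed ready meal, one minimally processed staple — absorb the
remaining energy in each NOVA stratum so the recomputed NOVA 4 energy
share equals the assigned exposure exactly. When an energy budget
cannot absorb its anchors (extreme shares), anchor grams are rescaled,
preserving the share at some cost in DASH fidelity; recomputed DASH
tracks the assigned score to a median error below one point.

Reported energy intake is a per-category EI:BMR ratio drawn from a
log-normal centred at PAL = 1.55 and truncated inside the Goldberg
interval of the assigned category, so the **Goldberg classifier — not a
label — reproduces the misreporting split**. Weight comes from BMI and
sex-specific height; BMR from the Schofield adult equations.

### 2.7 Randomness

All draws derive from the single config seed through named sub-streams
(BLAKE2 hash of seed and purpose), so outputs are bit-stable under a
fixed config and one stage's draws are independent of another's
presence.

## 3. Scoring conventions

* **DASH**: 8 components (fruit, vegetables, wholegrains,
  nuts/legumes, low-fat dairy; moderation: red/processed meat,
  sweetened drinks, sodium), 10 points each, targets editable in YAML.
  Adequacy: points ∝ intake/target, capped; moderation: full points at
  or below target, target/intake above. The working total is the raw
  0–80 sum — the printed slopes (≈ −0.2 points per %kcal, mediator SD
  ≈ 7.7) are impossible on a 0–10 scale — with a normalised 0–10 value
  exposed alongside.
* **Energy factors**: fat 9, protein 4, carbohydrate and NMES 3.75
  kcal/g (UK food-table convention). Energy density is computed over
  solid foods only; beverages are excluded (an assumption recorded in
  every output header).
* **Goldberg**: S = √(CV²wEI/d + CV²BMR + CV²PAL) with CVwEI = 23%,
  d = 7 days, CVBMR = 8.5%, CVPAL = 15.1%, PAL = 1.55, z = 1.96, giving
  cut-offs 1.0600 and 2.2665 (the interval brackets PAL geometrically
  for any positive constants).
* **CMR thresholds**: waist ≥ 94/80 cm (M/F); HDL < 1.0/1.3 mmol/L or
  non-HDL ≥ 4.0 or lipid medication; SBP ≥ 130 or DBP ≥ 85 mm Hg or
  antihypertensives; hs-CRP in [3, 10) mg/L — values ≥ 10 score 0 and
  are flagged as acute-phase rather than silently dropped; HbA1c
  ≥ 5.7% or glucose medication; high risk at total ≥ 3. Missing inputs
  raise; a component is never silently scored zero. HbA1c in mmol/mol
  is converted with the IFCC linear map at load.
* **Model covariate sets**: the adjusted diet-quality model ships in
  two variants (with and without sex and smoking, both defensible
  readings of the source tables); since neither covariate is
  correlated with the exposure in the generator, both recover the same
  slope. Reference categories are female, non-smoker, lowest income
  and education bands, low activity, acceptable reporting, recorded on
  every fit. Backward stepwise selection is deliberately not
  reimplemented; the final covariate sets are fixed model specs.

## 4. Problem sizes used in the tests

Moment and structure recovery are tested at n = 20 000 (3 MC-SE
bands); the acceptance checks use n = 50 000 for the exposure moments
and crude correlation, and average 10 (test) / 30 (acceptance script)
cohorts at the study size n = 9009 for slope recovery. Bootstrap
coverage uses 200 datasets of n = 2000 at B = 500 replicates. These
sizes put Monte-Carlo error well below the quantities under test while
keeping the default suite fast on one CPU.

## 5. What the generator does and does not emulate

It reproduces: the exposure distribution and its gradient across
misreporting categories, the crude and adjusted exposure–mediator
slopes and crude correlation, the mediator→outcome and direct paths,
the misreporting split via the Goldberg classifier, 5-component CMR
prevalences, and diary-level consistency of the NOVA 4 share.

It does not emulate: the real food-composition database (the
catalogue is 16 codes, not thousands), day-to-day and weekday/weekend
diet variation, correlated clinical markers (markers are conditionally
independent given latent risk), BMI–diet or BMI–waist dependence,
nutrient-profile correlations with the exposure (diary-mode nutrient
profiles are emergent, not calibrated), item-level misreporting (only
total energy is scaled), or any longitudinal structure. Passing tests
therefore demonstrate correctness of the pipeline's computations and
recoverability of the configured structure — not that the pipeline
would be unbiased on real diaries, where classification ambiguity and
differential misreporting are material.

## 6. Known limitations

* NOVA keyword matching is substring-based and case-insensitive;
  descriptors are assumed curated (e.g. "strawberry" would match the
  staple keyword "raw" — the shipped rule tables are meant to be
  edited against a real catalogue).
* CMR is modelled with linear regression on a 0–5 count, as in the
  source analysis; no ordinal alternative is provided in the default
  pipeline.
* Sequential ignorability is assumed, not testable here; no
  exposure–mediator interaction, no sensitivity analysis, single
  mediator only.
* Participants on multiple medication classes are scored per component
  independently; the source is silent on this.
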