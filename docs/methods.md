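# Methods

## The problem

Carboplatin is dosed to a target systemic exposure (AUC, mg·min/mL) through
the Calvert relation

    dose = target AUC × (GFR + 25 mL/min),

where GFR is in practice replaced by an estimated creatinine clearance
(CrCL).  The Cockcroft–Gault (CG) estimator overestimates CrCL in overweight
patients (body weight rises faster than muscle mass) and in cachectic
patients with low serum creatinine.  The package implements an adjusted CG
dosing algorithm (aCG) and nine comparator renal-function/clearance
estimators, simulates the resulting individual exposure under a
two-compartment infusion model with sparse sampling, estimates each
individual's realised clearance by MAP (empirical-Bayes) estimation, and
scores every method's mean percentage prediction error (MPE%) and mean
absolute percentage error (MAPE%) against the target AUC per BMI stratum.

## Dosing algorithms

The aCG algorithm applies three conditional adjustments to conventional CG
(µmol/L dialect: CrCL = (140 − age)·weight·F_sex/Scr, F_male 1.23,
F_female 1.04):

1. **weight descriptor** — adjusted ideal body weight
   AIBW = IBW + 0.4·(ABW − IBW) replaces absolute body weight when
   BMI ≥ 25 kg/m² (boundary inclusive); IBW is Devine
   (50/45.5 kg + 2.3 kg per inch over 60 in, heights below the reference
   extrapolated linearly);
2. **creatinine floor** — serum creatinine below 60 µmol/L is replaced by
   60 µmol/L;
3. **clearance cap** — estimated CrCL above 125 mL/min is capped at
   125 mL/min.

Comparators: conventional CG with ABW (uncapped, and a capped variant that
applies both the floor and the cap) and with AIBW (uncapped); a
Chatelut-type carboplatin-clearance covariate model evaluated at
min(ABW, IBW) (the Bénézet weight-descriptor reading); a measured 24-h
creatinine clearance (excretion rate / serum concentration); a cystatin-C
direct carboplatin-clearance power model on CysC, weight, age, serum
creatinine and sex; the 2021 race-free CKD-EPI equations (creatinine, and
creatinine + cystatin C), de-indexed from mL/min/1.73 m² to absolute mL/min
with Du Bois BSA by default (the Calvert formula needs absolute clearance;
the de-indexing is a toggle); and flat dosing from the mean population
carboplatin clearance (112.4 mL/min).

Methods that predict carboplatin clearance *directly* (Chatelut/Bénézet,
cystatin-C model, flat dosing) store clearance − 25 in the CrCL slot of
their estimate with a `direct_clearance` flag, so the downstream Calvert
reconstruction CrCL + 25 returns the formula's clearance exactly and the
non-renal offset is never added twice.

Every formula reads its constants from a packaged TOML coefficient file
(SHA-256 logged at load).  The CG sex factors, Devine, Du Bois, Chatelut and
CKD-EPI sets are the standard published values.  The cystatin-C model's
numerical coefficients are package defaults that follow the published
covariate structure (typical clearance 110 mL/min at the reference
covariates; negative CysC, age and Scr exponents; positive weight exponent;
female factor < 1): sites validating against their own assay should override
them in the coefficient file.

Calculated doses are rounded to an administered dose at a configurable
increment, default 50 mg — consistent with the canonical worked example
(620 mg calculated → 600 mg administered) and vial-based practice.
Exact midpoints round **down**, the toxicity-conservative choice.  Rounding
perturbs the delivered AUC by at most increment/(2·(CrCL + 25)); this bound
is propagated to the evaluation tests.

## Pharmacokinetic model

Ultrafilterable carboplatin follows linear two-compartment kinetics with a
zero-order infusion: micro constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2;
macro constants α > β > 0 are roots of s² − (k10+k12+k21)s + k10k21 = 0
(β computed as k10·k21/α for numerical stability).  The finite infusion is
evaluated as a never-ending step response minus the same response delayed by
the infusion duration, which makes the profile continuous at the end of the
infusion by construction.  The repeated-root case α = β (reachable when
Q → 0 with k10 = k21) uses the closed-form limit, not a failure path.
AUC∞ = dose/CL exactly, independent of V1, Q, V2.

Canonical internal units are mg, mL, min; concentration files in µg/mL or
mg/L are converted at the I/O boundary.

Defaults: CL 112.4 mL/min (the mean population clearance above); V1 20 L,
Q 0.5 L/min, V2 20 L are placeholders chosen for a plausible biexponential
shape and are configuration keys — users wanting fidelity to a specific
published population model should set them from that model.  Infusion
duration defaults to 30 min (configurable).  Residual error is combined
proportional + additive, default 10% proportional, 0 additive;
inter-individual variability is a log-normal effect on CL with ω = 0.2
(≈20% CV), optionally also on V1.

The sparse sampling design is the study schedule: one predose sample, one at
the end of the infusion, and one at 1, 2.5 and 5 h after the end of the
infusion.  The cycle-1 predose sample carries no drug and is excluded from
fitting.

## MAP estimation

Individual random effects η minimise

    OFV(η) = Σ_j [ (y_j − f_j(η))²/g_j²(η) + ln g_j²(η) ] + ηᵀΩ⁻¹η,

with f_j the model prediction under θ·exp(η) and g_j² = σ_prop²f_j² + σ_add²
evaluated at the *individual* prediction (the interaction form).  Only η_CL
is estimated by default since AUC = dose/CL depends on clearance alone.
Population parameters are fixed, not re-estimated: only the post-hoc step is
implemented, which is all the exposure analysis requires.

Numerical choices:

* multi-start L-BFGS-B from η = 0 and ± one prior SD per component;
  ties broken by lowest OFV, then smallest ‖η‖;
* convergence is declared on the per-component Newton decrement |g/H| < 1e-5
  (central differences) rather than a raw gradient threshold: the OFV
  curvature scales like 1/σ², so an absolute gradient criterion would reject
  perfectly converged fits at small residual variance;
* |η| > 10 is smoothly penalised instead of bounded (guards exp underflow
  without constraining the optimizer);
* the σ → 0 residual model is handled by substituting a 1e-6 proportional SD
  — the likelihood then dominates the prior by ~σ⁻² while adding only O(σ²)
  shrinkage bias, giving the exact-recovery limit used by the noise-free
  self-consistency tests;
* non-converged fits are excluded downstream with a logged reason (per
  protocol), never silently retained.

A property worth knowing: with observations exactly at the population
prediction, the interaction term ln g²(η) shifts the MAP mode away from
η = 0 by O(σ_prop²) (≈0.012 at σ = 0.1 on the study design).  This is
inherent to the interaction objective, not an optimizer artefact; the test
suite asserts the shift shrinks quadratically with σ.

## Evaluation

Per-patient prediction error is PE% = (AUC_est − AUC_target)/AUC_target×100.
The dosing algorithm in use (aCG by default) is scored on its realised
exposure, AUC_actual = administered dose / CL_hat.  Comparator methods
support two readings, switchable via `auc_mode`:

* **counterfactual** (default): round(target × (CrCL_m + 25)) / CL_hat — the
  AUC the patient would have received had method *m* chosen the dose, given
  the measured clearance.  This is the reading under which a method whose
  clearance model matches the truth is unbiased, and it reproduces the
  qualitative overweight pattern (ABW-based CG overshoots in an obese
  stratum when the truth follows AIBW, while AIBW-based CG stays unbiased);
* **predicted**: administered dose / (CrCL_m + 25), the estimated-AUC
  reading of the worked example above.

MPE% is the mean PE, MAPE% the mean |PE|; both get Student-t 95% CIs on the
per-patient values (n < 2 → no CI).  Each method × stratum cell is flagged
against the ±15% acceptance band (85%–115% of target).  The report grid
always contains all 10 methods × 3 strata; patients missing cystatin C or
the 24-h urine collection are excluded *per method* with the reason
recorded, and strata with no evaluable patients are emitted with n = 0 and
null statistics.

The sample-size helper uses the normal approximation
n = c·(z_{1−α/2} + z_power)²·(sd/δ)² (c = 1 or 2 for one-/two-sample
designs), rounded up.  The two-sample design reproduces the 7-per-group
figure for δ = 1.8 (30% of target AUC 6), SD 1.2, α = 0.05, power 0.80.

## Synthetic cohorts

The generator emulates a small BMI-stratified carboplatin cohort: default
stratum sizes 7/5/6 (<25.0 / 25.0–29.9 / ≥30.0 kg/m²), covariates drawn
uniformly within per-stratum ranges matching the observed cohort
(e.g. obese weight 87–115 kg, height 160–180 cm), sex probabilities from the
observed per-stratum counts (6/7, 1/5, 3/6 male), target AUC drawn from
{5, 6} with P(6) = 0.8.  Uniform sampling within ranges is the simplest
model consistent with the printed per-stratum information; medians are not
separately enforced.  (Weight, height) pairs are rejection-sampled until the
BMI lands in the stratum band, so stratum purity is exact.

Each patient's latent truth is built on the Calvert relation: a configurable
truth formula (default aCG, so aCG dosing is unbiased by construction;
CG_AIBW or the cystatin model reproduce the biased regimes) defines the
latent CrCL, and true CL = (CrCL + 25)·exp(η), η ~ N(0, ω²), ω default 0.2.
The 24-h urine creatinine is back-computed as CrCL·Scr·1440/10⁶ mmol/24 h
with 10% multiplicative log-normal noise, so the 24-h clearance estimator
recovers the latent CrCL up to that noise (exactly at zero noise).  The
24-h clearance method is therefore not allowed as the truth formula (it
would be circular).

Randomness: one root seed; every patient draws from a substream keyed by
(seed, patient index), and observation noise from (seed, index, 1) — cohorts
are bit-reproducible and extensible without reshuffling earlier patients.

What the generator does **not** model: enrolment dropout (only evaluable
patients are generated), longitudinal cycles, covariate correlations beyond
the stratum structure, toxicity outcomes, and any covariate effect on PK
parameters other than the clearance truth itself.  Passing tests therefore
demonstrate the internal consistency and statistical behaviour of the
pipeline under its own generative assumptions, not the clinical performance
of any estimator on real patients.

## Problem sizes

The packaged simulation study uses the study-sized cohort (18 patients,
5 samples each); the Monte-Carlo regression of the MAP step uses 200
simulated patients on the sparse design with a 2×10⁻⁴-step grid-search
oracle, and distributional checks use 10³–10⁴ replicates.  The full test
suite runs in well under a minute.

## Known limitations

* The cystatin-C model's default coefficients are structural defaults, not a
  validated transcription; override them for quantitative use.
* V1/Q/V2 defaults are shape placeholders (AUC results are insensitive to
  them by AUC = dose/CL, but concentration-level quantities are not).
* No below-limit-of-quantification handling; observations are used as-is.
* The one-/two-sample choice in the sample-size helper materially changes
  the result; the two-sample default is the reading that matches the
  7-per-group design figure.
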