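# Default formula coefficient sets. Every renal-function / clearance
# estimator reads its constants from here so a deployment can swap dialects
# (e.g. the mg/dL "x72" Cockcroft-Gault) without code changes.

[cockcroft_gault]
# Serum creatinine in umol/L: CrCL = (140 - age) * weight * F_sex / Scr
f_male = 1.23
f_female = 1.04

[devine_ibw]
# IBW = base + kg_per_inch * (height_in - 60), heights extrapolated linearly
base_male_kg = 50.0
base_female_kg = 45.5
kg_per_inch = 2.3
reference_height_cm = 152.4
cm_per_inch = 2.54

[dubois_bsa]
# BSA = c * weight^a * height^b (kg, cm -> m^2)
coefficient = 0.007184
weight_exponent = 0.425
height_exponent = 0.725

[chatelut_benezet]
# Carboplatin clearance (mL/min) from a Chatelut-type covariate model,
# evaluated at min(ABW, IBW):
#   CL = theta_weight*W + theta_renal*W*(1 - age_slope*age)*(1 - female_factor*female)/Scr
theta_weight = 0.134
theta_renal = 218.0
age_slope = 0.00457
female_factor = 0.314

[schmitt]
# Direct carboplatin-clearance power model on cystatin C, weight, age, serum
# creatinine and sex. The covariate structure follows the published
# cystatin-C carboplatin model; the numerical values below are package
# defaults and are meant to be overridden with a site-validated set.
typical_cl_ml_min = 110.0
cysc_ref_mg_l = 1.0
cysc_exp = -0.327
weight_ref_kg = 65.0
weight_exp = 0.474
age_ref_yr = 56.0
age_exp = -0.387
scr_ref_umol_l = 75.0
scr_exp = -0.512
female_factor = 0.854

[ckdepi_creatinine]
# 2021 race-free creatinine equation, eGFR in mL/min/1.73 m^2
intercept = 142.0
kappa_female = 0.7
kappa_male = 0.9
alpha_female = -0.241
alpha_male = -0.302
beta = -1.200
age_base = 0.9938
female_factor = 1.012

[ckdepi_creatinine_cystatin]
# 2021 race-free creatinine - cystatin C equation
intercept = 135.0
kappa_female = 0.7
kappa_male = 0.9
alpha_female = -0.219
alpha_male = -0.144
beta = -0.544
cys_kappa = 0.8
cys_alpha = -0.323
cys_beta = -0.778
age_base = 0.9961
female_factor = 0.963
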