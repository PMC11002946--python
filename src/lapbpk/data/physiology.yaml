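# Physiology coefficients for a healthy white adult virtual population,
# ages 20-99 y, BMI 18.5-30.
#
# Every quantity is parameterised the same way:
#   value(age, sex) = ref[sex] * size_factor * exp(slope_pre * (min(age, onset) - 30)
#                                                  + slope_post * max(age - onset, 0))
# with an individual log-normal perturbation of the given geometric CV
# (mean-preserving).  `ref` is the population mean at age 30 for an individual
# at the reference body size (BMI 25).  Organ volumes additionally scale with
# (body_weight / reference_body_weight[sex]) ** allometric_exponent.
#
# Provenance: reference organ weights/flows follow standard reference-man /
# reference-woman compilations (ICRP-89-class values); age slopes follow the
# directions and approximate magnitudes reported for healthy aging (cardiac
# output, renal function, hepatic volume and perfusion, albumin decline;
# sarcopenia with faster post-menopausal muscle loss; adipose gain).  The
# numeric slopes and CVs are calibrated defaults of this package's virtual
# population, chosen once so that simulated young-adult pharmacokinetics and
# aging trends sit in clinically reported ranges; they are deliberately
# swappable without code changes.

version: "1"

reference:
  age: 30.0
  bmi: 25.0
  height_cm: {male: 176.0, female: 163.0}
  body_weight_kg: {male: 77.4, female: 66.4}   # BMI 25 at reference height
  hematocrit: 0.45                              # reference for blood:plasma scaling
  albumin_g_per_l: 46.0
  alpha1_acid_glycoprotein_g_per_l: 0.80
  gfr_ml_per_min: 115.0

demographics:
  height_mean_cm: {male: 176.0, female: 163.0}
  height_sd_cm: {male: 7.0, female: 6.5}
  height_age_slope_cm_per_year: -0.05   # secular/postural loss beyond age 30
  bmi_mean: 25.0
  bmi_sd: 3.5

scalars:
  cardiac_output:
    unit: L/h
    ref: {male: 390.0, female: 330.0}
    trend: {onset: 50.0, slope_pre: -0.002, slope_post: -0.0065}
    cv: 0.12
  hematocrit:
    unit: fraction
    ref: {male: 0.45, female: 0.40}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.0008}
    cv: 0.04
    bounds: [0.25, 0.55]
  albumin:
    unit: g/L
    ref: {male: 46.0, female: 46.0}
    trend: {onset: 40.0, slope_pre: 0.0, slope_post: -0.0018}
    cv: 0.06
  alpha1_acid_glycoprotein:
    unit: g/L
    ref: {male: 0.80, female: 0.80}
    trend: {onset: 40.0, slope_pre: 0.0, slope_post: 0.003}
    cv: 0.18
  gfr:
    unit: mL/min
    ref: {male: 115.0, female: 105.0}
    trend: {onset: 40.0, slope_pre: -0.001, slope_post: -0.008}
    cv: 0.15

enzymes:
  CYP3A4:
    ref: {male: 1.0, female: 1.0}
    trend: {onset: 40.0, slope_pre: 0.0, slope_post: -0.0020}
    cv: 0.30
  UGT1A1:
    ref: {male: 1.0, female: 1.0}
    trend: {onset: 40.0, slope_pre: 0.0, slope_post: -0.0012}
    cv: 0.62

# Organ volumes in litres at reference size; allometric exponent b applies to
# (BW / BW_ref) ** b.  Blood is split into arterial and venous pools below.
organ_volumes:
  adipose:
    ref: {male: 17.0, female: 24.0}
    allometric_exponent: 1.9
    trend: {onset: 50.0, slope_pre: 0.004, slope_post: 0.003}
    cv: 0.20
  bone:
    ref: {male: 10.5, female: 8.0}
    allometric_exponent: 0.8
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.002}
    cv: 0.06
  brain:
    ref: {male: 1.45, female: 1.30}
    allometric_exponent: 0.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.002}
    cv: 0.05
  gut:
    ref: {male: 1.65, female: 1.40}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.001}
    cv: 0.10
  heart:
    ref: {male: 0.35, female: 0.28}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.10
  kidneys:
    ref: {male: 0.31, female: 0.27}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.005}
    cv: 0.12
  liver:
    ref: {male: 1.80, female: 1.50}
    allometric_exponent: 1.0
    trend:
      onset: 40.0
      slope_pre: 0.0
      slope_post: {male: -0.0050, female: -0.0085}
    cv: 0.18
  lungs:
    ref: {male: 0.55, female: 0.45}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.08
  muscle:
    ref: {male: 29.0, female: 19.5}
    allometric_exponent: 0.9
    trend:
      onset: 50.0
      slope_pre: 0.0
      slope_post: {male: -0.0055, female: -0.0085}
    cv: 0.10
  pancreas:
    ref: {male: 0.15, female: 0.12}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.10
  skin:
    ref: {male: 3.30, female: 2.60}
    allometric_exponent: 0.9
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.10
  spleen:
    ref: {male: 0.15, female: 0.13}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.12
  rest:
    ref: {male: 3.50, female: 3.00}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.10
  blood:
    ref: {male: 5.60, female: 4.50}
    allometric_exponent: 1.0
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.002}
    cv: 0.08

blood_split: {arterial: 0.30, venous: 0.70}

# Fractions of cardiac output perfusing each systemic organ.  The liver
# receives the hepatic artery plus the portal outflow of gut, spleen and
# pancreas; the lungs receive the entire cardiac output in series.  Fractions
# are renormalised to sum to one after trends and individual variability, so
# the systemic circuit closes exactly on cardiac output.
flow_fractions:
  adipose:
    ref: {male: 0.050, female: 0.085}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  bone:
    ref: {male: 0.050, female: 0.042}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  brain:
    ref: {male: 0.120, female: 0.125}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.001}
    cv: 0.10
  gut:
    ref: {male: 0.145, female: 0.150}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  heart:
    ref: {male: 0.040, female: 0.050}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  kidneys:
    ref: {male: 0.190, female: 0.170}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: -0.003}
    cv: 0.15
  hepatic_artery:
    ref: {male: 0.065, female: 0.065}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  muscle:
    ref: {male: 0.170, female: 0.145}
    trend:
      onset: 50.0
      slope_pre: 0.0
      slope_post: {male: -0.004, female: -0.009}
    cv: 0.20
  pancreas:
    ref: {male: 0.010, female: 0.010}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  skin:
    ref: {male: 0.050, female: 0.050}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  spleen:
    ref: {male: 0.030, female: 0.030}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
  rest:
    ref: {male: 0.080, female: 0.093}
    trend: {onset: 50.0, slope_pre: 0.0, slope_post: 0.0}
    cv: 0.15
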