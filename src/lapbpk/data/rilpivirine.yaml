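# Rilpivirine drug model parameters.
#
# Provenance by field:
#   molecular_weight, log_p, pka, fu_plasma, blood_to_plasma_ratio: public
#     physicochemical/ADME characterisations of rilpivirine (NNRTI; lipophilic
#     weak base, very highly albumin-bound).
#   elimination_pathways: CYP3A4-dominant oxidative metabolism, negligible
#     renal excretion of unchanged drug.
#   intrinsic_clearance_reference, oral_absorption, kp_scalar: calibrated so a
#     young reference cohort reproduces the reported oral 25 mg steady-state
#     exposure (geometric-mean Cmax ~198 ng/mL, AUCtau ~3.2 ug*h/mL,
#     Cmin ~98 ng/mL) and a large distribution volume with a ~1.5-2 day
#     plasma half-life.
#   depot: long-acting injectable nanosuspension; single first-order release
#     with a release half-life of weeks (flip-flop kinetics).  k_release and
#     flow_sensitivity are calibrated defaults (see docs/methods.md) anchored
#     to the published week-8 and steady-state trough bands.

name: rilpivirine
molecular_weight: 366.42      # g/mol
log_p: 4.50
pka:
  - {value: 5.60, type: base}
fu_plasma: 0.003
blood_to_plasma_ratio: 0.67
protein_binding_partner: albumin

reference:
  hematocrit: 0.45
  albumin_g_per_l: 46.0
  alpha1_acid_glycoprotein_g_per_l: 0.80
  gfr_ml_per_min: 115.0
  liver_volume_l: 1.80

elimination_pathways: {CYP3A4: 0.9975, renal: 0.0025}
intrinsic_clearance_reference: 3100.0   # L/h, unbound, whole reference liver

oral_absorption: {ka: 0.50, fa: 0.95, lag: 0.0}

kp_scalar: 1.0

depot:
  release_model: single_first_order
  k_release_fast: 7.35e-4         # 1/h  (release half-life ~5.6 weeks)
  k_release_slow: 7.35e-4
  fast_fraction: 1.0
  bioavailable_fraction: 1.0
  flow_sensitivity: 0.8
  release_cv: 0.15
  reference_muscle_flow: 66.3
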