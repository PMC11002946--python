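# Cabotegravir drug model parameters.
#
# Provenance by field:
#   molecular_weight, log_p, pka, fu_plasma, blood_to_plasma_ratio: public
#     physicochemical/ADME characterisations of cabotegravir (integrase
#     inhibitor; weak acid, very highly albumin-bound, low blood:plasma ratio).
#   elimination_pathways: UGT1A1-dominant glucuronidation with a small renal
#     component, per public disposition data.
#   intrinsic_clearance_reference, oral_absorption, kp_scalar: calibrated so a
#     young reference cohort reproduces the reported oral 30 mg steady-state
#     exposure (geometric-mean Cmax ~8.5 ug/mL, AUCtau ~169 ug*h/mL,
#     Cmin ~5.5 ug/mL) and a plasma half-life near 2 days.
#   depot: long-acting injectable suspension; single first-order release with
#     a release half-life of weeks (flip-flop kinetics).  k_release and
#     flow_sensitivity are calibrated defaults (see docs/methods.md) anchored
#     to the published week-8 and steady-state trough bands.

name: cabotegravir
molecular_weight: 405.35      # g/mol
log_p: 1.10
pka:
  - {value: 8.05, type: acid}
fu_plasma: 0.003
blood_to_plasma_ratio: 0.52
protein_binding_partner: albumin

# Physiology of the reference individual the clearances are anchored to.
reference:
  hematocrit: 0.45
  albumin_g_per_l: 46.0
  alpha1_acid_glycoprotein_g_per_l: 0.80
  gfr_ml_per_min: 115.0
  liver_volume_l: 1.80

elimination_pathways: {UGT1A1: 0.888, renal: 0.112}
intrinsic_clearance_reference: 55.0   # L/h, unbound, whole reference liver

oral_absorption: {ka: 0.60, fa: 0.90, lag: 0.0}   # ka 1/h

kp_scalar: 1.0

depot:
  release_model: single_first_order
  k_release_fast: 6.65e-4         # 1/h  (release half-life ~6 weeks)
  k_release_slow: 6.65e-4
  fast_fraction: 1.0
  bioavailable_fraction: 1.0
  flow_sensitivity: 0.65           # k scales with (Q_muscle / reference)^gamma
  release_cv: 0.15                # inter-individual log-normal CV on k
  reference_muscle_flow: 66.3     # L/h, young male reference muscle perfusion
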