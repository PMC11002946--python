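# Methods

This note documents the models inside `lapbpk`, the choices made where the
design was genuinely open, and what the shipped defaults can and cannot
support.

## Virtual population

`population.generate_cohort` samples demographics and derives physiology:

* **Demographics.** Ages uniform on the cohort range (no density was
  available to justify anything else); the female/male split is allocated
  deterministically (`round(n·f)` females) so a "50% female" cohort of 100 is
  exactly 50/50; BMI is a truncated normal (mean 25, SD 3.5) clipped to
  [18.5, 30]; height is normal per sex (176 ± 7 cm men, 163 ± 6.5 cm women)
  with a small secular decline (−0.05 cm/y beyond age 30); weight follows
  from BMI and height.
* **Physiology.** Every quantity is
  `ref(sex) · size^b · exp(s_pre·(min(age,onset)−30) + s_post·max(age−onset,0))`
  times a mean-preserving log-normal factor with the configured geometric CV.
  Reference values are standard reference-man/woman compilations; age slopes
  encode healthy aging: cardiac output −0.65%/y and GFR −0.8%/y past their
  onsets, liver volume −0.50%/y (men) and −0.85%/y (women) past 40, muscle
  volume −0.55%/y (men) and −0.85%/y (women) past 50 with a matching decline
  in the muscle flow fraction, albumin −0.18%/y, adipose increasing
  throughout adulthood. The faster female post-50 decline of liver volume
  and muscle perfusion is the package's encoding of accelerated
  post-menopausal sarcopenia and the observed growth of female/male exposure
  differences with age; it is a calibrated population choice, not a measured
  equation.
* **Flow closure.** Flow fractions are renormalised per individual before
  multiplying by cardiac output, so the systemic circuit closes on CO to
  machine precision for every sampled individual — an invariant the tests
  enforce at 1e-6.
* **Seeds.** A cohort seed drives one demographics stream; each individual
  carries a derived 31-bit seed for its own variability draws, so any
  individual can be re-derived in isolation and serialized cohorts
  round-trip bit-identically.

The numeric slopes and CVs are calibrated defaults (see *Calibration*).
They describe a fit, community-dwelling white adult population aged 20–99
with BMI 18.5–30; frailty, organ impairment, pediatric or pregnant
physiology and non-white population priors are out of scope.

## Drug models

Each compound is a YAML parameter set: physicochemistry (log P, pKa, fu,
blood:plasma ratio, binding protein), elimination pathway split, a reference
unbound intrinsic clearance for the whole reference liver, first-order oral
absorption, and depot parameters.

* **Partitioning.** Tissue:plasma Kp values come from tissue-composition
  equations: moderate-to-strong bases (basic pKa ≥ 7) use intracellular pH
  trapping plus acidic-phospholipid binding with the association constant
  back-calculated from red-cell partitioning; acids, weak bases and neutrals
  use neutral-lipid/phospholipid partitioning plus tissue protein binding
  scaled from 1/fu. Adipose uses the vegetable-oil:water coefficient
  (log P_vow = 1.115·log P − 1.35). Cabotegravir (weak acid, fu 0.003,
  albumin-bound) gets small Kp everywhere (Vss ≈ 10 L); rilpivirine
  (lipophilic base, pKa 5.6) gets a large adipose Kp and a Vss of several
  hundred litres, so its half-life stretches as adipose mass grows with age.
* **Clearance scaling.** `fu` scales inversely with the individual's binding
  protein concentration; blood:plasma with hematocrit at fixed red-cell
  affinity; intrinsic clearance with liver volume × abundance-weighted
  enzyme scalars (UGT1A1 for cabotegravir, CYP3A4 for rilpivirine); hepatic
  clearance is well-stirred and renal clearance is fu·GFR. The pathway
  fractions in the config equal the hepatic/renal split of the reference
  individual, and the engine's integrated elimination reproduces that split
  within 2% in tests.
* **Depot.** Default single first-order release (a dual model is available;
  the shipped defaults do not need it). The individual release rate is
  `k_rel·(Q_mus/Q_ref)^γ` times a small log-normal formulation CV (0.15).
  γ (0.65 CAB, 0.8 RPV) expresses how strongly each suspension's dissolution
  responds to local perfusion; it is the mechanism by which the simulated
  age and sex differences of the long-acting regimens exceed the oral ones.
  Released drug enters venous blood (systemic uptake from the injection
  site); entry via the muscle compartment is available behind a switch.

## PBPK engine

Thirteen perfused organs plus arterial/venous blood, lungs in series,
portal drainage into the liver, oral first pass via the liver inflow, and
cumulative bookkeeping states for hepatic, renal and never-absorbed drug.
All transfers are first order, so between dose events the system is
`dA/dt = M·A` with a compartmental (Metzler, column-sum-zero) matrix.

The default integrator propagates with matrix exponentials cached per step
size: exact at every output time, unconditionally stable, and immune to the
stiffness of hour-scale distribution inside a 16,000-hour horizon. Doses are
instantaneous state increments; recorded values at a dose time are the
pre-dose (left) limit. An adaptive BDF solver (rtol 1e-8, atol 1e-10 mg)
remains available and is cross-checked against the exponential propagator in
the tests; mass balance, non-negativity, dose linearity and superposition
are asserted at 1e-6 or better. The output grid is 1 h during the 4-week
oral lead-in and 6 h thereafter, augmented with every injection time and
predose sampling point; time is internally hours, reported in weeks at the
I/O boundary.

## Study designs and statistics

The long-acting designs follow the registrational calendars: oral lead-in
(30 mg CAB / 25 mg RPV daily, 28 doses), first loading injection at week 4
(600 mg CAB / 900 mg RPV); Q4W continues with maintenance every 4 weeks from
week 8 (400 mg CAB / 600 mg RPV); Q8W gives a second loading dose at week 8
and maintenance every 8 weeks from week 16 (600 mg CAB / 900 mg RPV). The
calendar runs through the week-96 injection. "Predose" is injection time
minus 1 h. Week-96 metrics use the dosing interval ending at week 96 (AUCτ
by trapezoid on the simulation grid; Cmin is the predose value).

Cohort statistics are geometric means with geometric CV%
(`100·sqrt(exp(var(ln x))−1)`; arithmetic CV is available behind a flag).
Fold changes are ratios of geometric means with a seeded nonparametric
bootstrap (2,000 resamples) for the 5th–95th band. Threshold fractions use
strict `<` (ties count as not-below). Cohorts of 100 are partitioned into
10 virtual trials of 10 for display of between-trial variability.

In `reproduce.StudyEndpoints` (used by the acceptance script and tests) the
two cohorts of a comparison share a seed: the per-individual variability
draws are common random numbers while ages, sexes and anthropometry follow
each cohort's definition. Each cohort is marginally unchanged, but the
Monte-Carlo error of a fold change drops from about ±0.06 to about ±0.01 at
n = 100. Distinct (drug, regimen, group) study cells keep independent
derived seeds.

## Calibration

The numeric drug parameters and physiology slopes are not printed in any
single public source, so the shipped values are calibrated defaults, fixed
once and versioned:

1. Oral anchors: intrinsic clearances, ka and fa were set so young-cohort
   oral steady-state geometric means sit near the reported values
   (CAB ≈ 8.5 µg/mL Cmax, 169 µg·h/mL AUCτ, 5.5 µg/mL Cmin;
   RPV ≈ 198 / 3158 / 98 ng/mL), with enzyme CVs (UGT1A1 0.62, CYP3A4 0.30)
   reproducing the reported exposure CVs.
2. Depot anchors: release rates were calibrated (the `calibrate_depot`
   utility implements the procedure) so young-cohort geometric-mean troughs
   at week 8 and at steady state sit in the published threshold bands
   (CAB ≈ 1.6–1.8 µg/mL at week 8, ≈ 3.5 µg/mL at Q4W steady state;
   RPV ≈ 55 ng/mL at week 8, ≈ 105 ng/mL at Q4W steady state).
3. Aging and sex slopes were then fixed so the relative results — exposure
   ratios and threshold percentages across age and sex groups — fall in the
   reported ranges, and were verified stable across independent master
   seeds.

## Numerical and degenerate-input choices

Zero-width calibration bands are valid targets (exact trough matching);
an unreachable band returns the best parameters found with a convergence
flag. Zero-dose schedules produce identically zero profiles. Non-finite
parameters are rejected before integration. Non-positive metric values are
excluded from geometric statistics with a warning. Hematocrit draws are
clipped to [0.25, 0.55].

## Problem sizes

The shipped study size is 100 individuals per cohort (10 virtual trials of
10), the size the comparisons are designed around; examples use 10–20 for
brevity. A 96-week long-acting simulation takes ~15 ms, so the full
acceptance reproduction (14 cohorts) completes in well under a minute on
one CPU.

## Known limitations

* The model is linear and time-invariant: depot release is first order with
  a dose-independent rate. One consequence is that at steady state the AUCτ
  ratio between two populations equals their clearance ratio for *any*
  maintenance frequency — monthly and bimonthly AUC fold changes cannot
  differ. Reported data in which they do differ imply saturable,
  depot-size-dependent dissolution that this engine intentionally does not
  model (it would sacrifice the superposition guarantees the test suite is
  built on). Trough fold changes *do* depend on the frequency through the
  interval length and are the primary comparison endpoints here.
* All injections deposit in muscle: the ideal administration scenario.
  Real-world injection-site variability (accidental adipose deposition,
  inter-occasion variability) is not represented, so real-world variance
  will exceed the simulated one.
* Perfusion-limited tissues only; no lymphatic uptake, no transporters, no
  metabolites, no drug–drug interactions, no adherence modelling.
* Passing tests show the *relative* aging/sex effects are reproduced under
  this synthetic population's trend assumptions; they do not validate the
  physiology equations against measured organ data, and absolute
  concentrations carry the uncertainty of the calibrated defaults.
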