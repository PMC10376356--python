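# Methods

## The dosing problem

Meropenem is a time-dependent beta-lactam: efficacy tracks the fraction of
the dosing interval during which the free concentration stays above the
pathogen's MIC (fT>MIC). In septic ICU patients, renal function — the main
determinant of meropenem clearance — spans two orders of magnitude, so a
fixed label dose produces exposures from subtherapeutic to toxic. The
package implements a two-stage individualization program for continuous
infusion (CI):

1. **Empiric stage** — predict clearance from renal function and solve the
   CI steady-state relation for the dose that hits a target concentration.
2. **TDM stage** — measure the achieved concentration, convert it to an
   observed clearance, and re-dose proportionally.

Exposure is judged against the band 8–16 mg/L (4–8× the *Pseudomonas
aeruginosa* ECOFF of 2 mg/L); 16–24 mg/L is moderately high, >24 mg/L
potentially harmful, and <2 mg/L subtherapeutic.

## Pharmacokinetic model

One compartment, first-order elimination: `dC/dt = R(t)/V − (CL/V)·C`,
with clearance CL (L/h) and volume V (L). Closed forms used:

* constant-rate infusion from a drug-free state:
  `C(t) = (R0/CL)(1 − e^(−ke t))`, steady state `Css = R0/CL =
  daily_dose/(24·CL)` — V-independent, which is why the headline CI results
  are insensitive to V;
* single short infusion: the same rise, then mono-exponential decay;
* repeated intermittent infusions at steady state: superposition with
  accumulation factor `1/(1 − e^(−ke τ))`; the trough (at t = τ) is the
  classified value for the bolus arm, as the binding statistic for
  100% fT>MIC.

`conc_by_ode` integrates the ODE numerically (DOP853, rtol 1e-10) from the
piecewise-constant infusion schedule and shares no code with the closed
forms; tests and the acceptance sweep require agreement to a relative
1e-6 (1e-4 for the 40-dose superposition check, limited by residual
accumulation).

**V default = 25 L**: a typical meropenem distribution volume in critically
ill adults. It only affects transients and bolus troughs, not CI steady
states. Configurable.

## Renal function and clearance prediction

Creatinine clearance (mL/min) by Cockcroft–Gault:
`CrCL = (140 − age)·weight / (72·SCr)`, ×0.85 for women, actual body
weight, no cap by default (an optional cap is exposed because hyperdynamic
patients can show augmented renal clearance; the emulated population has
none). Ages ≥140 clamp to 0 with a warning rather than going negative.

Drug clearance by the Dettli rule — non-renal floor plus a renal part
linear in CrCL:

```
CL_pred = q0·CL_normal + (1 − q0)·CL_normal·(CrCL / CrCL_ref)
```

Defaults `CL_normal = 12.5 L/h`, `q0 = 0.25`, `CrCL_ref = 100 mL/min`.
These anchor the anuric floor at 3.125 L/h and put the prediction at the
cohort-median CrCL of 45.3 mL/min at 7.37 L/h, the scale reported for
renal dosing calculators in this population. All four constants are
config-overridable.

Under CRRT the renal term is replaced by the extracorporeal clearance
`saturation_coefficient × effluent_flow` (defaults 1.0 and 2.0 L/h;
meropenem is small and essentially unbound, so saturation ≈ 1). Residual
renal clearance on CRRT is excluded by default — continuous dialysis
patients are treated as oligoanuric — with a flag to include it.

## Dose selection and adjustment

* **Empiric CI dose**: `daily = setpoint × CL_pred × 24`, setpoint 12 mg/L
  (band midpoint), rounded to 100 mg (pump-practical), clamped to
  500–6000 mg/day (label ceiling for serious infections).
* **Loading dose**: fixed 500 mg over 15 min, excluded from maintenance
  accounting.
* **TDM adjustment**: observed clearance `CL_obs = (daily/24)/c` assuming
  the sample is a CI steady state (samples within 6 h of a dose change are
  flagged non-steady-state); new dose `setpoint × CL_obs × 24`, same
  rounding and bounds. Measurements already in 8–16 mg/L leave the dose
  untouched (no-touch rule, configurable). Proportional re-dosing with a
  no-touch band is the simplest rule consistent with expert practice:
  noise-free, one step lands every patient in band, and it is idempotent
  on in-band measurements.
* **Label comparison arm**: German SmPC renal tiers (CrCL >50:
  1000 mg q8h; 26–50: 1000 mg q12h; 10–25: 500 mg q12h; <10: 500 mg q24h;
  CRRT: 1000 mg q12h), classified either as 0.5 h bolus troughs or as the
  same daily dose given as CI.

## Band conventions

Half-open intervals with ties upward — 8.0 is therapeutic, 16.0 moderately
high — except 24.0, which stays moderately high because the harmful band
is defined strictly as >24 mg/L. Table percentages are printed to one
decimal, half-up.

## Statistics

Odds ratios are the cross-product `ad/bc` with the Woolf log-scale CI,
`exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`; zero cells fall back to
Haldane–Anscombe +0.5 with a flag. Chi-square tests are Pearson without
Yates correction by default (matching how the source counts were
analyzed); sparse 2×2 tables (min expected <5) report Fisher's exact test
instead, flagged. The unpaired two-proportion comparison of therapeutic
attainment before vs after TDM (55/91 vs 96/138) gives p ≈ 0.15; a paired
per-patient construction could differ, but patient-level pairing is not
available, so the package reports the unpaired test.

## Synthetic cohort

The generator emulates a septic ICU cohort: age truncated-normal
(median 73, IQR 18, bounds 18–100), weight log-normal (80, IQR 20), height
truncated-normal (170, IQR 10), 66% male, SOFA/SAPS truncated-normal
(8/41), 13% CRRT. CrCL is drawn log-normal (median 45.3, IQR 53.7 mL/min)
and capped at 130 mL/min — the emulated population shows no augmented
renal clearance — and serum creatinine is back-derived by inverting
Cockcroft–Gault so the cohort CSV is self-consistent. Distribution
families are a modeling choice; only medians/IQRs are constrained.

True clearance is latent: `CL_true = CL_pred × exp(η)`,
`η ~ N(0, ω²)` truncated at ±2 SD. **ω = 0.25** was calibrated once, ahead
of testing, so the predicted-vs-observed clearance Pearson r of a default
cohort sits in the low-to-mid 0.8s — the agreement scale reported for
renal dosing calculators against measured clearances in this population
(calibration, not validation). The ±2 SD truncation keeps clearances in
the physiologic range actually seen in such cohorts (max ≈ 25 L/h), which
also means the 6 g/day dose ceiling never pushes a noise-free adjusted
steady state out of band. Measurements carry proportional assay noise,
default CV 10%.

Mortality is generated from SOFA alone — logistic with slope ln(1.161)
per point and intercept −1.835, solved so cohort-mean mortality ≈ 39%
under the SOFA marginal. Concentration therefore has no causal effect on
death in the synthetic world, and the mortality-by-band odds ratio should
straddle 1; with a well-calibrated program the harmful band is usually
empty, so the 2×2 falls back to moderately-high vs therapeutic and records
which band was used.

Simulated program per patient: loading dose (bookkeeping only — washed out
by sampling time), empiric CI dose, one sample uniform in 24–48 h,
adjustment, then 1–3 samples uniform in 54–168 h under the adjusted dose.
Clearance is constant within a patient (no time-varying renal function).

### What the generator does not emulate

Correlations beyond CrCL→clearance (e.g. SOFA–renal function), within-
patient clearance drift, non-steady-state sampling, assay LLOQ censoring,
and real adjustment behavior of clinicians (who deviate from proportional
rules). Passing simulation tests therefore demonstrates the internal
consistency of the pipeline under its stated noise model, not clinical
performance.

## Problem sizes and determinism

Default simulations use n = 500 patients (~1450 measurements), enough to
estimate band fractions to ±2 percentage points while keeping the whole
suite fast. Every random quantity flows from an explicit integer seed
through `numpy.random.default_rng`; the measurement stream is derived from
the seed via a `SeedSequence` so cohort and sampling noise are independent
but jointly reproducible. Reported percentages use half-up decimal
rounding; dose rounding is to the nearest increment with ties away from
zero.

## Known limitations

* One-compartment total-concentration model; meropenem protein binding
  (~2%) is ignored as free ≈ total.
* The Dettli constants are population anchors, not fitted values; the
  package makes no claim of predictive accuracy in ARC or ECMO patients.
* The SmPC bolus arm is classified by steady-state trough; other choices
  (mid-interval concentration, fT>MIC itself) would grade the bolus
  strategy differently.
* Multivariable severity-score regressions on mortality are out of scope;
  only the 2×2 band contingency analysis is implemented.
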