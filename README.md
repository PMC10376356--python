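# meropk

Software-guided and TDM-guided meropenem dosing for critically ill
patients, as a tested Python pipeline: renal-function-based empiric dose
calculation (Cockcroft–Gault + Dettli, one-compartment PK), observed-
clearance estimation from measured concentrations, proportional dose
adjustment, exposure-band classification against the 8–16 mg/L therapeutic
target, comparison of dosing strategies, cohort contingency statistics,
and a seeded synthetic ICU cohort generator so the whole pipeline is
reproducible without patient data.

## Who this is for

Clinical pharmacists, PK/PD researchers and methodologists who want a
transparent, testable implementation of continuous-infusion beta-lactam
individualization: what dose a renal dosing calculator would give, what a
therapeutic drug monitoring (TDM) step changes, and how exposures
distribute across the <2, 2–8, 8–16, 16–24 and >24 mg/L bands.

## The model in brief

One-compartment PK with clearance CL and volume V. Under continuous
infusion the steady state is

```
Css = daily_dose / (24 · CL)
```

Empiric dosing predicts CL from renal function (Dettli):
`CL = q0·CL_normal + (1−q0)·CL_normal·(CrCL/CrCL_ref)`, with CrCL from
Cockcroft–Gault, or `CL = q0·CL_normal + sieving·effluent_flow` on CRRT —
then solves `daily_dose = 12 mg/L × CL × 24`. TDM inverts the same
relation: `CL_obs = (daily_dose/24)/c`, and re-doses proportionally.
Cohort statistics use the cross-product odds ratio with the Woolf CI and
Pearson chi-square. Details and all defaults: `docs/methods.md`.

## Worked example

```python
from meropk import (
    TargetDefinition, PopulationPkConfig, RenalStatus,
    crcl_cockcroft_gault, predict_clearance, empiric_daily_dose,
    ConcentrationRecord, adjust_dose, observed_clearance,
)

# 73-year-old man, 80 kg, serum creatinine 1.3 mg/dL
crcl = crcl_cockcroft_gault(age=73, weight=80, serum_creatinine=1.3, sex="male")
status = RenalStatus(serum_creatinine=1.3, crcl=crcl)
cl_pred = predict_clearance(PopulationPkConfig(), status)
regimen = empiric_daily_dose(TargetDefinition(), cl_pred)
print(f"CrCL {crcl:.1f} mL/min -> predicted CL {cl_pred:.2f} L/h -> {regimen.daily_dose_mg:.0f} mg/day CI")

# a concentration measured at 36 h under that dose
rec = ConcentrationRecord("P1", time_h=36.0, daily_dose_mg=regimen.daily_dose_mg, value=18.5)
adjusted = adjust_dose(regimen, rec, TargetDefinition())
print(f"measured 18.5 mg/L -> observed CL {observed_clearance(rec):.2f} L/h "
      f"-> adjusted to {adjusted.daily_dose_mg:.0f} mg/day")
```

prints

```
CrCL 57.3 mL/min -> predicted CL 8.49 L/h -> 2400 mg/day CI
measured 18.5 mg/L -> observed CL 5.41 L/h -> adjusted to 1600 mg/day
```

The first line is the empiric stage: moderate renal impairment maps to a
predicted clearance of 8.49 L/h and a 2400 mg/day continuous infusion
aimed at the 12 mg/L setpoint. The measured 18.5 mg/L is above the 8–16
band, so the TDM stage lowers the dose to 1600 mg/day, which puts the
predicted steady state back on the setpoint at the observed clearance.

The same operations are available from the shell:

```
meropk dose --patients cohort.csv --out doses.csv
meropk tdm-adjust --concentrations conc.csv --out adjusted.csv
meropk simulate --out-dir report/          # synthetic end-to-end program
meropk tables                              # recompute published-count statistics
meropk cohort-gen --out-dir data/          # write a synthetic cohort + measurements
```

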