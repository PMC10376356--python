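{
  "description": "Printed cohort counts from the source study (91 septic ICU patients, 229 meropenem concentrations) used by the verification harness. Bands in mg/L.",
  "bands": ["<2", "2-8", "8-16", "16-24", ">24"],
  "concentration_tallies": {
    "software_guided_first48": {"n": 91, "counts": [0, 6, 55, 21, 9]},
    "tdm_guided_post48": {"n": 138, "counts": [0, 13, 96, 29, 0]}
  },
  "strategy_tallies": {
    "standard_bolus": {"n": 229, "counts": [45, 62, 61, 35, 26]},
    "standard_ci": {"n": 229, "counts": [0, 15, 110, 60, 44]},
    "individualized_ci": {"n": 229, "counts": [0, 19, 151, 50, 9]}
  },
  "mortality_2x2": {
    "rows": ["conc >24 mg/L", "conc 8-16 mg/L"],
    "cols": ["died", "survived"],
    "a": 4, "b": 5, "c": 22, "d": 33
  },
  "attainment_comparison": {
    "first48_therapeutic": [55, 91],
    "post48_therapeutic": [96, 138]
  },
  "printed_reference": {
    "therapeutic_pct_first48": 60.4,
    "therapeutic_pct_post48": 69.6,
    "harmful_pct_first48": 9.9,
    "individualized_ci_therapeutic_pct": 65.9,
    "standard_bolus_therapeutic_pct": 26.6,
    "mortality_or": 1.200,
    "mortality_or_ci": [0.290, 4.970],
    "mortality_p": 0.801
  }
}
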