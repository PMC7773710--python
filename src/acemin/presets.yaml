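# Forward-model presets for the six incubation temperatures (degC).
# o2_uM: initial oxygen inventory; rates in uM acetate per day; lag_d: days
# between oxygen exhaustion and sulfide onset; sulfide_yield: mol HS- per
# mol acetate mineralized in the sulfidogenic phase.  The 60 degC setting is
# aerobic-only; 80 degC is inactive.
12:
  o2_uM: 231.2
  phase1_rate_uM_per_d: 12.2
  lag_d: 53.5
  phase2_rate_uM_per_d: 9.8
  sulfide_yield: 0.89
25:
  o2_uM: 358.5
  phase1_rate_uM_per_d: 75.0
  lag_d: 7.6
  phase2_rate_uM_per_d: 18.8
  sulfide_yield: 1.01
38:
  o2_uM: 330.5
  phase1_rate_uM_per_d: 74.1
  lag_d: 7.8
  phase2_rate_uM_per_d: 22.9
  sulfide_yield: 0.86
45:
  o2_uM: 326.7
  phase1_rate_uM_per_d: 10.7
  lag_d: 26.7
  phase2_rate_uM_per_d: 7.6
  sulfide_yield: 0.71
60:
  o2_uM: 362.0
  phase1_rate_uM_per_d: 71.4
  lag_d: 0.0
  phase2_rate_uM_per_d: 0.0
  sulfide_yield: 0.0
80:
  o2_uM: 0.0
  phase1_rate_uM_per_d: 0.0
  lag_d: 0.0
  phase2_rate_uM_per_d: 0.0
  sulfide_yield: 0.0
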