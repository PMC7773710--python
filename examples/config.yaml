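isotope:
  r13_vpdb: 0.0111802
  bicarbonate_mM: 30.0
  acetate_mM: 1.0
  n_labeled: 2
  label_purity: 0.99
kinetics:
  sulfide_detection_uM: 10.0
  plateau_tol_permil: 50.0
stoichiometry:
  o2_per_acetate: 2.0
  sulfide_per_acetate: 1.0
  hco3_per_acetate: 2.0
community:
  order_threshold: 0.05
  genus_threshold: 0.03
  rarefaction_seed: 0
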