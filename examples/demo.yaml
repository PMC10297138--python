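seed: 5
simulate:
  compounds:
    - {compound_id: ACT1, f_max: 4.0}
    - {compound_id: INH1, f_max: 0.1}
    - {compound_id: TOX1, toxicity: 0.9}
  n_inactive: 5
  n_neg: 6
  n_pos: 2
  n_no_biotin: 2
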