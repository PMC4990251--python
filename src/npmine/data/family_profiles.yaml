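# Default peptide-family profiles, evaluated in order; first match wins.
- name: insulin_like
  positional_rules:
    allow_partial_b_chain: true
- name: vasopressin
  positional_rules:
    cys_positions: [1, 6]
    length_range: [9, 16]
- name: GPB5
  positional_rules:
    length_range: [80, 130]
    min_cys: 9
- name: pedal_orcokinin_FDSIG
  motif_patterns: ["IG.G"]
  positional_rules:
    length_range: [10, 16]
- name: NPF
  motif_patterns: ["R.R[FY]$"]
  positional_rules:
    fallback_length_range: [30, 40]
    fallback_min_sulfated_tyr: 2
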