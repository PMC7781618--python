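# Minimal demo: two short-splice-variant cohorts, I-V protocol only.
# Cohort means come from the bundled reference rows; n is kept small so the
# whole simulate -> analyze -> compare chain runs in seconds.
cohorts:
  - construct: "8b 43S"
    table: splice_43S
    n_cells: 4
  - construct: "8b 11 43S"
    table: splice_43S
    n_cells: 4
protocols:
  kinds: [IV]
preprocess:
  leak: offline
comparisons: reference
seed: 1
out_dir: cavgating_out
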