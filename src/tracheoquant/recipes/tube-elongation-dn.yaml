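name: tube-elongation-dn
description: >
  Dorsal-trunk elongation under EGFR downregulation: two cohorts of 20
  tube phantoms (control tortuosity 1.10 vs a 22.6% longer mutant-like
  cohort), auto-traced and compared by percent difference of mean
  arc/chord ratios with a pooled t-test.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: tube_cohorts
    params:
      control: control
      length_um: 40.0
      diameter_um: 3.0
      groups:
        control: {tortuosity: 1.10, n: 20}
        egfr_dn: {tortuosity: 1.3486, n: 20}
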