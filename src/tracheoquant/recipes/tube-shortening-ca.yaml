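name: tube-shortening-ca
description: >
  Mild dorsal-trunk shortening under constitutive EGFR activation: control
  cohort (tortuosity 1.10) vs a cohort reduced by 3%, measured as the
  percent reduction of mean arc/chord ratio.
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
        egfr_ca: {tortuosity: 1.067, n: 20}
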