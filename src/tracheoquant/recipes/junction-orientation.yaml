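name: junction-orientation
description: >
  Axial vs circumferential junction-length comparison on lattice phantoms:
  a control group and a group with elongated axial junctions, classified
  by folded chord angle (axial within 30 deg of the tube axis) and
  compared per class by pooled t-test.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: junction_comparison
    params:
      n_cells: 50
      orientation_jitter_deg: 5.0
      length_sd_um: 0.15
      groups:
        control: {axial_length_um: 2.0, circumferential_length_um: 1.0}
        elongated: {axial_length_um: 2.5, circumferential_length_um: 1.0}
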