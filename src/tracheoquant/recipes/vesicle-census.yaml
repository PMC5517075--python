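name: vesicle-census
description: >
  Cargo census of sorting endosomes: a 194-vesicle two-channel field with
  class probabilities 0.67/0.15/0.18 (dual-cargo / channel-1 only /
  channel-2 only), detected, cargo-classified and tallied.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: vesicle_census
    params:
      n_vesicles: 194
      p_both: 0.67
      p_ch1_only: 0.15
      p_ch2_only: 0.18
      diameter_um_mean: 0.55
      diameter_um_sd: 0.05
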