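name: straight-tube-ratio
description: >
  Arc/chord tortuosity of a perfectly straight traced dorsal-trunk path;
  a ratio of 1 means a straight tube.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: straight_ratio
    params:
      length_um: 40.0
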