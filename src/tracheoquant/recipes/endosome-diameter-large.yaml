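name: endosome-diameter-large
description: >
  Diameter recovery of enlarged (1.3 um) endosomes at 0.1 um/px under the
  default acquisition model, via LoG detection, half-maximum segmentation
  and PSF-corrected equivalent-circle diameter.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: diameter_recovery
    params:
      n_vesicles: 30
      diameter_um: 1.3
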