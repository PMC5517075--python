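name: endosome-diameter-small
description: >
  Diameter recovery of small (0.28 um) recycling endosomes near the
  resolution limit, sampled at 0.05 um/px without noise; PSF broadening
  removed by blurred-disc inversion.
seed: 0
pixel_size_um: 0.05
stages:
  - kind: diameter_recovery
    params:
      n_vesicles: 30
      diameter_um: 0.28
      imaging:
        pixel_size_um: 0.05
        psf_sigma_um: 0.1
        poisson_noise: false
        read_noise_sigma: 0.0
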