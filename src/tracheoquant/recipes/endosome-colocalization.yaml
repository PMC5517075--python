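name: endosome-colocalization
description: >
  Within-endosome colocalized-signal fraction: 118 dual-cargo endosomes
  generated with 60% of each cargo's signal in the shared sub-domain;
  per-object thresholded-ratio (cutoff 0.5) integrated-density fractions
  averaged across endosomes.
seed: 0
pixel_size_um: 0.05
stages:
  - kind: coloc_overlap
    params:
      n_vesicles: 118
      within_vesicle_overlap: 0.6
      diameter_um_mean: 0.6
      diameter_um_sd: 0.05
      ratio_cutoff: 0.5
      imaging:
        pixel_size_um: 0.05
        psf_sigma_um: 0.1
        read_noise_sigma: 1.0
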