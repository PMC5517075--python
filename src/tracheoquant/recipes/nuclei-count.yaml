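name: nuclei-count
description: >
  Tracheal cell-number census: nuclei counting on four phantom stacks with
  planted counts 25/26/25/26 (group mean 25.5), blob detection plus
  watershed splitting.
seed: 0
pixel_size_um: 0.1
stages:
  - kind: nuclei_count
    params:
      n_images: 4
      n_nuclei: [25, 26, 25, 26]
      nucleus_diameter_um: 2.5
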