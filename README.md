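# tracheoquant

Morphometric and trafficking quantifications for tubular epithelia, with a
synthetic fluorescence phantom generator that plants known ground truth so
every measurement can be verified without microscopy data.

The package targets the image-analysis workflow used to characterize
tube-size and cargo-trafficking phenotypes in the *Drosophila* embryonic
tracheal system — the dorsal trunk (DT), its cells' apical junctions, the
apical determinant Crumbs (Crb), the luminal chitin deacetylase Serpentine
(Serp), and the sorting endosomes both proteins transit — but the
measurements are generic to any tubular epithelium imaged by confocal
fluorescence microscopy.

## What it measures

- **Tube tortuosity** — the arc-to-chord ratio of a traced tube path,
  `ratio = L_arc / L_chord`, where `L_arc` is the traced path length and
  `L_chord` the straight distance between the two anchor landmarks.
  A ratio of 1 is a straight tube. Paths can be supplied as polyline ROIs
  or traced automatically (Otsu threshold → skeletonize → shortest
  skeleton path between anchors).
- **Junction orientation morphometrics** — each junction segment's chord
  angle relative to the tube axis (axis = 0°), folded into [0°, 90°];
  axial = 0° ± 30°, circumferential = 90° ± 30°, the rest unclassified;
  per-class length means, standard errors and group comparisons.
- **Normalized intensity ratio (DT/MT)** — mean fluorescence in a wide
  band (default width 60 px) traced along the tube of interest, divided by
  the mean in a narrow band (width 10 px) along the Malpighian tubules, an
  internal reference that cancels specimen-to-specimen staining variation.
- **Subcellular accumulation ratio (SAR/AFR)** — summed fluorescence in a
  band on the traced cell contour (subapical region) over the summed
  fluorescence of an inner apical region facing the lumen.
- **Thresholded-ratio colocalization** — a pixel is colocalized when both
  channels exceed their thresholds and `min(I₁, I₂) / max(I₁, I₂) ≥ 0.5`;
  per channel, the colocalized-signal fraction is the integrated density
  over the mask divided by the integrated density over that channel's
  above-threshold pixels (Manders-style), reported field-wide and per
  endosome.
- **Endosome census and diameters** — Laplacian-of-Gaussian blob
  detection, half-maximum segmentation, equivalent-circle diameters with
  optional PSF-broadening inversion, cargo classification
  (both / channel-1 only / channel-2 only) and the census of proportions.
- **Nuclei counting** — blob detection with watershed splitting for cell
  number per tube region.
- **Statistics** — unpaired two-tailed pooled-variance Student's t-tests,
  standard errors, percent differences vs control, significance stars
  (\*P<0.05, 0.001<\*\*P<0.01, \*\*\*P<0.001), box-plot summaries.

Each quantity has a phantom generator (`tracheoquant.phantoms`) that
renders the corresponding structure — curved tube, junction lattice,
two-channel vesicle field with per-vesicle cargo composition and
sub-domain overlap, apical cell with contour band, nuclei field — under a
Gaussian-PSF + Poisson + read-noise acquisition model, and records the
generating truth for parameter-recovery testing.

## Worked example

```bash
python examples/01_tube_tortuosity.py
```

```
planted arc/chord ratio : 1.2261
traced arc length       : 39.96 um
traced chord length     : 32.63 um
measured arc/chord ratio: 1.2248
```

A tube phantom is generated whose centerline is 22.6% longer than the
straight line between its anchors (planted ratio 1.226); automatic
tracing recovers 1.2248, within 0.2% of the truth. The other examples
cover junction orientation (`02`), the DT/MT and SAR/AFR intensity ratios
(`03`), per-endosome colocalization (`04`), the endosome cargo census
(`05`) and end-to-end recipes (`06`); each prints the planted value next
to the recovered one.

A thin CLI mirrors the library:

```bash
tracheoquant simulate --kind vesicles --out field.tif --seed 0
tracheoquant vesicles --image field.tif
tracheoquant run vesicle-census --seed 0 --out results/
tracheoquant recipes   # list bundled experiment recipes
```

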