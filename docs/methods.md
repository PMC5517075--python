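# Methods

This note documents the measurement definitions, the synthetic-data model
behind the test suite, the numerical choices, and the limits of what the
phantom-based validation shows.

## Measurement definitions

**Tortuosity.** For a traced tube path `p₁ … pₙ` (pixel coordinates), the
arc length is the sum of Euclidean segment lengths times the pixel size,
the chord is the straight distance between the first and last point (the
two anchor landmarks of the tracing), and the tortuosity is arc/chord.
The statistic is dimensionless, ≥ 1 up to floating rounding, equal to 1
iff the path is collinear with its endpoints, and invariant to rotation,
translation and uniform scaling. Automatic tracing thresholds the lumen
channel (Otsu), closes small gaps (disk radius 2), skeletonizes, and
takes the weighted shortest path along the 8-connected skeleton between
the skeleton pixels nearest each anchor; the chain is Gaussian-smoothed
(σ = 2 px, endpoints pinned) before length measurement because a raw
8-connected pixel chain systematically overestimates arc length through
staircase steps. The anchors themselves are prepended/appended so the
measured path runs landmark to landmark. Chord-from-endpoints replaces a
separately traced straight reference path; the two are equivalent by
construction and it removes one manual tracing.

**Junction orientation.** A segment's orientation is the angle of its
endpoint-to-endpoint chord relative to the tube axis (axis = 0°), folded
into [0°, 90°] since orientation is undirected:
`fold(θ) = |((θ − axis + 90) mod 180) − 90|`. Classes: axial for angle
≤ 30°, circumferential for angle ≥ 60°, otherwise unclassified. The named
bands are closed (30° is axial, 60° circumferential) so each band is the
closed interval its "±30°" definition spells; boundary assignment is a
convention the angle data cannot decide. Segments in (30°, 60°) are
excluded from the two-class comparison. The chord convention (rather
than a total-least-squares fit through all points) matches the overall
orientation of a freehand-traced junction; a TLS mode exists behind
`segment_angle(..., fit="tls")`.

**Band intensity ratios.** A band of width *w* around a polyline is the
set of pixels whose centers lie within perpendicular distance *w*/2 of
the polyline — per-segment rectangular strips with discs at interior
vertices, no end caps, so a straight 10-pixel line of width 3 covers
exactly 30 pixels. The DT/MT ratio uses band means (default widths 60
and 10 px, the conventional wide-line widths for whole-tube and
reference-tubule tracings) because the two bands differ grossly in size
and the ratio must not depend on traced length; whether the original
wide-line measurements averaged or summed pixels is not recoverable from
the method description, so the mean was chosen and the widths are
configurable. The SAR/AFR ratio uses sums: SAR is the band (default
width 3 px) centered on the closed cell-contour ring, AFR the pixels
inside an inner polygon; the two pixel sets must be disjoint, and the
ratio is undefined (raised) when the AFR sum is zero. No background
subtraction is applied by default; a constant-offset option exists.

**Colocalization.** With per-channel thresholds t₁, t₂ (Otsu when not
given) and ratio cutoff c (default 0.5), a pixel is colocalized iff
I₁ > t₁, I₂ > t₂ and min(I₁,I₂)/max(I₁,I₂) ≥ c. The symmetric min/max
form makes the criterion channel-order invariant; the literal directional
red/green ratio is available behind a flag. The colocalized-signal
fraction of channel K is its integrated density over the mask divided by
its integrated density over its own above-threshold pixels; a pixel-count
variant is reported alongside because "number of pixels" and "integrated
density" are distinct readouts that coincide only for flat signals.
Per-object fractions restrict numerator and denominator to an object's
pixel set (ROI polygon, boolean mask, or centroid+radius disc); objects
with no above-threshold pixels are flagged and excluded from the
across-object mean.

**Vesicles.** Detection runs multi-scale LoG blob detection on the
per-pixel maximum of the selected channels, then segments each blob at
half-maximum above the local background (threshold = background median +
0.5·(peak − background), with the peak taken as the median of the five
brightest window pixels to resist shot-noise inflation of a single
maximum). Diameter is the equivalent-circle diameter 2·√(area/π)·pixel
size. When the PSF σ is known, PSF broadening is inverted through the
exact radial profile of a uniform disc convolved with an isotropic
Gaussian (a Rice integral evaluated by Gauss–Legendre quadrature, with a
cached monotone lookup true-diameter → blurred half-max diameter): a
quadrature subtraction is exact only in the point-object limit, while
this inversion is correct across the size range, which matters for
sizing ~0.3 μm recycling endosomes imaged near the resolution limit.
Cargo presence in channel K requires the vesicle's mean intensity in K
to exceed 2× (configurable) the channel's background median — a proxy
for the by-eye "contains cargo" judgement, which has no published
intensity rule; the census tallies both / ch1-only / ch2-only over
detections with at least one cargo present. The within-vesicle
colocalized fraction is deliberately reported by the colocalization
module, separately from the presence-based census. Nuclei are counted by
Otsu thresholding plus a watershed split seeded at distance-transform
peaks at least one nucleus radius apart, discarding fragments smaller
than a quarter of the nominal nucleus area.

**Statistics.** Group comparisons use the classic pooled-variance
unpaired two-tailed Student's t (df = n₁ + n₂ − 2); Welch's form is an
option. Standard error is s.d./√n. Stars: \* p<0.05, \*\* 0.001<p<0.01,
\*\*\* p<0.001, with strict inequalities at the thresholds. Percent
difference is (mean_other − mean_ctrl)/mean_ctrl · 100. No
multiple-testing correction is applied (none is conventional for these
single-comparison figures); a report running more than five comparisons
carries a flag saying so. Measurements are pooled across cells
regardless of specimen of origin, as is conventional for these figures;
treating the specimen as the experimental unit (mixed models) is out of
scope and the tables retain enough structure to regroup.

## Synthetic-data model

All phantoms share one acquisition model: the noise-free scene is blurred
with an isotropic Gaussian PSF (default σ = 0.2 μm, about the lateral
resolution of a high-NA confocal), Poisson shot noise resamples the
blurred signal, Gaussian read noise (default σ = 2 intensity units) is
added, and the result is clipped to the detector bit depth (default
16-bit). The default pixel size is 0.1 μm/px so the smallest quoted
object (~0.3 μm) spans ~3 px; diameter-recovery and colocalization
recipes that need finer sampling use 0.05 μm/px. A single integer seed
drives deterministic per-purpose sub-streams (placement, class draws,
sizes, noise), so identical parameters and seed give bit-identical
images and ground truth. Ground-truth quantities are always computed
from the planted geometry, never from rendered pixels.

- **Tube**: the centerline is a single-period sinusoid spanning a chord
  of `length/tortuosity`; its amplitude is solved by bisection (ratio
  tolerance 1e-4) so the planted arc/chord ratio hits the requested
  tortuosity. The rendered tube is all pixels within one radius of the
  centerline. The shape is a modeling choice — only the arc/chord
  statistic, not the curve family, is constrained by the phenotype.
- **Junction lattice**: one axial and one circumferential segment per
  cell on a grid, each at its nominal orientation plus Gaussian jitter
  (and optional Gaussian length variability), anti-aliased lines;
  segments, true folded angles, true lengths and the signed jitter draws
  are recorded.
- **Vesicle field**: centers rejection-sampled at a minimum separation;
  classes drawn i.i.d. from (p_both, p_ch1, p_ch2). The census recipe
  uses (0.67, 0.15, 0.18): the three quoted percentages sum to 0.99 and
  the remainder is assigned to the dual-cargo class. Dual-cargo vesicles
  split each channel between a private flank and a shared central band
  of the disc; the shared-band pixel count is sized to the target signal
  overlap and the private-pixel intensity is then solved exactly, so the
  planted per-channel integrated-density overlap equals
  `within_vesicle_overlap` to machine precision per vesicle.
- **Apical cell**: polygon mask; the SAR band is the in-mask pixels
  within the band width of the boundary (distance transform, with a
  1e-6 px tolerance so integer-width bands are closed), the AFR the
  rest; the generating ratio is recorded from exhaustive pixel counts,
  or flagged undefined when the interior intensity is zero.
- **Nuclei**: non-overlapping uniform discs at a minimum separation.

**Cohort conditions.** The tube-cohort recipes compare 20 control
phantoms against 20 mutant-like phantoms. The control tortuosity is set
to 1.10 — a mildly curved, realistic control trunk (the phenotype
figures show controls visibly above the straight-line minimum); the
elongated cohort plants 1.10 × 1.226 and the shortened cohort
1.10 × 0.97, i.e. the +22.6% and −3% effects are planted as
multiplicative shifts of the group mean. The census field plants 194
vesicles, the colocalization field 118 dual-cargo endosomes at 60%
signal overlap (pixel 0.05 μm, PSF σ 0.1 μm, read noise 1 — a low-noise,
high-zoom acquisition as appropriate for single-endosome insets), and
the cell-number recipe four stacks with 25/26/25/26 nuclei. These sizes
keep each recipe in the seconds-to-a-minute range while matching the
reference sample sizes where those are meaningful (n = 194, n = 118).

**What the phantoms do not emulate.** Real trachea have branching tubes,
out-of-focus haze, chromatic misregistration, autofluorescent gut, and
touching/overlapping endosomes in 3-D; junctions are curved and form a
connected lattice; staining varies within a specimen. Passing recovery
tests therefore shows the *measurement definitions and pipeline* are
correct and unbiased under a standard acquisition model — not that
detection or tracing is robust to every real-data failure mode. Manual
ROI input remains the primary path for real images; automation
(tracing, detection) is a convenience layered on top.

## Numerical choices and degenerate inputs

- Angle folding uses exact modular arithmetic; classification outside
  [0°, 90°] is a contract violation, not a silent clamp.
- Zero pooled variance in the t-test: equal means → t = 0, p = 1;
  unequal means → flagged degenerate with p = 0.
- Ratios with zero denominators (MT mean, AFR sum, above-threshold
  density, empty census) raise or report NaN with a flag rather than
  returning a number.
- Band membership is binary by pixel center against exact
  point-to-segment distances, not a raster approximation, so unit tests
  can compare against a literal per-pixel oracle.
- Vesicle placement retries are bounded (400 per vesicle); an
  overcrowded field raises a placement error rather than looping.
- Diameter inversion returns the smallest tabulated diameter when the
  measured footprint is at or below the PSF's own half-max footprint —
  the floor of what the data can support.

## Known limitations

- The blurred-disc diameter inversion assumes in-focus uniform discs; at
  ~0.3 μm the discrete-grid bias still reaches ~10–15%, inside the 20%
  band used for that regime but not better.
- With the PSF enabled, band-mean ratios (DT/MT) acquire a small bias
  from edge signal leaving the narrow reference band; the recovery tests
  therefore exercise shot noise without blur. On real images the same
  effect argues for tracing reference bands generously wide.
- The junction generator plants straight segments; curved junctions
  would make the chord-vs-TLS angle convention matter more than it does
  here.
- Colocalization thresholds default to per-channel Otsu; on sparse
  fields with heavy background structure a manual threshold is the
  safer choice, and all thresholds are explicit parameters.
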