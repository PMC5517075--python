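"""Thresholded-ratio colocalization: build the binary mask (both channels
above threshold and intensity ratio >= 0.5) and compute per-endosome
colocalized-signal fractions.

A field of dual-cargo endosomes is generated with 60% of each cargo's
signal planted in a shared sub-domain; the per-object fractions should
average close to 0.60.
"""

from tracheoquant import (
    ColocParams,
    ImagingParams,
    VesicleFieldParams,
    generate_vesicle_field,
    per_object_coloc,
)

imaging = ImagingParams(pixel_size_um=0.05, psf_sigma_um=0.1, read_noise_sigma=1.0, seed=0)
params = VesicleFieldParams(
    n_vesicles=60, p_both=1.0, p_ch1_only=0.0, p_ch2_only=0.0,
    within_vesicle_overlap=0.6, diameter_um_mean=0.6,
)
img, truth = generate_vesicle_field(params, imaging)

# circle each planted endosome, as one would select vesicles by hand
objects = [
    (v["centroid"], v["diameter_um"] / 2 / imaging.pixel_size_um + 2)
    for v in truth.vesicles
]
res = per_object_coloc(img, "ch1", "ch2", objects, ColocParams(ratio_cutoff=0.5))

print(f"endosomes analysed          : {len(objects)}")
print(f"field-level fraction ch1    : {res.fraction_ch1:.3f}")
print(f"field-level fraction ch2    : {res.fraction_ch2:.3f}")
print(f"mean per-endosome fraction  : {res.mean_object_fraction:.3f} (planted 0.600)")
# The mean per-endosome fraction is the share of each cargo's integrated
# signal lying in pixels where both cargoes coincide at comparable
# intensity — the degree of shared sub-domain occupancy.
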