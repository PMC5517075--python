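"""Junction orientation morphometrics: classify junction segments as
axial (within 30 degrees of the tube axis) or circumferential (within 30
degrees of the perpendicular) and compare their lengths between groups.

Two lattice phantoms are generated: a control and a group with elongated
axial junctions, mimicking a cell-shape bias along the tube axis.  The
pooled t-test on the axial class should flag the planted difference.
"""

from tracheoquant import (
    ImagingParams,
    JunctionLatticeParams,
    PolylineROI,
    generate_junction_lattice,
    make_segment,
    summarize_junctions,
)

segments = []
for group, axial_len, seed in [("control", 2.0, 1), ("elongated", 2.5, 2)]:
    params = JunctionLatticeParams(
        n_cells=40, axial_length_um=axial_len, circumferential_length_um=1.0,
        length_sd_um=0.15, orientation_jitter_deg=5.0,
    )
    _, truth = generate_junction_lattice(params, ImagingParams(seed=seed))
    for s in truth.junction_segments:
        segments.append(make_segment(PolylineROI(s["polyline"]), 0.1, group=group))

summary, comparisons = summarize_junctions(segments)
print(summary.to_string(index=False))
for cls, comp in comparisons.items():
    print(
        f"{cls}: mean {comp.means[0]:.2f} vs {comp.means[1]:.2f} um, "
        f"t = {comp.t_statistic:.2f}, p = {comp.p_value:.2e} {comp.star}"
    )
# Expect a *** difference for the axial class (2.0 vs 2.5 um planted)
# and no significant difference for the circumferential class.
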