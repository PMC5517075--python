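"""Synthetic fluorescence phantoms with known ground truth.

Every structure the measurement modules quantify can be generated here with
its generating parameters recorded, so each statistic (arc/chord tortuosity,
junction angles, intensity ratios, colocalized fractions, cargo census,
nuclei counts) has a recoverable truth without any microscopy data.

Acquisition model: the noise-free scene is blurred with an isotropic
Gaussian PSF, shot noise is applied as Poisson resampling of the blurred
signal, Gaussian read noise is added, and the result is clipped to the
detector bit depth.  Identical parameters and seed produce bit-identical
images.

Ground-truth geometric quantities are always computed from the planted
geometry, never from rendered pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, PlacementError
from .image import MultiChannelImage, PolygonROI

__all__ = [
    "ImagingParams",
    "TubePhantomParams",
    "JunctionLatticeParams",
    "VesicleFieldParams",
    "ApicalCellParams",
    "NucleiFieldParams",
    "GroundTruth",
    "generate_tube",
    "generate_junction_lattice",
    "generate_vesicle_field",
    "generate_apical_cell",
    "generate_nuclei_field",
    "fold_angle_deg",
]

GROUND_TRUTH_SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition parameters shared by all phantom generators.

    pixel_size_um
        Lateral sampling, micrometres per pixel.  Default 0.1 so the
        smallest object of interest (a ~0.3 um recycling endosome) spans
        ~3 px; recipes that need finer sampling use 0.05.
    psf_sigma_um
        Isotropic Gaussian PSF sigma.  Default 0.2 um, roughly the lateral
        resolution of a high-NA confocal.
    read_noise_sigma
        Additive Gaussian noise (intensity units) applied after shot noise.
    bit_depth
        8 or 16; rendered intensities are clipped to the detector range.
    """

    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.2
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.psf_sigma_um < 0:
            raise ParameterError("psf_sigma_um must be >= 0")
        if self.read_noise_sigma < 0:
            raise ParameterError("read_noise_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class TubePhantomParams:
    """A single curved bright tube (lumen channel) on dark background.

    ``tortuosity`` is the target arc/chord ratio of the centerline between
    its two endpoint landmarks; the rendered tube follows a single-period
    smooth sinusoid whose amplitude is solved to hit that ratio.
    """

    length_um: float = 40.0
    diameter_um: float = 3.0
    tortuosity: float = 1.0
    waviness_wavelength_um: float | None = None
    lumen_intensity: float = 180.0
    background_intensity: float = 5.0
    fov_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.tortuosity < 1:
            raise ParameterError("tortuosity must be >= 1")
        if not 0 < self.diameter_um < self.length_um:
            raise ParameterError("need 0 < diameter_um < length_um")


@dataclass(frozen=True)
class JunctionLatticeParams:
    """A jittered lattice of axial and circumferential junction segments."""

    n_cells: int = 25
    axial_length_um: float = 2.0
    circumferential_length_um: float = 1.0
    length_sd_um: float = 0.0
    orientation_jitter_deg: float = 5.0
    tube_axis_deg: float = 0.0
    junction_intensity: float = 160.0
    background_intensity: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.axial_length_um <= 0 or self.circumferential_length_um <= 0:
            raise ParameterError("junction lengths must be > 0")
        if self.orientation_jitter_deg < 0:
            raise ParameterError("orientation_jitter_deg must be >= 0")
        if self.length_sd_um < 0:
            raise ParameterError("length_sd_um must be >= 0")


@dataclass(frozen=True)
class VesicleFieldParams:
    """A two-channel field of vesicles with per-vesicle cargo composition.

    Class probabilities follow the dual-cargo census convention: ``p_both``
    vesicles carry both cargoes, split between two private sub-domains and
    a shared central sub-domain so that a fraction ``within_vesicle_overlap``
    of each channel's integrated signal lies in the shared sub-domain.
    """

    n_vesicles: int = 100
    diameter_um_mean: float = 0.55
    diameter_um_sd: float = 0.05
    p_both: float = 0.67
    p_ch1_only: float = 0.15
    p_ch2_only: float = 0.18
    within_vesicle_overlap: float = 0.6
    cargo_intensity: float = 150.0
    background_intensity: float = 10.0
    min_separation_um: float = 1.2
    fov_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if abs(self.p_both + self.p_ch1_only + self.p_ch2_only - 1.0) > 1e-9:
            raise ParameterError("class probabilities must sum to 1 (tol 1e-9)")
        if min(self.p_both, self.p_ch1_only, self.p_ch2_only) < 0:
            raise ParameterError("class probabilities must be >= 0")
        if self.diameter_um_mean <= 0 or self.diameter_um_sd < 0:
            raise ParameterError("diameters must be > 0")
        if not 0 <= self.within_vesicle_overlap <= 1:
            raise ParameterError("within_vesicle_overlap must be in [0, 1]")
        if self.n_vesicles < 0:
            raise ParameterError("n_vesicles must be >= 0")


@dataclass(frozen=True)
class ApicalCellParams:
    """One apical cell: a contour band (SAR) around an interior (AFR)."""

    contour_polygon: tuple = (
        (10.0, 10.0),
        (60.0, 10.0),
        (60.0, 60.0),
        (10.0, 60.0),
    )
    sar_band_width_um: float = 0.3
    sar_intensity: float = 200.0
    afr_intensity: float = 100.0
    background_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.sar_band_width_um <= 0:
            raise ParameterError("sar_band_width_um must be > 0")
        PolygonROI(np.asarray(self.contour_polygon, dtype=float))  # validates


@dataclass(frozen=True)
class NucleiFieldParams:
    """Scattered non-overlapping bright nuclear discs (DAPI-like)."""

    n_nuclei: int = 25
    nucleus_diameter_um: float = 2.5
    min_separation_um: float = 3.5
    nucleus_intensity: float = 150.0
    background_intensity: float = 5.0
    fov_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ParameterError("n_nuclei must be >= 0")
        if self.nucleus_diameter_um <= 0:
            raise ParameterError("nucleus_diameter_um must be > 0")


# --------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Per-phantom record of the generating parameters and geometry.

    Only the fields relevant to a given phantom are populated.  Coordinates
    are pixel coordinates (x, y); lengths and diameters are micrometres.
    """

    pixel_size_um: float = 0.1
    centerline: list | None = None  # ordered [(x, y), ...]
    landmarks: list | None = None  # [(x, y), (x, y)] chord endpoints
    arc_chord_ratio: float | None = None
    tube_diameter_um: float | None = None
    junction_segments: list = field(default_factory=list)
    vesicles: list = field(default_factory=list)
    nuclei: list | None = None
    sar_afr_true_ratio: float | None = None
    sar_afr_undefined: bool = False
    dt_mt_true_ratio: float | None = None
    extras: dict = field(default_factory=dict)
    schema_version: int = GROUND_TRUTH_SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).exists())
            else str(source)
        )
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# acquisition


def _acquire(clean: np.ndarray, imaging: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    """Apply PSF blur, Poisson shot noise, read noise and bit-depth clip."""
    out = np.asarray(clean, dtype=float)
    sigma_px = imaging.psf_sigma_um / imaging.pixel_size_um
    if sigma_px > 0:
        out = np.stack([ndimage.gaussian_filter(c, sigma_px) for c in out])
    if imaging.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if imaging.read_noise_sigma > 0:
        out = out + rng.normal(0.0, imaging.read_noise_sigma, out.shape)
    return np.clip(out, 0, 2**imaging.bit_depth - 1)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-purpose sub-streams from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def fold_angle_deg(angle_deg: float, axis_deg: float = 0.0) -> float:
    """Fold an undirected orientation into [0, 90] degrees relative to an axis."""
    return abs((angle_deg - axis_deg + 90.0) % 180.0 - 90.0)


def _polyline_arc_chord(points: np.ndarray) -> float:
    seg = np.diff(points, axis=0)
    arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    chord = float(np.hypot(*(points[-1] - points[0])))
    if chord == 0:
        raise GeometryError("degenerate centerline: coincident endpoints")
    return arc / chord


# --------------------------------------------------------------------------
# tube


def _sinusoid_ratio(amplitude: float, chord: float, periods: int, n: int = 4001) -> float:
    x = np.linspace(0.0, chord, n)
    y = amplitude * np.sin(2 * np.pi * periods * x / chord)
    return _polyline_arc_chord(np.column_stack([x, y]))


def _solve_amplitude(tortuosity: float, chord: float, periods: int, tol: float = 1e-4) -> float:
    """Bisect the sinusoid amplitude to the requested arc/chord ratio."""
    if tortuosity <= 1.0 + 1e-12:
        return 0.0
    lo, hi = 0.0, chord
    while _sinusoid_ratio(hi, chord, periods) < tortuosity:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = _sinusoid_ratio(mid, chord, periods)
        if abs(r - tortuosity) < tol:
            return mid
        if r < tortuosity:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_tube(
    params: TubePhantomParams, imaging: ImagingParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a curved bright tube whose centerline hits the target
    arc/chord ratio between its two endpoint landmarks.

    The centerline is a smooth sinusoid spanning a chord of
    ``length_um / tortuosity`` so its arc length equals ``length_um``; the
    amplitude is solved numerically (bisection, ratio tolerance 1e-4).
    """
    ps = imaging.pixel_size_um
    chord_um = params.length_um / params.tortuosity
    if params.waviness_wavelength_um:
        periods = max(1, int(round(chord_um / params.waviness_wavelength_um)))
    else:
        periods = 1
    amp_um = _solve_amplitude(params.tortuosity, chord_um, periods)

    n_pts = 2001
    x_um = np.linspace(0.0, chord_um, n_pts)
    y_um = amp_um * np.sin(2 * np.pi * periods * x_um / chord_um)

    margin_um = params.diameter_um + 4 * imaging.psf_sigma_um + 2 * ps
    width_um = chord_um + 2 * margin_um
    height_um = 2 * (amp_um + margin_um)
    if params.fov_um is not None:
        if width_um > params.fov_um[0] or height_um > params.fov_um[1]:
            raise GeometryError(
                f"tube ({width_um:.1f} x {height_um:.1f} um) does not fit the "
                f"requested field of view {params.fov_um}"
            )
        width_um, height_um = params.fov_um

    w = int(np.ceil(width_um / ps))
    h = int(np.ceil(height_um / ps))
    cx0 = (width_um - chord_um) / 2 / ps
    cy0 = height_um / 2 / ps
    centerline_px = np.column_stack([cx0 + x_um / ps, cy0 + y_um / ps])

    # rasterize the centerline, then dilate to the tube radius via EDT
    seed_mask = np.zeros((h, w), dtype=bool)
    cols = np.clip(np.round(centerline_px[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(centerline_px[:, 1]).astype(int), 0, h - 1)
    seed_mask[rows, cols] = True
    dist = ndimage.distance_transform_edt(~seed_mask)
    tube = dist <= (params.diameter_um / 2) / ps

    clean = np.full((1, h, w), params.background_intensity, dtype=float)
    clean[0][tube] = params.lumen_intensity

    (rng_noise,) = _substreams(imaging.seed, 1)
    img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["lumen"], ps)

    truth = GroundTruth(
        pixel_size_um=ps,
        centerline=centerline_px.tolist(),
        landmarks=[centerline_px[0].tolist(), centerline_px[-1].tolist()],
        arc_chord_ratio=_polyline_arc_chord(centerline_px),
        tube_diameter_um=params.diameter_um,
    )
    return img, truth


# --------------------------------------------------------------------------
# junction lattice


def generate_junction_lattice(
    params: JunctionLatticeParams, imaging: ImagingParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a grid of bright junction segments.

    Each cell contributes one axial segment (drawn at the tube axis plus
    Gaussian jitter) and one circumferential segment (axis + 90 deg plus
    jitter).  Ground truth records every segment's endpoints, true folded
    angle in [0, 90] relative to the tube axis, and true length.
    """
    from skimage.draw import line_aa

    ps = imaging.pixel_size_um
    n_side = int(np.ceil(np.sqrt(params.n_cells)))
    cell_w_um = params.axial_length_um * 1.6
    cell_h_um = params.circumferential_length_um * 1.6 + params.axial_length_um * 0.4
    margin_um = 2.0
    w = int(np.ceil((n_side * cell_w_um + 2 * margin_um) / ps))
    h = int(np.ceil((n_side * cell_h_um + 2 * margin_um) / ps))

    rng_geom, rng_noise = _substreams(imaging.seed, 2)
    clean = np.full((1, h, w), params.background_intensity, dtype=float)
    segments = []

    def draw_segment(cx_um, cy_um, length_um, angle_deg, jitter_deg):
        theta = np.deg2rad(angle_deg)
        half = length_um / 2
        p0 = np.array([cx_um - half * np.cos(theta), cy_um - half * np.sin(theta)]) / ps
        p1 = np.array([cx_um + half * np.cos(theta), cy_um + half * np.sin(theta)]) / ps
        rr, cc, val = line_aa(
            int(round(p0[1])), int(round(p0[0])), int(round(p1[1])), int(round(p1[0]))
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        clean[0][rr[keep], cc[keep]] = np.maximum(
            clean[0][rr[keep], cc[keep]], params.junction_intensity * val[keep]
        )
        segments.append(
            {
                "polyline": [p0.tolist(), p1.tolist()],
                "true_angle_deg": fold_angle_deg(angle_deg, params.tube_axis_deg),
                "true_length_um": float(length_um),
                "jitter_deg": float(jitter_deg),  # signed draw, pre-folding
            }
        )

    placed = 0
    for gy in range(n_side):
        for gx in range(n_side):
            if placed >= params.n_cells:
                break
            cx = margin_um + (gx + 0.5) * cell_w_um
            cy = margin_um + (gy + 0.5) * cell_h_um
            jit = rng_geom.normal(0.0, params.orientation_jitter_deg, 2) \
                if params.orientation_jitter_deg > 0 else np.zeros(2)
            if params.length_sd_um > 0:
                lengths = np.maximum(
                    rng_geom.normal(
                        [params.axial_length_um, params.circumferential_length_um],
                        params.length_sd_um,
                    ),
                    0.2,
                )
            else:
                lengths = np.array(
                    [params.axial_length_um, params.circumferential_length_um]
                )
            draw_segment(
                cx, cy - params.circumferential_length_um * 0.6,
                lengths[0], params.tube_axis_deg + jit[0], jit[0],
            )
            draw_segment(
                cx - params.axial_length_um * 0.6, cy,
                lengths[1], params.tube_axis_deg + 90.0 + jit[1], jit[1],
            )
            placed += 1

    img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["junctions"], ps)
    truth = GroundTruth(pixel_size_um=ps, junction_segments=segments)
    return img, truth


# --------------------------------------------------------------------------
# vesicle field


def _place_points(
    n: int, w: float, h: float, min_sep: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n points with a minimum pairwise separation."""
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(2000, 400 * n)
    while len(pts) < n:
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} objects at separation {min_sep:.1f}px "
                f"in a {w:.0f}x{h:.0f}px field after {max_attempts} attempts"
            )
        attempts += 1
        p = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts).reshape(n, 2)


def _field_size(n: int, min_sep_px: float, margin_px: float, fov_um, ps: float) -> tuple[int, int]:
    if fov_um is not None:
        return int(np.ceil(fov_um[0] / ps)), int(np.ceil(fov_um[1] / ps))
    # ~4x the close-packing area so rejection sampling terminates quickly
    side = int(np.ceil(np.sqrt(max(n, 1) * 4.0) * max(min_sep_px, 1.0) + 2 * margin_px))
    return max(side, 96), max(side, 96)


def _vesicle_pixel_sets(
    center: np.ndarray, radius_px: float, overlap: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a disc into (private-ch1, shared, private-ch2) pixel index sets.

    The shared sub-domain is a central band in the x-order of disc pixels
    sized so that, with matched intensities, a fraction ``overlap`` of each
    channel's integrated signal falls in the shared band.
    """
    h, w = shape
    r = max(radius_px, 1.0)
    y0, y1 = int(np.floor(center[1] - r)), int(np.ceil(center[1] + r)) + 1
    x0, x1 = int(np.floor(center[0] - r)), int(np.ceil(center[0] + r)) + 1
    yy, xx = np.mgrid[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)]
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r**2
    ys, xs = yy[inside], xx[inside]
    order = np.lexsort((ys, xs))  # sort by x, then y
    ys, xs = ys[order], xs[order]
    n = len(xs)
    # shared-band pixel count: m/(m + (n-m)/2) = overlap  =>  m = n*ov/(2-ov)
    m = int(round(n * overlap / (2.0 - overlap))) if overlap < 1 else n
    k = (n - m) // 2
    idx1 = slice(0, k)
    idx_s = slice(k, n - k)
    idx2 = slice(n - k, n)
    return (
        np.stack([ys[idx1], xs[idx1]]),
        np.stack([ys[idx_s], xs[idx_s]]),
        np.stack([ys[idx2], xs[idx2]]),
    )


def generate_vesicle_field(
    params: VesicleFieldParams, imaging: ImagingParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a two-channel vesicle field with per-vesicle cargo classes.

    Classes are drawn multinomially from (p_both, p_ch1_only, p_ch2_only).
    Dual-cargo vesicles carry each channel's signal split between a private
    sub-domain and a shared central sub-domain; per-pixel intensities are
    chosen so the planted integrated-density fraction in the shared
    sub-domain equals ``within_vesicle_overlap`` exactly for each channel.
    """
    ps = imaging.pixel_size_um
    min_sep_px = params.min_separation_um / ps
    margin_px = (params.diameter_um_mean / ps) + 4 * (imaging.psf_sigma_um / ps) + 2
    w, h = _field_size(params.n_vesicles, min_sep_px, margin_px, params.fov_um, ps)

    rng_place, rng_class, rng_size, rng_noise = _substreams(imaging.seed, 4)
    clean = np.full((2, h, w), params.background_intensity, dtype=float)
    truth = GroundTruth(pixel_size_um=ps)

    if params.n_vesicles == 0:
        img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["ch1", "ch2"], ps)
        return img, truth

    centers = _place_points(
        params.n_vesicles, w, h, min_sep_px, margin_px, rng_place
    )
    classes = rng_class.choice(
        ["both", "ch1_only", "ch2_only"],
        size=params.n_vesicles,
        p=[params.p_both, params.p_ch1_only, params.p_ch2_only],
    )
    diam_um = rng_size.normal(
        params.diameter_um_mean, params.diameter_um_sd, params.n_vesicles
    )
    diam_um = np.clip(diam_um, 2 * ps, None)  # keep every vesicle resolvable

    for center, cls, d_um in zip(centers, classes, diam_um):
        r_px = (d_um / 2) / ps
        planted = {"ch1": 0.0, "ch2": 0.0}
        if cls == "both":
            ov = params.within_vesicle_overlap
            p1, shared, p2 = _vesicle_pixel_sets(center, r_px, ov, (h, w))
            n_s, n_p = shared.shape[1], p1.shape[1]
            i_s = params.cargo_intensity
            if ov >= 1 or n_p == 0:
                i_p, n_p = 0.0, 0
            elif ov <= 0 or n_s == 0:
                i_s, n_s = 0.0, 0
                i_p = params.cargo_intensity
            else:
                # private intensity making the shared density fraction exact
                i_p = i_s * n_s * (1 - ov) / (ov * n_p)
            if n_s:
                clean[0][shared[0], shared[1]] += i_s
                clean[1][shared[0], shared[1]] += i_s
            if n_p:
                clean[0][p1[0], p1[1]] += i_p
                clean[1][p2[0], p2[1]] += i_p
            planted["ch1"] = i_s * n_s + i_p * n_p
            planted["ch2"] = i_s * n_s + i_p * n_p
        else:
            _, whole, _ = _vesicle_pixel_sets(center, r_px, 1.0, (h, w))
            ch = 0 if cls == "ch1_only" else 1
            clean[ch][whole[0], whole[1]] += params.cargo_intensity
            planted["ch1" if ch == 0 else "ch2"] = (
                params.cargo_intensity * whole.shape[1]
            )
        truth.vesicles.append(
            {
                "centroid": center.tolist(),
                "diameter_um": float(d_um),
                "cargo_class": str(cls),
                "planted_integrated": planted,
                "planted_overlap": (
                    params.within_vesicle_overlap if cls == "both" else None
                ),
            }
        )

    img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["ch1", "ch2"], ps)
    return img, truth


# --------------------------------------------------------------------------
# apical cell


def generate_apical_cell(
    params: ApicalCellParams, imaging: ImagingParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one apical cell: a contour band (SAR) around an interior (AFR).

    Ground truth records the generating sum-intensity ratio
    ``sar_intensity * band_area / (afr_intensity * interior_area)`` computed
    by exhaustive pixel enumeration of the planted masks; if the interior
    intensity is zero the ratio is flagged undefined instead of reported.
    """
    from skimage.draw import polygon2mask

    ps = imaging.pixel_size_um
    poly = np.asarray(params.contour_polygon, dtype=float)
    margin = 4 * (imaging.psf_sigma_um / ps) + 3
    w = int(np.ceil(poly[:, 0].max() + margin))
    h = int(np.ceil(poly[:, 1].max() + margin))
    if poly.min() < 1:
        raise GeometryError("polygon must lie inside the field of view")

    mask = polygon2mask((h, w), poly[:, ::-1])  # polygon2mask takes (row, col)
    band_px = params.sar_band_width_um / ps
    inner_dist = ndimage.distance_transform_edt(mask)
    band = mask & (inner_dist <= band_px + 1e-6)
    interior = mask & ~band
    if not interior.any():
        raise GeometryError("SAR band wider than the polygon inradius")

    clean = np.full((1, h, w), params.background_intensity, dtype=float)
    clean[0][band] = params.sar_intensity
    clean[0][interior] = params.afr_intensity

    (rng_noise,) = _substreams(imaging.seed, 1)
    img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["apical"], ps)

    truth = GroundTruth(pixel_size_um=ps)
    sar_sum = params.sar_intensity * int(band.sum())
    afr_sum = params.afr_intensity * int(interior.sum())
    if afr_sum == 0:
        truth.sar_afr_undefined = True
    else:
        truth.sar_afr_true_ratio = sar_sum / afr_sum
    truth.extras.update(
        band_area_px=int(band.sum()),
        interior_area_px=int(interior.sum()),
        band_width_px=band_px,
    )
    return img, truth


# --------------------------------------------------------------------------
# nuclei


def generate_nuclei_field(
    params: NucleiFieldParams, imaging: ImagingParams
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render n non-overlapping bright nuclear discs; truth lists centroids."""
    ps = imaging.pixel_size_um
    r_px = (params.nucleus_diameter_um / 2) / ps
    min_sep_px = params.min_separation_um / ps
    margin_px = r_px + 4 * (imaging.psf_sigma_um / ps) + 2
    w, h = _field_size(params.n_nuclei, min_sep_px, margin_px, params.fov_um, ps)

    rng_place, rng_noise = _substreams(imaging.seed, 2)
    clean = np.full((1, h, w), params.background_intensity, dtype=float)
    truth = GroundTruth(pixel_size_um=ps, nuclei=[])

    if params.n_nuclei:
        centers = _place_points(params.n_nuclei, w, h, min_sep_px, margin_px, rng_place)
        yy, xx = np.mgrid[0:h, 0:w]
        for c in centers:
            disc = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_px**2
            clean[0][disc] = params.nucleus_intensity
            truth.nuclei.append(c.tolist())

    img = MultiChannelImage(_acquire(clean, imaging, rng_noise), ["nuclei"], ps)
    return img, truth
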