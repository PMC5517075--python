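"""Vesicle/endosome detection, diameter measurement, cargo classification
and the cargo census.

Detection runs multi-scale Laplacian-of-Gaussian blob detection on the
per-pixel maximum of the requested channels, then segments each blob at
half-maximum above local background for measurement.  Diameter is the
equivalent-circle diameter of the segmented blob, optionally corrected
for PSF broadening by quadrature subtraction — necessary to size objects
near the optical resolution limit (a ~0.3 um recycling endosome imaged
with a ~0.2 um-FWHM-class PSF measures markedly larger than it is).

A cargo is "present" in a vesicle when the vesicle's mean intensity in
that channel exceeds ``presence_factor`` times the channel's background
median; the census tallies both / channel-1-only / channel-2-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import MeasurementError, ParameterError
from .image import MultiChannelImage

__all__ = [
    "VesicleDetection",
    "VesicleCensus",
    "detect_vesicles",
    "equivalent_diameter_um",
    "classify_cargo",
    "census",
    "count_nuclei",
]

PRESENCE_FACTOR_DEFAULT = 2.0


@dataclass
class VesicleDetection:
    centroid: tuple[float, float]  # (x, y), pixels
    diameter_um: float
    mask: np.ndarray  # boolean segmented region (full-frame)
    mean_intensity: dict[str, float] = field(default_factory=dict)
    integrated_intensity: dict[str, float] = field(default_factory=dict)
    cargo_class: str | None = None


@dataclass(frozen=True)
class VesicleCensus:
    n_total: int
    n_both: int
    n_ch1_only: int
    n_ch2_only: int

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"both": float("nan"), "ch1_only": float("nan"), "ch2_only": float("nan")}
        return {
            "both": self.n_both / self.n_total,
            "ch1_only": self.n_ch1_only / self.n_total,
            "ch2_only": self.n_ch2_only / self.n_total,
        }


_LEGGAUSS = np.polynomial.legendre.leggauss(64)


def _blurred_disc_profile(r: float, radius: float, sigma: float) -> float:
    """Radial profile at r of a unit uniform disc convolved with an
    isotropic Gaussian (Rice/Marcum integral, Gauss-Legendre quadrature)."""
    from scipy.special import i0e

    if sigma <= 0:
        return 1.0 if r <= radius else 0.0
    nodes, weights = _LEGGAUSS
    s = 0.5 * radius * (nodes + 1.0)
    w = 0.5 * radius * weights
    integrand = (s / sigma**2) * np.exp(-((s - r) ** 2) / (2 * sigma**2)) * i0e(
        r * s / sigma**2
    )
    return float(np.sum(w * integrand))


def _half_max_radius(radius: float, sigma: float) -> float:
    """Half-max radius of the blurred-disc profile (relative to its peak)."""
    peak = _blurred_disc_profile(0.0, radius, sigma)
    lo, hi = 0.0, radius + 6 * sigma
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if _blurred_disc_profile(mid, radius, sigma) > peak / 2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=32)
def _inversion_table(sigma: float, d_max: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Monotone lookup: true disc diameter -> blurred half-max diameter."""
    d_true = np.linspace(0.02 * sigma, d_max, 256)
    d_meas = np.array([2 * _half_max_radius(d / 2, sigma) for d in d_true])
    return tuple(d_true), tuple(d_meas)


def psf_corrected_diameter_um(d_measured_um: float, psf_sigma_um: float) -> float:
    """Invert PSF broadening of a half-maximum-segmented disc.

    The segmented (half-max) diameter of a uniform disc blurred by a
    Gaussian PSF differs from the true diameter, markedly so near the
    resolution limit.  This solves for the disc diameter whose blurred
    half-max diameter equals the measured one, using a cached monotone
    lookup built from the exact blurred-disc profile.  Measurements at or
    below the PSF's own half-max footprint return the smallest tabulated
    diameter — the floor of what the data can support.
    """
    if psf_sigma_um <= 0:
        return float(d_measured_um)
    # bucket the table's upper end so repeated measurements share one table
    span = 50 * psf_sigma_um
    d_max = span * float(np.ceil((2 * d_measured_um + 8 * psf_sigma_um) / span))
    d_true, d_meas = _inversion_table(round(psf_sigma_um, 6), round(d_max, 3))
    return float(np.interp(d_measured_um, np.asarray(d_meas), np.asarray(d_true)))


def equivalent_diameter_um(
    area_px: int, pixel_size_um: float, psf_sigma_um: float | None = None
) -> float:
    """Equivalent-circle diameter ``2*sqrt(area/pi)`` in micrometres.

    When ``psf_sigma_um`` is given, PSF broadening is removed by inverting
    the blurred-disc half-max model (see :func:`psf_corrected_diameter_um`).
    """
    if area_px <= 0:
        raise MeasurementError("empty segmented region")
    d = 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um
    if psf_sigma_um:
        d = psf_corrected_diameter_um(d, psf_sigma_um)
    return float(d)


def _segment_blob(
    plane: np.ndarray, center_rc: tuple[int, int], radius_px: float, background: float
) -> np.ndarray:
    """Half-maximum segmentation of one blob in a local window.

    Threshold = background + 0.5 * (peak - background); keeps the
    connected component containing the blob center.
    """
    h, w = plane.shape
    r = int(np.ceil(radius_px * 2.5)) + 2
    r0, c0 = center_rc
    y0, y1 = max(r0 - r, 0), min(r0 + r + 1, h)
    x0, x1 = max(c0 - r, 0), min(c0 + r + 1, w)
    win = plane[y0:y1, x0:x1]
    # robust peak: median of the five brightest pixels resists shot-noise
    # inflation of a single maximum
    top = np.sort(win.ravel())[-5:]
    peak = float(np.median(top))
    thr = background + 0.5 * (peak - background)
    lbl, _ = ndimage.label(win > thr)
    lab = lbl[min(r0 - y0, win.shape[0] - 1), min(c0 - x0, win.shape[1] - 1)]
    mask = np.zeros_like(plane, dtype=bool)
    if lab > 0:
        mask[y0:y1, x0:x1] = lbl == lab
    return mask


def detect_vesicles(
    img: MultiChannelImage,
    channels: list[int | str] | None = None,
    min_diameter_um: float = 0.2,
    max_diameter_um: float = 2.0,
    detect_threshold: float = 0.1,
    psf_sigma_um: float | None = None,
) -> list[VesicleDetection]:
    """Detect vesicles by multi-scale LoG blob detection.

    Blobs are found on the per-pixel maximum of the listed channels
    (default: all), filtered to [min_diameter_um, max_diameter_um], and
    each is segmented by local half-maximum thresholding; overlapping
    segmentations are resolved in favor of the brighter blob.  Returns a
    (possibly empty) list with per-channel mean and integrated intensity.
    """
    from skimage.feature import blob_log

    if not 0 < min_diameter_um < max_diameter_um:
        raise ParameterError("need 0 < min_diameter_um < max_diameter_um")
    ps = img.pixel_size_um
    names = img.channel_names if channels is None else [
        c if isinstance(c, str) else img.channel_names[c] for c in channels
    ]
    planes = {n: np.asarray(img.channel(n), dtype=float) for n in names}
    detect_plane = np.max(np.stack(list(planes.values())), axis=0)
    if detect_plane.max() <= detect_plane.min():
        return []

    norm = (detect_plane - detect_plane.min()) / (detect_plane.max() - detect_plane.min())
    # blob_log radius ~ sigma * sqrt(2)
    min_sigma = max((min_diameter_um / 2) / ps / np.sqrt(2), 0.8)
    max_sigma = (max_diameter_um / 2) / ps / np.sqrt(2) * 1.5
    blobs = blob_log(
        norm,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=8,
        threshold=detect_threshold,
        overlap=0.3,
    )

    bg_detect = float(np.median(detect_plane))
    detections: list[VesicleDetection] = []
    claimed = np.zeros_like(detect_plane, dtype=bool)
    # brighter blobs first so they claim contested pixels
    order = np.argsort(
        [-detect_plane[int(b[0]), int(b[1])] for b in blobs]
    ) if len(blobs) else []
    for i in order:
        r, c, sigma = blobs[i]
        mask = _segment_blob(detect_plane, (int(r), int(c)), sigma * np.sqrt(2), bg_detect)
        mask &= ~claimed
        area = int(mask.sum())
        if area == 0:
            continue
        d_um = equivalent_diameter_um(area, ps, psf_sigma_um)
        if not min_diameter_um * 0.5 <= d_um <= max_diameter_um * 1.5:
            continue
        claimed |= mask
        ys, xs = np.nonzero(mask)
        det = VesicleDetection(
            centroid=(float(xs.mean()), float(ys.mean())),
            diameter_um=d_um,
            mask=mask,
        )
        for n, p in planes.items():
            det.mean_intensity[n] = float(p[mask].mean())
            det.integrated_intensity[n] = float(p[mask].sum())
        detections.append(det)
    # stable order: by position
    detections.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    return detections


def classify_cargo(
    detection: VesicleDetection,
    img: MultiChannelImage,
    ch1: int | str,
    ch2: int | str,
    presence_factor: float = PRESENCE_FACTOR_DEFAULT,
) -> str | None:
    """Assign a cargo class from per-channel presence.

    Channel K is present when the vesicle's mean intensity in K exceeds
    ``presence_factor`` times the background median of K (median of the
    whole channel — vesicles are sparse).  Returns 'both', 'ch1_only',
    'ch2_only', or None when neither cargo is present (the detection is
    then discarded from the census).
    """
    present = []
    for ch in (ch1, ch2):
        plane = np.asarray(img.channel(ch), dtype=float)
        bg = float(np.median(plane))
        mean = float(plane[detection.mask].mean())
        present.append(mean > presence_factor * bg if bg > 0 else mean > 0)
    if all(present):
        detection.cargo_class = "both"
    elif present[0]:
        detection.cargo_class = "ch1_only"
    elif present[1]:
        detection.cargo_class = "ch2_only"
    else:
        detection.cargo_class = None
    return detection.cargo_class


def census(detections: list[VesicleDetection]) -> VesicleCensus:
    """Tally cargo classes over classified detections.

    Detections with ``cargo_class`` None (no cargo present) are excluded.
    """
    classes = [d.cargo_class for d in detections if d.cargo_class]
    return VesicleCensus(
        n_total=len(classes),
        n_both=classes.count("both"),
        n_ch1_only=classes.count("ch1_only"),
        n_ch2_only=classes.count("ch2_only"),
    )


def count_nuclei(
    img: MultiChannelImage,
    channel: int | str = 0,
    min_diameter_um: float = 1.5,
) -> int:
    """Count nuclei in a nuclear-stain channel.

    Otsu threshold, then a watershed split of touching discs seeded at
    distance-transform peaks at least one nucleus radius apart.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    plane = np.asarray(img.channel(channel), dtype=float)
    if plane.max() <= plane.min():
        return 0
    mask = plane > threshold_otsu(plane)
    min_area = np.pi * (min_diameter_um / 2 / img.pixel_size_um) ** 2 / 4
    if not mask.any():
        return 0
    dist = ndimage.distance_transform_edt(mask)
    min_dist = max(int((min_diameter_um / 2) / img.pixel_size_um), 1)
    peaks = peak_local_max(dist, min_distance=min_dist, labels=mask, exclude_border=False)
    if len(peaks) == 0:
        return 0
    markers = np.zeros_like(plane, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=mask)
    counts = np.bincount(labels.ravel())
    return int(np.sum(counts[1:] >= min_area))
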