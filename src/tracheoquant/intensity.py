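"""Normalized and subcellular apical intensity ratios.

Two ratio measurements:

* DT/MT ratio — mean fluorescence in a wide band traced along the main
  tube (default width 60 px) divided by the mean in a narrow band along
  the internal reference tubules (default width 10 px).  Normalizing to an
  internal structure cancels embryo-to-embryo staining variation.
* SAR/AFR ratio — summed fluorescence in a band centered on the traced
  cell contour (subapical region) divided by the summed fluorescence
  inside an inner polygon (apical free region).  The two pixel sets must
  be disjoint.

Band membership is binary by pixel center: a pixel belongs to a band when
its center lies within ``width / 2`` of the traced polyline (exact
point-to-segment distance, not a raster approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MeasurementError, ParameterError
from .image import MultiChannelImage, PolygonROI, PolylineROI

__all__ = [
    "NormalizedIntensityResult",
    "SarAfrResult",
    "band_pixels",
    "dt_mt_ratio",
    "sar_afr_ratio",
    "DT_BAND_WIDTH_PX",
    "MT_BAND_WIDTH_PX",
    "SAR_BAND_WIDTH_PX",
]

# default traced-line widths, in pixels
DT_BAND_WIDTH_PX = 60
MT_BAND_WIDTH_PX = 10
SAR_BAND_WIDTH_PX = 3


@dataclass(frozen=True)
class NormalizedIntensityResult:
    dt_mean: float
    mt_mean: float
    ratio: float


@dataclass(frozen=True)
class SarAfrResult:
    sar_sum: float
    afr_sum: float
    ratio: float
    sar_n_px: int
    afr_n_px: int


def _strip_distances(
    px: np.ndarray, py: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Perpendicular distance from pixel centers to segment p0-p1, valid
    only where the foot of the perpendicular falls on the segment
    (``inf`` elsewhere): a wide line has no end caps."""
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        return np.full(px.shape, np.inf)
    t = ((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / len2
    dist = np.hypot(px - (p0[0] + t * d[0]), py - (p0[1] + t * d[1]))
    return np.where((t >= 0.0) & (t <= 1.0), dist, np.inf)


def band_pixels(
    polyline: PolylineROI | np.ndarray,
    width_px: float,
    shape: tuple[int, int],
    closed: bool = False,
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within perpendicular
    distance ``width_px / 2`` of the polyline.

    Each segment contributes a rectangular strip (a wide line selection
    has no end caps); interior joints are rounded with discs so adjoining
    strips meet without wedge gaps.  ``closed=True`` treats the point list
    as a ring (contour band), where every vertex is interior.  Bands
    extending beyond the image are clipped with a warning.
    """
    if width_px < 1:
        raise ParameterError("width_px must be >= 1")
    pts = polyline.points if isinstance(polyline, PolylineROI) else np.asarray(polyline, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
        joints = pts[:-1]
    else:
        joints = pts[1:-1]
    h, w = shape
    half = width_px / 2.0

    # true band extent: strip corners (p +- half * normal) and joint discs
    corners = []
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        norm = np.hypot(*d)
        if norm == 0:
            continue
        n = np.array([-d[1], d[0]]) / norm * half
        corners += [p0 + n, p0 - n, p1 + n, p1 - n]
    for j in joints:
        corners += [j + half, j - half]
    corners = np.array(corners)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    if lo[0] < -0.5 or lo[1] < -0.5 or hi[0] > w - 0.5 or hi[1] > h - 0.5:
        warnings.warn("band extends beyond the image; clipped to bounds")
    x0, x1 = int(max(np.floor(lo[0]), 0)), int(min(np.ceil(hi[0]), w - 1))
    y0, y1 = int(max(np.floor(lo[1]), 0)), int(min(np.ceil(hi[1]), h - 1))
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    xx = xx.astype(float)
    yy = yy.astype(float)
    dmin = np.full(xx.shape, np.inf)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        np.minimum(dmin, _strip_distances(xx, yy, p0, p1), out=dmin)
    for j in joints:
        np.minimum(dmin, np.hypot(xx - j[0], yy - j[1]), out=dmin)
    mask[y0 : y1 + 1, x0 : x1 + 1] = dmin <= half
    return mask


def dt_mt_ratio(
    img: MultiChannelImage,
    channel: int | str,
    dt_roi: PolylineROI,
    mt_roi: PolylineROI,
    dt_width_px: int | None = None,
    mt_width_px: int | None = None,
    background: float = 0.0,
) -> NormalizedIntensityResult:
    """Mean band intensity along the main tube normalized to the mean along
    the internal reference tubules.

    Band widths default to the ROIs' own ``width_px`` (falling back to the
    conventional 60/10 when the ROIs carry width 1).  Means, not sums, so
    the ratio does not depend on traced length.  ``background`` is an
    optional constant offset subtracted from both means.
    """
    plane = np.asarray(img.channel(channel), dtype=float)
    if plane.ndim != 2:
        raise ParameterError("dt_mt_ratio expects a projected 2-D image")
    dt_w = dt_width_px or (dt_roi.width_px if dt_roi.width_px > 1 else DT_BAND_WIDTH_PX)
    mt_w = mt_width_px or (mt_roi.width_px if mt_roi.width_px > 1 else MT_BAND_WIDTH_PX)
    dt_mask = band_pixels(dt_roi, dt_w, plane.shape)
    mt_mask = band_pixels(mt_roi, mt_w, plane.shape)
    if not dt_mask.any() or not mt_mask.any():
        raise MeasurementError("empty measurement band")
    dt_mean = float(plane[dt_mask].mean()) - background
    mt_mean = float(plane[mt_mask].mean()) - background
    if mt_mean <= 0:
        raise MeasurementError("reference (MT) mean is zero; ratio undefined")
    return NormalizedIntensityResult(dt_mean, mt_mean, dt_mean / mt_mean)


def polygon_mask(poly: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center inclusion mask of a polygon."""
    from skimage.draw import polygon2mask

    return polygon2mask(shape, poly.vertices[:, ::-1])


def sar_afr_ratio(
    img: MultiChannelImage,
    channel: int | str,
    contour: PolygonROI,
    inner: PolygonROI,
    band_width_px: int = SAR_BAND_WIDTH_PX,
    background: float = 0.0,
) -> SarAfrResult:
    """Subcellular accumulation ratio: summed intensity in a band centered
    on the traced cell contour (SAR) over the summed intensity inside the
    inner polygon (AFR).

    The inner polygon must lie strictly inside the contour and the two
    pixel sets must be disjoint after banding.
    """
    plane = np.asarray(img.channel(channel), dtype=float)
    if plane.ndim != 2:
        raise ParameterError("sar_afr_ratio expects a projected 2-D image")
    sar_mask = band_pixels(contour.ring(), band_width_px, plane.shape)
    afr_mask = polygon_mask(inner, plane.shape)
    if not afr_mask.any():
        raise MeasurementError("inner polygon contains no pixels")
    if (sar_mask & afr_mask).any():
        raise GeometryError(
            "SAR band and inner (AFR) region overlap; trace the inner polygon "
            "further from the contour or narrow the band"
        )
    sar_sum = float(plane[sar_mask].sum()) - background * int(sar_mask.sum())
    afr_sum = float(plane[afr_mask].sum()) - background * int(afr_mask.sum())
    if afr_sum <= 0:
        raise MeasurementError("AFR sum is zero; ratio undefined")
    return SarAfrResult(
        sar_sum, afr_sum, sar_sum / afr_sum, int(sar_mask.sum()), int(afr_mask.sum())
    )
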