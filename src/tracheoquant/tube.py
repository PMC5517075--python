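"""Tube-length tortuosity and diameter measurements.

The central statistic is the arc-to-chord ratio of a traced tube path:
the real path length divided by the straight endpoint-to-endpoint
distance.  A ratio of 1 means a perfectly straight tube.  Paths may be
traced manually (ROIs) or extracted automatically from a lumen channel by
skeletonization between two anchor landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import ndimage

from .errors import MeasurementError, ParameterError, TracingError
from .image import LandmarkSet, MultiChannelImage, PolylineROI

__all__ = [
    "TubeLengthResult",
    "DiameterResult",
    "arc_length",
    "dt_ratio",
    "trace_centerline",
    "measure_diameter",
]


@dataclass(frozen=True)
class TubeLengthResult:
    arc_length_um: float
    chord_length_um: float
    ratio: float


@dataclass(frozen=True)
class DiameterResult:
    diameter_um: float
    position: tuple[float, float]


def arc_length(path: PolylineROI, pixel_size_um: float) -> float:
    """Sum of Euclidean segment lengths along the polyline, in micrometres."""
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be > 0")
    return path.arc_length_px() * pixel_size_um


def dt_ratio(path: PolylineROI, pixel_size_um: float) -> TubeLengthResult:
    """Arc-to-chord ratio of a traced tube path.

    The chord is the straight segment between the first and last point of
    the path (the two anchor landmarks of the tracing); the arc is the
    traced path length.  Always >= 1 up to floating-point rounding.
    """
    chord_px = float(np.hypot(*(path.points[-1] - path.points[0])))
    if chord_px == 0:
        raise MeasurementError("degenerate path: coincident endpoints")
    arc_um = arc_length(path, pixel_size_um)
    chord_um = chord_px * pixel_size_um
    return TubeLengthResult(arc_um, chord_um, arc_um / chord_um)


# --------------------------------------------------------------------------
# automatic tracing


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton, edges weighted by step length."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    nodes = set(zip(rows.tolist(), cols.tolist()))
    for r, c in nodes:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in nodes:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _smooth_path(points: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-smooth the coordinate sequences of a pixel chain.

    Removes the staircase inflation of arc length that raw 8-connected
    skeleton chains carry; endpoints are preserved.
    """
    if len(points) < 5:
        return points
    sm = np.column_stack(
        [
            ndimage.gaussian_filter1d(points[:, 0], sigma, mode="nearest"),
            ndimage.gaussian_filter1d(points[:, 1], sigma, mode="nearest"),
        ]
    )
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def trace_centerline(
    lumen: MultiChannelImage,
    channel: int | str,
    anchors: LandmarkSet,
    smooth_sigma: float = 2.0,
) -> PolylineROI:
    """Extract the tube centerline between two anchor landmarks.

    Pipeline: Otsu threshold -> binary closing -> skeletonize -> shortest
    path along the skeleton between the skeleton pixels nearest each
    anchor.  The returned polyline starts and ends at the anchors
    themselves (the tracing runs between the landmarks), with the skeleton
    chain smoothed to suppress pixel-grid staircase artifacts.
    """
    from skimage.filters import threshold_otsu
    from skimage.morphology import closing, disk, skeletonize

    if len(anchors.points) != 2:
        raise ParameterError("exactly two anchor landmarks are required")
    plane = np.asarray(lumen.channel(channel), dtype=float)
    if plane.ndim != 2:
        raise ParameterError("trace_centerline expects a projected 2-D image")
    if plane.max() <= plane.min():
        raise TracingError("blank image: no tube to trace")
    mask = plane > threshold_otsu(plane)
    if not mask.any():
        raise TracingError("empty mask after thresholding")
    mask = closing(mask, disk(2))
    skel = skeletonize(mask)
    if not skel.any():
        raise TracingError("skeletonization produced an empty skeleton")

    rows, cols = np.nonzero(skel)
    skel_pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    ends = []
    for p in anchors.points:
        d = np.hypot(skel_pts[:, 0] - p[0], skel_pts[:, 1] - p[1])
        i = int(np.argmin(d))
        ends.append((int(rows[i]), int(cols[i])))

    graph = _skeleton_graph(skel)
    try:
        chain = nx.shortest_path(graph, ends[0], ends[1], weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise TracingError("anchors are not connected on the skeleton") from exc

    path = np.array([(c, r) for r, c in chain], dtype=float)
    path = _smooth_path(path, smooth_sigma)
    pts = np.vstack([anchors.points[0], path, anchors.points[1]])
    # drop duplicated consecutive points (anchor may coincide with chain end)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return PolylineROI(pts[keep], name="traced-centerline")


def measure_diameter(
    lumen: MultiChannelImage,
    channel: int | str,
    at: tuple[float, float],
    axis_dir_deg: float = 0.0,
    threshold: float | None = None,
) -> DiameterResult:
    """Tube diameter at a point: length of the above-threshold intensity run
    along the perpendicular to the tube axis through that point.

    ``threshold`` defaults to Otsu of the channel.
    """
    from skimage.filters import threshold_otsu

    plane = np.asarray(lumen.channel(channel), dtype=float)
    if threshold is None:
        threshold = float(threshold_otsu(plane))
    h, w = plane.shape
    x0, y0 = at
    ix, iy = int(round(x0)), int(round(y0))
    if not (0 <= ix < w and 0 <= iy < h) or plane[iy, ix] <= threshold:
        raise MeasurementError(f"point {at} is not inside the tube mask")

    theta = np.deg2rad(axis_dir_deg + 90.0)  # perpendicular direction
    ux, uy = np.cos(theta), np.sin(theta)
    max_t = float(np.hypot(h, w))
    ts = np.arange(-max_t, max_t, 0.5)
    xs, ys = x0 + ts * ux, y0 + ts * uy
    ok = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    ts, xs, ys = ts[ok], xs[ok], ys[ok]
    vals = ndimage.map_coordinates(plane, [ys, xs], order=1)
    above = vals > threshold
    # the contiguous above-threshold run containing t = 0
    i0 = int(np.argmin(np.abs(ts)))
    if not above[i0]:
        raise MeasurementError(f"point {at} is not inside the tube mask")
    lo = i0
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(ts) - 1 and above[hi + 1]:
        hi += 1
    diameter_px = ts[hi] - ts[lo] + 0.5
    return DiameterResult(float(diameter_px) * lumen.pixel_size_um, (x0, y0))
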