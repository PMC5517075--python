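"""Image and ROI containers, TIFF/JSON I/O, and z-projection.

Conventions
-----------
Coordinates are 0-based pixel-center coordinates with ``x`` = column and
``y`` = row (y increases downward).  All physical quantities are derived
from ``pixel_size_um`` (micrometres per pixel).

Pixel arrays are stored as ``[channel, y, x]`` or, for z-stacks,
``[z, channel, y, x]``.  TIFF files written here carry channel names and
pixel size in a JSON description tag so a write→read round trip preserves
both pixels and metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import FormatError, ParameterError

ROI_SCHEMA_VERSION = 1

__all__ = [
    "MultiChannelImage",
    "PolylineROI",
    "PolygonROI",
    "LandmarkSet",
    "max_project",
    "read_image",
    "write_image",
    "read_rois",
    "write_rois",
]


@dataclass
class MultiChannelImage:
    """A multi-channel (optionally z-stacked) grayscale image.

    Parameters
    ----------
    pixels
        Array of shape ``(channel, y, x)`` or ``(z, channel, y, x)`` with
        non-negative intensities.
    channel_names
        One unique name per channel.
    pixel_size_um
        Lateral pixel size in micrometres per pixel (> 0).
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (3, 4):
            raise ParameterError(
                f"pixels must be (c, y, x) or (z, c, y, x); got shape {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise ParameterError("intensities must be non-negative")
        n_ch = self.pixels.shape[-3]
        if len(self.channel_names) != n_ch:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError("channel names must be unique")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[-3]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a 2-D (or 3-D if z-stacked) array."""
        if isinstance(which, str):
            try:
                which = self.channel_names.index(which)
            except ValueError:
                raise ParameterError(
                    f"unknown channel {which!r}; have {self.channel_names}"
                ) from None
        if not 0 <= which < self.n_channels:
            raise ParameterError(f"channel index {which} out of range")
        return self.pixels[..., which, :, :]


def max_project(img: MultiChannelImage) -> MultiChannelImage:
    """Per-channel pixelwise maximum-intensity projection over z.

    Mirrors the standard confocal workflow of flattening a z-stack before
    2-D measurement.  An image without a z dimension is returned unchanged
    with a warning; projecting twice is therefore a no-op (idempotence).
    """
    if not img.has_z:
        warnings.warn("image has no z dimension; max_project is a no-op")
        return img
    return MultiChannelImage(
        pixels=img.pixels.max(axis=0),
        channel_names=list(img.channel_names),
        pixel_size_um=img.pixel_size_um,
    )


# --------------------------------------------------------------------------
# ROIs


def _as_points(points: Sequence[Sequence[float]]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) sequence of (x, y)")
    return pts


@dataclass
class PolylineROI:
    """An open traced path (e.g. a freehand line selection).

    ``width_px`` is the band width used when the polyline stands for a wide
    line selection (1 = pure path).
    """

    points: np.ndarray
    name: str = ""
    width_px: int = 1

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ParameterError("polyline needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ParameterError("consecutive polyline points must be distinct")
        if int(self.width_px) < 1:
            raise ParameterError("width_px must be a positive integer")
        self.width_px = int(self.width_px)

    def arc_length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


@dataclass
class PolygonROI:
    """A closed simple polygon (e.g. a traced cell contour).

    ``vertices`` is the open ring: the closing edge from last to first
    vertex is implicit.
    """

    vertices: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices)
        # drop an explicitly repeated closing vertex
        if len(self.vertices) > 1 and np.all(self.vertices[0] == self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ParameterError("polygon needs at least 3 vertices")
        if _self_intersects(self.vertices):
            raise ParameterError(f"polygon {self.name!r} is self-intersecting")

    def ring(self) -> np.ndarray:
        """Closed ring: vertices with the first point appended."""
        return np.vstack([self.vertices, self.vertices[:1]])


@dataclass
class LandmarkSet:
    """Named anchor points in pixel coordinates."""

    points: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if not self.names:
            self.names = [f"p{i}" for i in range(len(self.points))]
        if len(self.names) != len(self.points):
            raise ParameterError("one name per landmark required")


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper intersection test for two segments (shared endpoints allowed)."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(q1, q2, p1)
    d2 = cross(q1, q2, p2)
    d3 = cross(p1, p2, q1)
    d4 = cross(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _self_intersects(vertices: np.ndarray) -> bool:
    ring = np.vstack([vertices, vertices[:1]])
    n = len(vertices)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closing edge
            if _segments_intersect(ring[i], ring[i + 1], ring[j], ring[j + 1]):
                return True
    return False


# --------------------------------------------------------------------------
# TIFF I/O


def write_image(path: str | Path, img: MultiChannelImage) -> None:
    """Write a multi-channel image as a TIFF with JSON metadata.

    Channels (and z planes) are stored as separate pages; the description
    tag records axis order, channel names and pixel size.
    """
    meta = {
        "axes": "ZCYX" if img.has_z else "CYX",
        "channel_names": list(img.channel_names),
        "pixel_size_um": img.pixel_size_um,
    }
    kwargs = {"photometric": "minisblack"}
    if img.n_channels > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(str(path), img.pixels, description=json.dumps(meta), **kwargs)


def read_image(
    path: str | Path, default_pixel_size_um: float = 0.1
) -> MultiChannelImage:
    """Read a TIFF written by :func:`write_image` (or a plain grayscale TIFF).

    A plain TIFF without our metadata tag is accepted: a 2-D file becomes a
    single unnamed channel and the configured default pixel size is used
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            pixels = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        warnings.warn(
            f"{path.name}: no pixel-size metadata; using default "
            f"{default_pixel_size_um} um/px"
        )
        pixel_size = default_pixel_size_um

    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        pixels = pixels[None]
    axes = meta.get("axes")
    if axes == "ZCYX" and pixels.ndim == 3:
        # single z plane collapsed by tifffile
        pixels = pixels[None]
    names = meta.get("channel_names") or [f"ch{i}" for i in range(pixels.shape[-3])]
    return MultiChannelImage(pixels, list(names), float(pixel_size))


# --------------------------------------------------------------------------
# ROI JSON I/O (versioned schema; stands in for manual tracings)


def _roi_to_record(roi) -> dict:
    if isinstance(roi, PolylineROI):
        return {
            "type": "polyline",
            "name": roi.name,
            "width_px": roi.width_px,
            "points": roi.points.tolist(),
        }
    if isinstance(roi, PolygonROI):
        return {"type": "polygon", "name": roi.name, "points": roi.vertices.tolist()}
    if isinstance(roi, LandmarkSet):
        return {"type": "landmarks", "names": roi.names, "points": roi.points.tolist()}
    raise ParameterError(f"cannot serialize {type(roi).__name__}")


def write_rois(path: str | Path, rois: Sequence) -> None:
    doc = {
        "schema_version": ROI_SCHEMA_VERSION,
        "rois": [_roi_to_record(r) for r in rois],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_rois(path: str | Path) -> list:
    """Read a versioned ROI JSON file into typed ROI objects.

    Unknown record fields are preserved on the returned objects as an
    ``extra`` attribute; schema violations name the offending record.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read ROI file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "rois" not in doc:
        raise FormatError(f"{path}: not an ROI document (missing 'rois')")
    out = []
    known = {"type", "name", "names", "width_px", "points"}
    for i, rec in enumerate(doc["rois"]):
        where = f"{path.name} record {i}"
        if not isinstance(rec, dict) or "type" not in rec:
            raise FormatError(f"{where}: missing 'type'")
        try:
            kind = rec["type"]
            if kind == "polyline":
                roi = PolylineROI(
                    rec["points"], rec.get("name", ""), rec.get("width_px", 1)
                )
            elif kind == "polygon":
                roi = PolygonROI(rec["points"], rec.get("name", ""))
            elif kind == "landmarks":
                roi = LandmarkSet(rec["points"], list(rec.get("names", [])))
            else:
                raise FormatError(f"{where}: unknown ROI type {kind!r}")
            extra = {k: v for k, v in rec.items() if k not in known}
            if extra:
                roi.extra = extra  # type: ignore[attr-defined]
        except (KeyError, ParameterError) as exc:
            raise FormatError(f"{where}: {exc}") from exc
        out.append(roi)
    return out
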