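"""Junction orientation classification and length morphometrics.

Cell junction segments are classified by the angle of their endpoint
chord relative to the tube axis (set to 0 deg), folded into [0, 90]
because orientation is undirected: axial junctions lie within 30 deg of
the axis, circumferential junctions within 30 deg of the perpendicular,
and segments in between are left unclassified and excluded from the
two-class comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasurementError, ParameterError
from .image import PolylineROI
from .phantoms import fold_angle_deg
from .stats import GroupComparison, students_t

AXIAL_MAX_DEG = 30.0
CIRCUMFERENTIAL_MIN_DEG = 60.0

__all__ = [
    "JunctionSegment",
    "segment_angle",
    "classify_junction",
    "junction_length",
    "summarize_junctions",
]


@dataclass
class JunctionSegment:
    polyline: PolylineROI
    angle_deg: float
    length_um: float
    class_label: str
    group: str = ""


def segment_angle(
    polyline: PolylineROI, tube_axis_deg: float = 0.0, fit: str = "chord"
) -> float:
    """Orientation of a junction segment relative to the tube axis, in
    [0, 90] degrees.

    By default the orientation is that of the endpoint-to-endpoint chord
    (the overall direction of a freehand-traced junction); ``fit="tls"``
    instead uses the total-least-squares direction through all points.
    """
    pts = polyline.points
    if fit == "chord":
        d = pts[-1] - pts[0]
        if d[0] == 0 and d[1] == 0:
            raise MeasurementError("degenerate junction: coincident endpoints")
        raw = np.degrees(np.arctan2(d[1], d[0]))
    elif fit == "tls":
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        raw = np.degrees(np.arctan2(vt[0, 1], vt[0, 0]))
    else:
        raise ParameterError(f"unknown fit mode {fit!r}")
    return fold_angle_deg(raw, tube_axis_deg)


def classify_junction(angle_deg: float) -> str:
    """Assign axial / circumferential / unclassified from a folded angle.

    The named bands are closed: 30 deg is axial and 60 deg is
    circumferential; the open interval (30, 60) is unclassified.
    """
    if not 0.0 <= angle_deg <= 90.0:
        raise ParameterError(f"angle {angle_deg} outside [0, 90]")
    if angle_deg <= AXIAL_MAX_DEG:
        return "axial"
    if angle_deg >= CIRCUMFERENTIAL_MIN_DEG:
        return "circumferential"
    return "unclassified"


def junction_length(polyline: PolylineROI, pixel_size_um: float) -> float:
    """Polyline arc length in micrometres."""
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be > 0")
    return polyline.arc_length_px() * pixel_size_um


def make_segment(
    polyline: PolylineROI,
    pixel_size_um: float,
    tube_axis_deg: float = 0.0,
    group: str = "",
) -> JunctionSegment:
    """Measure and classify one junction polyline."""
    angle = segment_angle(polyline, tube_axis_deg)
    return JunctionSegment(
        polyline=polyline,
        angle_deg=angle,
        length_um=junction_length(polyline, pixel_size_um),
        class_label=classify_junction(angle),
        group=group,
    )


def summarize_junctions(
    segments: list[JunctionSegment],
) -> tuple[pd.DataFrame, dict[str, GroupComparison]]:
    """Per-class, per-group length summaries and between-group t-tests.

    Returns a tidy summary table (group, class, n, mean length, s.e.) and,
    when exactly two groups are present, a Student's t comparison per
    class.  Unclassified segments are summarized but never compared.
    """
    if not segments:
        return pd.DataFrame(
            columns=["group", "class", "n", "mean_length_um", "se_length_um"]
        ), {}
    df = pd.DataFrame(
        {
            "group": [s.group for s in segments],
            "class": [s.class_label for s in segments],
            "angle_deg": [s.angle_deg for s in segments],
            "length_um": [s.length_um for s in segments],
        }
    )
    rows = []
    for (group, cls), sub in df.groupby(["group", "class"], sort=True):
        n = len(sub)
        rows.append(
            {
                "group": group,
                "class": cls,
                "n": n,
                "mean_length_um": sub["length_um"].mean(),
                "se_length_um": (
                    sub["length_um"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                ),
            }
        )
    summary = pd.DataFrame(rows)

    comparisons: dict[str, GroupComparison] = {}
    groups = sorted(df["group"].unique())
    if len(groups) == 2:
        for cls in ("axial", "circumferential"):
            a = df[(df["group"] == groups[0]) & (df["class"] == cls)]["length_um"]
            b = df[(df["group"] == groups[1]) & (df["class"] == cls)]["length_um"]
            if len(a) >= 2 and len(b) >= 2:
                comparisons[cls] = students_t(
                    a.to_numpy(), b.to_numpy(), labels=(groups[0], groups[1])
                )
    return summary, comparisons
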