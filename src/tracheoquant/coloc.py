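"""Thresholded-ratio pixel colocalization (Manders-style fractions).

A pixel counts as colocalized when both channels exceed their per-channel
thresholds and the intensity ratio between them is at least a cutoff
(default 0.5).  The ratio is taken symmetrically as min/max so the
criterion does not depend on channel order; a directional red/green mode
is available behind a flag.  From the binary mask, the colocalized-signal
fraction of a channel is its integrated density over the mask divided by
its integrated density over all of its above-threshold pixels (a
pixel-count variant is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .image import MultiChannelImage, PolygonROI
from .intensity import polygon_mask

__all__ = ["ColocParams", "ColocResult", "coloc_mask", "coloc_fractions", "per_object_coloc"]


@dataclass(frozen=True)
class ColocParams:
    """Thresholds and ratio cutoff for the colocalization mask.

    ``threshold_ch1/2 = None`` means Otsu per channel.  ``directional=True``
    uses the literal ch1/ch2 ratio instead of the symmetric min/max form.
    """

    threshold_ch1: float | None = None
    threshold_ch2: float | None = None
    ratio_cutoff: float = 0.5
    directional: bool = False

    def __post_init__(self) -> None:
        for t in (self.threshold_ch1, self.threshold_ch2):
            if t is not None and t < 0:
                raise ParameterError("thresholds must be >= 0")
        if not 0 < self.ratio_cutoff <= 1:
            raise ParameterError("ratio_cutoff must be in (0, 1]")


@dataclass
class ColocResult:
    fraction_ch1: float
    fraction_ch2: float
    fraction_ch1_px: float
    fraction_ch2_px: float
    n_coloc_pixels: int
    per_object: list[dict] = field(default_factory=list)


def _planes(
    img: MultiChannelImage | np.ndarray, ch1, ch2
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(img, MultiChannelImage):
        a = np.asarray(img.channel(ch1), dtype=float)
        b = np.asarray(img.channel(ch2), dtype=float)
    else:
        a = np.asarray(ch1, dtype=float)
        b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"channel shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _thresholds(a: np.ndarray, b: np.ndarray, params: ColocParams) -> tuple[float, float]:
    from skimage.filters import threshold_otsu

    t1 = params.threshold_ch1
    t2 = params.threshold_ch2
    if t1 is None:
        t1 = float(threshold_otsu(a)) if a.max() > a.min() else float(a.max())
    if t2 is None:
        t2 = float(threshold_otsu(b)) if b.max() > b.min() else float(b.max())
    return t1, t2


def coloc_mask(
    img: MultiChannelImage | np.ndarray,
    ch1: int | str | np.ndarray,
    ch2: int | str | np.ndarray,
    params: ColocParams = ColocParams(),
) -> np.ndarray:
    """Binary colocalization mask.

    A pixel is colocalized iff ``i1 > t1`` and ``i2 > t2`` and
    ``min(i1, i2) / max(i1, i2) >= ratio_cutoff`` (or ``i1 / i2`` in
    directional mode).  Accepts either a MultiChannelImage plus channel
    selectors or two bare arrays.
    """
    a, b = _planes(img, ch1, ch2)
    t1, t2 = _thresholds(a, b, params)
    above = (a > t1) & (b > t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.directional:
            ratio = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.inf)
        else:
            hi = np.maximum(a, b)
            ratio = np.where(hi > 0, np.minimum(a, b) / np.where(hi > 0, hi, 1.0), 0.0)
    return above & (ratio >= params.ratio_cutoff)


def coloc_fractions(
    img: MultiChannelImage | np.ndarray,
    ch1: int | str | np.ndarray,
    ch2: int | str | np.ndarray,
    mask: np.ndarray | None = None,
    params: ColocParams = ColocParams(),
    restrict: np.ndarray | None = None,
) -> ColocResult:
    """Colocalized-signal fraction per channel.

    fraction_chK = (integrated density of channel K over the mask) /
    (integrated density of channel K over its above-threshold pixels);
    ``fraction_chK_px`` is the pixel-count variant.  ``restrict`` limits
    the computation to a region (used for per-object fractions).  A channel
    with no above-threshold signal gets fraction NaN.
    """
    a, b = _planes(img, ch1, ch2)
    t1, t2 = _thresholds(a, b, params)
    if mask is None:
        mask = coloc_mask(img, ch1, ch2, params)
    if mask.shape != a.shape:
        raise ParameterError("mask shape does not match channels")
    region = np.ones_like(mask) if restrict is None else restrict.astype(bool)

    out = []
    for plane, t in ((a, t1), (b, t2)):
        above = (plane > t) & region
        m = mask & region
        dens_above = float(plane[above].sum())
        dens_coloc = float(plane[m].sum())
        frac = dens_coloc / dens_above if dens_above > 0 else float("nan")
        frac_px = int(m.sum()) / int(above.sum()) if above.sum() > 0 else float("nan")
        out.append((frac, frac_px))
    return ColocResult(
        fraction_ch1=out[0][0],
        fraction_ch2=out[1][0],
        fraction_ch1_px=out[0][1],
        fraction_ch2_px=out[1][1],
        n_coloc_pixels=int((mask & region).sum()),
    )


def per_object_coloc(
    img: MultiChannelImage | np.ndarray,
    ch1: int | str | np.ndarray,
    ch2: int | str | np.ndarray,
    objects: list,
    params: ColocParams = ColocParams(),
    mask: np.ndarray | None = None,
) -> ColocResult:
    """Colocalized fractions restricted to each object's pixel set.

    ``objects`` may be PolygonROIs, boolean masks, or ``(center, radius_px)``
    disc tuples (the typical way a selected vesicle is circled).  Each
    object gets per-channel fractions and their mean; objects with no
    above-threshold pixels in either channel are flagged and excluded from
    the across-object summary, which is the mean over valid objects.
    """
    a, b = _planes(img, ch1, ch2)
    if mask is None:
        mask = coloc_mask(img, ch1, ch2, params)

    per_object: list[dict] = []
    for i, obj in enumerate(objects):
        if isinstance(obj, PolygonROI):
            region = polygon_mask(obj, a.shape)
        elif isinstance(obj, np.ndarray) and obj.dtype == bool:
            region = obj
        else:
            center, radius = obj
            yy, xx = np.mgrid[0 : a.shape[0], 0 : a.shape[1]]
            region = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
        res = coloc_fractions(img, ch1, ch2, mask=mask, params=params, restrict=region)
        fr = [f for f in (res.fraction_ch1, res.fraction_ch2) if np.isfinite(f)]
        per_object.append(
            {
                "object": i,
                "fraction_ch1": res.fraction_ch1,
                "fraction_ch2": res.fraction_ch2,
                "mean_fraction": float(np.mean(fr)) if fr else float("nan"),
                "n_coloc_pixels": res.n_coloc_pixels,
                "excluded": not fr,
            }
        )

    valid = [o["mean_fraction"] for o in per_object if not o["excluded"]]
    summary = coloc_fractions(img, ch1, ch2, mask=mask, params=params)
    summary.per_object = per_object
    summary.mean_object_fraction = (  # type: ignore[attr-defined]
        float(np.mean(valid)) if valid else float("nan")
    )
    return summary
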