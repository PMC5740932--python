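"""Per-pot growth traits in metric units.

All traits are computed from a refined pot mask plus the image scale:
projected leaf area (mm²), perimeter (mm), convex-hull area/length/width
(mm² / mm), stockiness and compactness (%), hull-region greenness (0-255)
and the per-day relative growth rate between consecutive images.

Stockiness is the circularity score 100 * (4π·Area) / (2π·R)² with R half
the convex hull's longest axis — exactly 100% for a circular rosette and
smaller the more serrated or elongated the plant.  Compactness is the
percentage of the hull filled by leaf pixels.  The daily relative growth
rate between areas A1 (earlier) and A2 (later) captured Δt days apart is

    RGR = (ln A2 - ln A1) / ln A1 / Δt

which is undefined when A1 = 1 mm² (ln A1 = 0) and recorded as absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology

from .calibrate import CalibratedImage, ImageScale
from .errors import InvalidInputError
from .pots import PotMask
from .segment import compute_greenness_img


@dataclass(frozen=True)
class GrowthPair:
    """Projected areas of one pot in two consecutive images, Δt days apart."""

    area1_mm2: float
    area2_mm2: float
    dt_days: float

    def __post_init__(self):
        if self.dt_days <= 0:
            raise InvalidInputError("dt_days must be positive")
        if self.area1_mm2 <= 0 or self.area2_mm2 <= 0:
            raise InvalidInputError("areas must be positive")


@dataclass
class TraitRecord:
    """One pot's trait vector at one timepoint (one CSV row)."""

    image_name: str
    capture_time: datetime | None
    pot_index: int
    px_per_mm: float
    area_mm2: float = 0.0
    perimeter_mm: float = 0.0
    hull_area_mm2: float = 0.0
    hull_length_mm: float = 0.0
    hull_width_mm: float = 0.0
    stockiness_pct: float = 0.0
    compactness_pct: float = 0.0
    leaf_count: int | None = 0
    large_leaf_count: int | None = 0
    greenness: float = 0.0
    daily_rgr: float | None = None


def projected_leaf_area(pot: PotMask, scale: ImageScale) -> float:
    """Foreground pixel count converted to mm²; 0 for an empty mask."""
    return scale.px2_to_mm2(float(pot.count))


def leaf_perimeter(pot: PotMask, scale: ImageScale) -> float:
    """Total leaf-contour length over all components, in mm.

    Uses the weighted boundary-configuration estimator, which is additive
    over disjoint components and accurate to a few percent on rasterised
    shapes; 0 for an empty mask.
    """
    if pot.count == 0:
        return 0.0
    per_px = measure.perimeter(pot.mask)
    return scale.px_to_mm(float(per_px))


def daily_rgr(g: GrowthPair) -> float | None:
    """Per-day relative growth rate, or None when undefined (area1 = 1 mm²)."""
    ln1 = math.log(g.area1_mm2)
    if ln1 == 0.0:
        return None
    return (math.log(g.area2_mm2) - ln1) / ln1 / g.dt_days


def convex_hull_metrics(
    pot: PotMask, scale: ImageScale
) -> tuple[float, float, float, np.ndarray]:
    """Convex hull of the leaf pixels: (area mm², length mm, width mm, hull mask).

    Hull length is the maximum distance between hull vertices (Feret
    diameter); hull width is the extent perpendicular to that axis.  Both
    are rotation-invariant.  An empty mask yields zeros and an empty hull
    (harvested pots are legal inputs).
    """
    empty = np.zeros(pot.mask.shape, dtype=bool)
    if pot.count == 0:
        return 0.0, 0.0, 0.0, empty

    hull_mask = morphology.convex_hull_image(pot.mask)
    hull_area = scale.px2_to_mm2(float(hull_mask.sum()))

    ys, xs = np.nonzero(pot.mask)
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        verts = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear or single-pixel foreground
        verts = pts

    # Feret diameter over hull vertices; O(v²) is fine, v is small.
    diff = verts[:, None, :] - verts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length_px = math.sqrt(d2[i, j])

    if length_px > 0:
        axis = (verts[j] - verts[i]) / length_px
        normal = np.array([-axis[1], axis[0]])
        proj = verts @ normal
        width_px = float(proj.max() - proj.min())
    else:
        width_px = 0.0

    return (
        hull_area,
        scale.px_to_mm(length_px),
        scale.px_to_mm(min(width_px, length_px)),
        hull_mask,
    )


def stockiness(area_mm2: float, hull_length_mm: float) -> float:
    """Circularity score 100·(4π·A)/(2π·R)² with R = hull_length / 2, capped at 100."""
    if hull_length_mm <= 0:
        return 0.0
    r = hull_length_mm / 2.0
    return min(100.0, 100.0 * (4.0 * math.pi * area_mm2) / (2.0 * math.pi * r) ** 2)


def compactness(area_mm2: float, hull_area_mm2: float) -> float:
    """Percentage of the convex hull filled by leaf pixels; 0 for an empty hull."""
    if hull_area_mm2 <= 0:
        return 0.0
    if area_mm2 > hull_area_mm2:
        raise InvalidInputError("projected area cannot exceed hull area")
    return 100.0 * area_mm2 / hull_area_mm2


def greenness_mean(img: CalibratedImage | np.ndarray, hull_mask: np.ndarray) -> float:
    """Mean clipped greenness G_V over the hull region; 0 for an empty hull."""
    if hull_mask.sum() == 0:
        return 0.0
    gv = compute_greenness_img(img).values
    if gv.shape != hull_mask.shape:
        raise InvalidInputError("hull mask does not match image dimensions")
    return float(gv[hull_mask].mean())


def measure_pot(
    pot: PotMask,
    img: CalibratedImage,
    image_name: str = "",
    capture_time: datetime | None = None,
) -> TraitRecord:
    """All shape and colour traits for one pot (leaf counts filled in later)."""
    scale = img.scale
    x0, y0, x1, y1 = pot.region.bbox
    sub = img.pixels[y0:y1, x0:x1]

    area = projected_leaf_area(pot, scale)
    perim = leaf_perimeter(pot, scale)
    hull_area, hull_len, hull_wid, hull_mask = convex_hull_metrics(pot, scale)
    return TraitRecord(
        image_name=image_name,
        capture_time=capture_time,
        pot_index=pot.region.index,
        px_per_mm=scale.px_per_mm,
        area_mm2=area,
        perimeter_mm=perim,
        hull_area_mm2=hull_area,
        hull_length_mm=hull_len,
        hull_width_mm=hull_wid,
        stockiness_pct=stockiness(area, hull_len),
        compactness_pct=compactness(area, hull_area),
        greenness=greenness_mean(sub, hull_mask),
    )
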