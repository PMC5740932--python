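"""Pot-level partitioning and mask refinement.

The tray ROI is tiled into a rows x cols lattice of pot cells (row-major,
left-to-right then top-to-bottom, 1-based indices).  The global leaf mask
is split along the lattice and each pot's sub-mask is refined with local
rules — minimum component size, pot-level greenness contrast, and leaf
position — to strip algae speckle and soil false positives while leaving
genuinely harvested (empty) pots empty rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .calibrate import CalibratedImage, ImageScale
from .errors import InvalidInputError
from .segment import LeafMask, compute_greenness_img

#: Components whose centroid falls outside the central fraction of the pot
#: are kept only if they sit close to the main plant (a leaf reaching over).
_CENTRAL_FRACTION = 0.90
_NEIGHBOUR_DIST_FRACTION = 0.20


@dataclass(frozen=True)
class TrayLayout:
    """Grid dimensions of the tray: ``rows`` x ``cols`` pots."""

    rows: int
    cols: int

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("tray layout needs rows >= 1 and cols >= 1")

    @property
    def n_pots(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class PotRegion:
    """One pot's cell in the tray lattice.

    ``bbox`` is the half-open pixel rectangle (x0, y0, x1, y1) in ROI
    coordinates; ``index`` is 1-based row-major.
    """

    index: int
    row: int
    col: int
    bbox: tuple[int, int, int, int]

    @property
    def width(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[1]


@dataclass(frozen=True)
class PotMask:
    """Binary leaf mask cropped to one pot's bounding box."""

    region: PotRegion
    mask: np.ndarray

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def build_pot_layout(roi_shape: tuple[int, int], layout: TrayLayout) -> list[PotRegion]:
    """Tile an ROI of shape (H, W) into ``layout.rows * layout.cols`` cells.

    Cell boundaries sit at ``round(j * W / cols)`` and ``round(i * H / rows)``
    so the regions are pairwise disjoint and cover the ROI exactly.
    """
    h, w = roi_shape[:2]
    if h < layout.rows or w < layout.cols:
        raise InvalidInputError("ROI smaller than the pot lattice")
    xs = [round(j * w / layout.cols) for j in range(layout.cols + 1)]
    ys = [round(i * h / layout.rows) for i in range(layout.rows + 1)]
    regions = []
    for r in range(1, layout.rows + 1):
        for c in range(1, layout.cols + 1):
            regions.append(
                PotRegion(
                    index=(r - 1) * layout.cols + c,
                    row=r,
                    col=c,
                    bbox=(xs[c - 1], ys[r - 1], xs[c], ys[r]),
                )
            )
    return regions


def split_into_pots(mask: LeafMask, regions: list[PotRegion]) -> list[PotMask]:
    """Crop the global mask to each pot cell.

    Leaves crossing a pot border are clipped at the border, so total
    foreground pixel count is conserved across the split.
    """
    h, w = mask.mask.shape
    for reg in regions:
        if reg.bbox[2] > w or reg.bbox[3] > h:
            raise InvalidInputError("pot regions do not fit the mask dimensions")
    return [
        PotMask(region=reg, mask=mask.mask[reg.bbox[1]:reg.bbox[3], reg.bbox[0]:reg.bbox[2]].copy())
        for reg in regions
    ]


def refine_pot_mask(
    pot: PotMask,
    img: CalibratedImage,
    min_area_px: int | None = None,
) -> PotMask:
    """Locally filter one pot's mask.

    Rules, applied in one pass (idempotent, never adds pixels):

    1. components smaller than ``min_area_px`` (default ~1 mm² via the
       image scale) are dropped — kills algae speckle;
    2. components whose mean greenness falls below the pot-level Otsu
       level of G_V are dropped — kills bright soil/grit;
    3. of the survivors, a component is kept if its centroid lies in the
       central 90% of the pot, or if it sits within 20% of the pot width
       of the largest surviving component (a leaf reaching over a border).

    An all-removed mask is a valid empty pot (harvested), not an error.
    """
    if pot.count == 0:
        return pot
    if min_area_px is None:
        min_area_px = max(1, round(img.scale.px_per_mm**2))

    x0, y0, x1, y1 = pot.region.bbox
    gv = compute_greenness_img(img.pixels[y0:y1, x0:x1]).values

    gv_level = None
    if np.ptp(gv) > 0:
        gv_level = threshold_otsu(gv)

    labels, n = ndimage.label(pot.mask)
    if n == 0:
        return pot
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    mean_gv = ndimage.mean(gv, labels, idx)
    centroids = np.array(ndimage.center_of_mass(pot.mask, labels, idx))  # (row, col)

    keep = areas >= min_area_px
    if gv_level is not None:
        keep &= mean_gv >= gv_level
    if not keep.any():
        return PotMask(region=pot.region, mask=np.zeros_like(pot.mask))

    h, w = pot.mask.shape
    margin_y = (1 - _CENTRAL_FRACTION) / 2 * h
    margin_x = (1 - _CENTRAL_FRACTION) / 2 * w
    central = (
        (centroids[:, 0] >= margin_y)
        & (centroids[:, 0] <= h - margin_y)
        & (centroids[:, 1] >= margin_x)
        & (centroids[:, 1] <= w - margin_x)
    )
    largest = idx[keep][np.argmax(areas[keep])] - 1
    near_largest = (
        np.linalg.norm(centroids - centroids[largest], axis=1)
        < _NEIGHBOUR_DIST_FRACTION * w
    )
    keep &= central | near_largest

    out = np.isin(labels, idx[keep])
    return PotMask(region=pot.region, mask=out)
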