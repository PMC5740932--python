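"""Image pre-processing and calibration.

Raw top-view tray photographs are rescaled to a fixed working height,
the four red circular fiducial stickers glued to the tray corners are
detected, their mean pixel radius is converted to a pixel-per-millimetre
scale, and the quadrilateral they span is warped to an axis-aligned
region of interest (ROI).  Every downstream measurement (areas in mm²,
lengths in mm) is expressed through the scale derived here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .errors import (
    DegenerateGeometryError,
    InvalidInputError,
    MarkerDetectionError,
)

#: Working-image height (px) used for all pixel-space computation.
WORKING_HEIGHT = 1024

# Morphological gates for genuine circular stickers.  Components must be
# nearly convex and round, and of comparable size to the median candidate.
_MIN_SOLIDITY = 0.9
_MAX_ECCENTRICITY = 0.6
_AREA_BAND = (0.25, 4.0)
_MIN_CANDIDATE_AREA_PX = 9  # specks below this are never plausible stickers


@dataclass(frozen=True)
class RawImage:
    """An RGB image as loaded from disk, channels in 0-255."""

    pixels: np.ndarray
    source_name: str = ""
    capture_time: datetime | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] == 0 or p.shape[1] == 0:
            raise InvalidInputError(
                f"expected a non-empty H x W x 3 image, got shape {p.shape}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class MarkerSet:
    """Four retained circular markers: centres and radii in pixels."""

    markers: tuple[tuple[float, float, float], ...]  # (cx, cy, radius_px)
    mean_radius_px: float = field(init=False)

    def __post_init__(self):
        if len(self.markers) != 4:
            raise MarkerDetectionError(len(self.markers))
        radii = [m[2] for m in self.markers]
        if min(radii) <= 0:
            raise DegenerateGeometryError("marker with non-positive radius")
        object.__setattr__(self, "mean_radius_px", float(np.mean(radii)))

    @property
    def centres(self) -> np.ndarray:
        """4x2 array of (x, y) centres."""
        return np.array([(m[0], m[1]) for m in self.markers], dtype=float)


@dataclass(frozen=True)
class ImageScale:
    """Pixel-to-millimetre conversion derived from the fiducial markers."""

    px_per_mm: float
    marker_radius_mm: float

    def __post_init__(self):
        if self.px_per_mm <= 0 or self.marker_radius_mm <= 0:
            raise DegenerateGeometryError("scale factors must be positive")

    def px_to_mm(self, length_px: float) -> float:
        return length_px / self.px_per_mm

    def px2_to_mm2(self, area_px: float) -> float:
        return area_px / self.px_per_mm**2


@dataclass(frozen=True)
class CalibratedImage:
    """Tray ROI with an attached metric scale."""

    pixels: np.ndarray
    scale: ImageScale
    source_name: str = ""
    capture_time: datetime | None = None

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def rescale_to_height(img: RawImage, target_height: int = WORKING_HEIGHT) -> RawImage:
    """Resize ``img`` so its height is ``target_height``, preserving aspect ratio.

    The input object is never modified; if the image already has the target
    height it is returned as-is.
    """
    if target_height <= 0:
        raise InvalidInputError("target_height must be positive")
    h, w = img.height, img.width
    if h == target_height:
        return img
    new_w = round(w * target_height / h)
    resized = transform.resize(
        img.pixels, (target_height, new_w), order=1, anti_aliasing=(target_height < h),
        preserve_range=True,
    )
    return replace(img, pixels=np.clip(np.rint(resized), 0, 255).astype(np.uint8))


def marker_threshold(pixel) -> int:
    """Classify one (r, g, b) triple as red-sticker (1) or not (0).

    A pixel belongs to the reference mask iff r > 125, b < 225 and
    r - g > 50 — a single-colour extraction tuned for strongly red objects
    under variable illumination.
    """
    r, g, b = (int(c) for c in pixel)
    return int(r > 125 and b < 225 and (r - g) > 50)


def marker_mask(pixels: np.ndarray) -> np.ndarray:
    """Vectorised red-sticker threshold over a whole H x W x 3 image."""
    p = pixels.astype(np.int16)
    r, g, b = p[..., 0], p[..., 1], p[..., 2]
    return (r > 125) & (b < 225) & ((r - g) > 50)


def detect_reference_markers(img: RawImage) -> MarkerSet:
    """Find the four red circular corner stickers on a working image.

    Connected components of the red-threshold mask are screened by
    solidity, eccentricity and area (relative to the median candidate) to
    reject red non-circular objects such as labels or cables.  If more
    than four round candidates survive, the four closest to the image
    corners are kept.

    Raises
    ------
    MarkerDetectionError
        If fewer than four candidates survive the screen.
    """
    mask = marker_mask(img.pixels)
    labels, _ = ndimage.label(mask)
    props = [p for p in measure.regionprops(labels) if p.area >= _MIN_CANDIDATE_AREA_PX]
    if not props:
        raise MarkerDetectionError(0)

    median_area = float(np.median([p.area for p in props]))
    lo, hi = _AREA_BAND[0] * median_area, _AREA_BAND[1] * median_area
    keep = [
        p
        for p in props
        if p.solidity >= _MIN_SOLIDITY
        and p.eccentricity <= _MAX_ECCENTRICITY
        and lo <= p.area <= hi
    ]
    if len(keep) < 4:
        raise MarkerDetectionError(len(keep))

    if len(keep) > 4:
        h, w = img.height, img.width
        corners = np.array([(0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)], float)
        chosen: list = []
        pool = list(keep)
        for corner in corners:
            dists = [
                math.hypot(p.centroid[1] - corner[0], p.centroid[0] - corner[1])
                for p in pool
            ]
            best = int(np.argmin(dists))
            chosen.append(pool.pop(best))
        keep = chosen

    markers = tuple(
        (float(p.centroid[1]), float(p.centroid[0]), float(p.equivalent_diameter_area / 2))
        for p in keep
    )
    return MarkerSet(markers=markers)


def compute_scale(markers: MarkerSet, marker_radius_mm: float = 4.0) -> ImageScale:
    """Convert the mean marker pixel radius to a px/mm scale.

    The stickers have a known physical radius (4 mm by default; 5 mm for
    the wheat setup), so ``px_per_mm = mean_radius_px / marker_radius_mm``.
    """
    if marker_radius_mm <= 0:
        raise DegenerateGeometryError("marker_radius_mm must be positive")
    if markers.mean_radius_px <= 0:
        raise DegenerateGeometryError("zero mean marker radius")
    return ImageScale(
        px_per_mm=markers.mean_radius_px / marker_radius_mm,
        marker_radius_mm=marker_radius_mm,
    )


def _order_corners(centres: np.ndarray) -> np.ndarray:
    """Order 4 points as top-left, top-right, bottom-right, bottom-left.

    Points are sorted by angle about their centroid (orientation-stable),
    then the cycle is rotated so the corner nearest the top-left extreme
    comes first.
    """
    c = centres.mean(axis=0)
    ang = np.arctan2(centres[:, 1] - c[1], centres[:, 0] - c[0])
    order = np.argsort(ang)  # counter-clockwise in math coords = clockwise on screen
    pts = centres[order]
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def extract_tray_roi(
    img: RawImage, markers: MarkerSet, scale: ImageScale
) -> CalibratedImage:
    """Warp the quadrilateral spanned by the marker centres to a rectangle.

    The output rectangle's width is the mean of the top and bottom edge
    lengths and its height the mean of the left and right edge lengths,
    which minimises anisotropic distortion for nearly-rectangular trays.

    Raises
    ------
    DegenerateGeometryError
        If the marker centres are collinear or duplicated.
    """
    tl, tr, br, bl = _order_corners(markers.centres)
    # shoelace area of the quad; ~0 means collinear/duplicate centres
    quad = np.array([tl, tr, br, bl])
    x, y = quad[:, 0], quad[:, 1]
    area2 = abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 < 4.0:
        raise DegenerateGeometryError("marker centres are collinear or duplicated")

    out_w = int(round((np.linalg.norm(tr - tl) + np.linalg.norm(br - bl)) / 2))
    out_h = int(round((np.linalg.norm(bl - tl) + np.linalg.norm(br - tr)) / 2))
    out_w, out_h = max(out_w, 1), max(out_h, 1)

    # corner centres map to the cell grid edges, so an axis-aligned marker
    # rectangle becomes an exact pixel crop (identity homography)
    dst = np.array([(0, 0), (out_w, 0), (out_w, out_h), (0, out_h)], float)
    tform = transform.ProjectiveTransform.from_estimate(dst, quad)
    if not tform:
        raise DegenerateGeometryError("could not estimate perspective transform")
    roi = transform.warp(
        img.pixels, tform, output_shape=(out_h, out_w), order=1, preserve_range=True
    )
    return CalibratedImage(
        pixels=np.clip(np.rint(roi), 0, 255).astype(np.uint8),
        scale=scale,
        source_name=img.source_name,
        capture_time=img.capture_time,
    )


def denoise(img: CalibratedImage) -> CalibratedImage:
    """Smooth the ROI with a 3x3 per-channel median filter.

    Median filtering knocks down salt-and-pepper speckle from soil grit
    and sensor noise while preserving leaf edges; dimensions and scale
    are unchanged and a uniform image passes through untouched.
    """
    out = np.empty_like(img.pixels)
    for c in range(3):
        out[..., c] = ndimage.median_filter(img.pixels[..., c], size=3)
    return replace(img, pixels=out)


def calibrate_image(
    img: RawImage,
    marker_radius_mm: float = 4.0,
    target_height: int = WORKING_HEIGHT,
) -> CalibratedImage:
    """Full calibration chain: rescale, detect markers, scale, ROI, denoise."""
    work = rescale_to_height(img, target_height)
    markers = detect_reference_markers(work)
    scale = compute_scale(markers, marker_radius_mm)
    roi = extract_tray_roi(work, markers, scale)
    return denoise(roi)
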