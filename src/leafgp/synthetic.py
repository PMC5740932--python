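"""Synthetic top-view tray images with exact ground truth.

Renders the kind of scene the pipeline is built for: a soil-textured
tray photographed from above at the working resolution, four red
circular fiducial stickers at the corners, and one green rosette per pot
drawn as an n-petalled rose curve (petal count = leaf count, known
exactly).  Optional nuisance features mirror real experiments: algae
speckle on the soil and harvested (empty) pots.

Because every pixel is placed by the generator, it returns exact ground
truth — per-pot leaf masks, leaf counts, marker geometry and the true
px/mm scale — which the test-suite uses as an oracle for calibration,
segmentation and trait recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, polygon

from .errors import InvalidInputError

#: Mean soil and leaf colours (R, G, B).  Soil is a warm brown with zero
#: clipped greenness; leaves are a mid green with G_V well above soil.
SOIL_RGB = (120, 85, 60)
LEAF_RGB = (45, 140, 55)
MARKER_RGB = (220, 40, 35)
ALGAE_RGB = (80, 150, 70)


@dataclass(frozen=True)
class SyntheticTrayParams:
    """Scene description for one rendered tray image.

    Defaults emulate the study setup: a 4 x 6 pot tray photographed at
    the 1024-px working height with 4 mm red stickers that span 40 px
    (i.e. a true scale of 5 px/mm).
    """

    rows: int = 4
    cols: int = 6
    height: int = 1024
    width: int = 1365
    marker_radius_px: float = 20.0
    marker_radius_mm: float = 4.0
    marker_margin_px: int = 34
    #: per-pot petal (leaf) counts, row-major; None draws 2-12 at random
    leaf_counts: tuple[int, ...] | None = None
    #: rosette outer radius as a fraction of the smaller pot dimension
    rosette_radius_fraction: float = 0.30
    #: pots rendered empty regardless of leaf_counts (1-based indices)
    harvested: tuple[int, ...] = ()
    n_algae_speckles: int = 0
    noise_sigma: float = 4.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("rows and cols must be >= 1")
        if self.marker_radius_px <= 0:
            raise InvalidInputError("marker_radius_px must be positive")
        if self.leaf_counts is not None:
            if len(self.leaf_counts) != self.rows * self.cols:
                raise InvalidInputError("need one leaf count per pot")
            if any(c < 0 for c in self.leaf_counts):
                raise InvalidInputError("leaf counts must be >= 0")


@dataclass
class TrayGroundTruth:
    """Exact scene knowledge returned alongside a rendered image."""

    leaf_mask: np.ndarray  # full-image bool mask of all leaf pixels
    roi_bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) marker-centre rectangle
    marker_centres: np.ndarray  # 4 x 2 (x, y)
    marker_radius_px: float
    px_per_mm: float
    rows: int = 1
    cols: int = 1
    pot_leaf_counts: dict[int, int] = field(default_factory=dict)

    def roi_leaf_mask(self) -> np.ndarray:
        x0, y0, x1, y1 = self.roi_bbox
        return self.leaf_mask[y0:y1, x0:x1]


def disc_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    """Filled disc as a boolean mask; ``centre`` is (x, y)."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = disk((centre[1], centre[0]), radius, shape=shape)
    mask[rr, cc] = True
    return mask


def rose_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    r_outer: float,
    n_petals: int,
    petal_depth: float = 0.45,
    phase: float = 0.0,
    samples: int = 1440,
) -> np.ndarray:
    """Filled rose curve r(θ) = r_outer·(1 - depth + depth·cos(n(θ - φ))).

    ``n_petals`` lobes of maximum radius ``r_outer``; depth close to 0.5
    gives deeply separated petals.  With ``n_petals == 0`` the shape is a
    plain disc (a round seedling).
    """
    if n_petals == 0:
        return disc_mask(shape, centre, r_outer)
    theta = np.linspace(0.0, 2.0 * np.pi, samples, endpoint=False)
    r = r_outer * (1.0 - petal_depth + petal_depth * np.cos(n_petals * (theta - phase)))
    xs = centre[0] + r * np.cos(theta)
    ys = centre[1] + r * np.sin(theta)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = polygon(ys, xs, shape=shape)
    mask[rr, cc] = True
    return mask


def _soil_background(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float64)
    # low-frequency mottling plus per-pixel grain
    yy = np.linspace(0, 2 * np.pi, h)[:, None]
    xx = np.linspace(0, 2 * np.pi, w)[None, :]
    mottle = 6.0 * np.sin(3 * yy + rng.uniform(0, 6)) * np.cos(2 * xx + rng.uniform(0, 6))
    for c, base in enumerate(SOIL_RGB):
        img[..., c] = base + mottle + rng.normal(0.0, sigma, size=(h, w))
    return img


def _paint(img: np.ndarray, mask: np.ndarray, colour, rng, jitter: float = 6.0):
    n = int(mask.sum())
    for c, base in enumerate(colour):
        img[..., c][mask] = base + rng.normal(0.0, jitter, size=n)


def generate_synthetic_tray(
    params: SyntheticTrayParams = SyntheticTrayParams(), seed: int = 0
) -> tuple[np.ndarray, TrayGroundTruth]:
    """Render one tray image and its exact ground truth.

    Deterministic for a given ``(params, seed)`` pair.  Returns a
    ``(H, W, 3) uint8`` image and a :class:`TrayGroundTruth`.
    """
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    img = _soil_background((h, w), rng, params.noise_sigma)

    m = params.marker_margin_px
    centres = np.array(
        [(m, m), (w - 1 - m, m), (w - 1 - m, h - 1 - m), (m, h - 1 - m)], dtype=float
    )
    for cx, cy in centres:
        _paint(img, disc_mask((h, w), (cx, cy), params.marker_radius_px), MARKER_RGB, rng, 4.0)

    x0, y0 = int(centres[0][0]), int(centres[0][1])
    x1, y1 = int(centres[2][0]), int(centres[2][1])
    roi_w, roi_h = x1 - x0, y1 - y0

    n_pots = params.rows * params.cols
    counts = params.leaf_counts
    if counts is None:
        counts = tuple(int(c) for c in rng.integers(2, 13, size=n_pots))
    counts = tuple(
        0 if (i + 1) in params.harvested else c for i, c in enumerate(counts)
    )

    leaf_mask = np.zeros((h, w), dtype=bool)
    pot_counts: dict[int, int] = {}
    pot_w, pot_h = roi_w / params.cols, roi_h / params.rows
    for r in range(params.rows):
        for c in range(params.cols):
            idx = r * params.cols + c + 1
            n = counts[idx - 1]
            pot_counts[idx] = n
            if n == 0:
                continue
            cx = x0 + (c + 0.5) * pot_w + rng.uniform(-0.03, 0.03) * pot_w
            cy = y0 + (r + 0.5) * pot_h + rng.uniform(-0.03, 0.03) * pot_h
            r_out = params.rosette_radius_fraction * min(pot_w, pot_h)
            phase = rng.uniform(0, 2 * np.pi)
            rosette = rose_mask((h, w), (cx, cy), r_out, n, phase=phase)
            leaf_mask |= rosette

    _paint(img, leaf_mask, LEAF_RGB, rng)

    for _ in range(params.n_algae_speckles):
        sx = rng.uniform(x0 + 10, x1 - 10)
        sy = rng.uniform(y0 + 10, y1 - 10)
        speck = disc_mask((h, w), (sx, sy), rng.uniform(1.0, 1.8)) & ~leaf_mask
        _paint(img, speck, ALGAE_RGB, rng, 4.0)

    truth = TrayGroundTruth(
        leaf_mask=leaf_mask,
        roi_bbox=(x0, y0, x1, y1),
        marker_centres=centres,
        marker_radius_px=params.marker_radius_px,
        px_per_mm=params.marker_radius_px / params.marker_radius_mm,
        rows=params.rows,
        cols=params.cols,
        pot_leaf_counts=pot_counts,
    )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth


def write_synthetic_series(
    out_dir,
    params: SyntheticTrayParams,
    n_images: int = 3,
    seed: int = 0,
    exp_ref: str = "ExpA",
    tray_no: str = "T01",
    start_date: str = "2017-03-01",
    fmt: str = "png",
) -> list:
    """Write an ``n_images``-long growth series to disk with parseable names.

    Rosette size grows linearly across the series (the same pot keeps the
    same leaf count).  Files are named ``<ExpRef>_<TrayNo>_<YYYY-MM-DD>.<ext>``
    one day apart.  Returns the written paths.
    """
    import datetime as _dt
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    day0 = _dt.date.fromisoformat(start_date)
    rng = np.random.default_rng(seed)
    n_pots = params.rows * params.cols
    counts = params.leaf_counts or tuple(int(c) for c in rng.integers(2, 13, size=n_pots))

    paths = []
    for i in range(n_images):
        frac = 0.6 + 0.4 * i / max(1, n_images - 1)
        p_i = SyntheticTrayParams(
            rows=params.rows,
            cols=params.cols,
            height=params.height,
            width=params.width,
            marker_radius_px=params.marker_radius_px,
            marker_radius_mm=params.marker_radius_mm,
            marker_margin_px=params.marker_margin_px,
            leaf_counts=counts,
            rosette_radius_fraction=params.rosette_radius_fraction * frac,
            harvested=params.harvested,
            n_algae_speckles=params.n_algae_speckles,
            noise_sigma=params.noise_sigma,
        )
        img, _ = generate_synthetic_tray(p_i, seed=seed + i)
        name = f"{exp_ref}_{tray_no}_{day0 + _dt.timedelta(days=i)}.{fmt}"
        path = out / name
        iio.imwrite(path, img)
        paths.append(path)
    return paths
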