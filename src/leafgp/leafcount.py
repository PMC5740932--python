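"""Leaf-number estimation for rosette plants.

Two independent detectors are combined:

* **skeleton end points** — the pot mask is thinned to a 1-px skeleton
  and end points (leaf tips) are located with four hit-or-miss kernels
  (a foreground pixel with background above/below/left/right and on both
  laterals).  The skeleton is also read as a weighted graph (centroid and
  tips as vertices) whose edge weights — geodesic tip length and the leaf
  area behind each tip — classify "large" leaves (> 15 mm long or
  > 100 mm² by default);
* **outline sweeping** — the squared Euclidean distance from the plant
  centroid to its contour is sampled at each of 360 degrees, Gaussian-
  smoothed, and its circular peaks counted; each peak is one leaf tip.

The skeleton route misses small central leaves and the sweep merges
overlapping tips, so the final count takes the larger of the two.  Counts
are meaningful for rosette species only; wheat canopies are too
overlapped, and the pipeline leaves the count columns empty for wheat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import binary_hit_or_miss
from scipy.signal import find_peaks
from scipy.sparse.csgraph import dijkstra

from .calibrate import ImageScale
from .errors import InvalidInputError
from .pots import PotMask

#: Default thresholds above which a skeleton edge counts as a large/long leaf.
LARGE_LEAF_LENGTH_MM = 15.0
LARGE_LEAF_AREA_MM2 = 100.0

#: Outline-sweeping defaults: smoothing width (degrees), peak prominence as a
#: fraction of the smoothed series' range, and the flat-series guard.
SWEEP_SIGMA_DEG = 3.0
PEAK_PROMINENCE_FRACTION = 0.05
FLAT_RANGE_FRACTION = 0.02

#: Skeleton branches shorter than this (geodesic px to the nearest junction)
#: are rasterisation spurs, not leaves; nearby tips are merged within this
#: radius as well.
SPUR_PRUNE_PX = 3.0

# Hit-or-miss templates for skeleton end points: the centre foreground pixel
# has background on both laterals and across the whole far side; the row/col
# the line continues into is "don't care".  Four orientations.
_ONES = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=np.uint8)


def _zeros_template(direction: str) -> np.ndarray:
    z = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
    if direction == "up":  # line continues downward
        z[2, :] = 0
    elif direction == "down":
        z[0, :] = 0
    elif direction == "left":  # line continues rightward
        z[:, 2] = 0
    elif direction == "right":
        z[:, 0] = 0
    return z


_ZERO_TEMPLATES = [_zeros_template(d) for d in ("up", "down", "left", "right")]


@dataclass(frozen=True)
class SkeletonGraph:
    """Weighted star graph of a pot's skeleton.

    One edge per end point, weighted by the geodesic skeleton length from
    the plant centroid to the tip (mm) and by the area of the mask
    component behind the tip shared across its tips (mm²).
    """

    centroid: tuple[float, float]  # (x, y) px
    endpoints: tuple[tuple[int, int], ...]  # (x, y) px
    edges: tuple[tuple[tuple[int, int], float, float], ...]  # (tip, length_mm, area_mm2)


@dataclass(frozen=True)
class DistanceSeries:
    """Squared centroid-to-contour distance per degree, raw and smoothed."""

    values: np.ndarray  # length 360, px²
    smoothed: np.ndarray
    sigma: float = SWEEP_SIGMA_DEG

    def __post_init__(self):
        if len(self.values) != 360 or len(self.smoothed) != 360:
            raise InvalidInputError("distance series must have 360 samples")


@dataclass(frozen=True)
class LeafCountResult:
    skeleton_tips: int
    sweep_peaks: int
    combined: int
    large_leaves: int


def skeletonize_mask(pot: PotMask | np.ndarray) -> np.ndarray:
    """1-px-wide medial skeleton of a binary mask (empty in, empty out)."""
    from skimage.morphology import skeletonize

    mask = pot.mask if isinstance(pot, PotMask) else np.asarray(pot, dtype=bool)
    return skeletonize(mask)


def find_end_points(skeleton: np.ndarray) -> list[tuple[int, int]]:
    """Coordinates (x, y) of skeleton end points via four hit-or-miss kernels."""
    skel = np.asarray(skeleton, dtype=bool)
    hits = np.zeros_like(skel)
    for zeros in _ZERO_TEMPLATES:
        hits |= binary_hit_or_miss(skel, structure1=_ONES, structure2=zeros)
    ys, xs = np.nonzero(hits)
    return sorted(zip(xs.tolist(), ys.tolist()))


def _skeleton_adjacency(coords: np.ndarray):
    """Sparse 8-neighbour graph over skeleton pixels, diagonal cost sqrt(2)."""
    from scipy.sparse import coo_matrix

    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    rows, cols, w = [], [], []
    for i, (y, x) in enumerate(map(tuple, coords)):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    w.append(np.hypot(dy, dx))
    n = len(coords)
    return coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()


def build_skeleton_graph(
    pot: PotMask, scale: ImageScale, prune_px: float = SPUR_PRUNE_PX
) -> SkeletonGraph:
    """Skeletonise a pot mask and weight each centroid-to-tip edge.

    Thinning a rasterised mask sprouts spurious 1-2 px side branches;
    end points closer than ``prune_px`` (geodesic) to a skeleton junction
    are discarded, and surviving tips within ``prune_px`` of each other
    collapse to one.  Edge length is the geodesic path length along the
    skeleton from the skeleton pixel nearest the mask centroid to the
    tip, in mm; the leaf area weight is the area of the connected mask
    component holding the tip divided by that component's tip count, in mm².
    """
    mask = pot.mask
    if mask.sum() == 0:
        return SkeletonGraph(centroid=(0.0, 0.0), endpoints=(), edges=())
    cy, cx = ndimage.center_of_mass(mask)
    skel = skeletonize_mask(mask)
    endpoints = find_end_points(skel)
    if not endpoints:
        return SkeletonGraph(centroid=(float(cx), float(cy)), endpoints=(), edges=())

    coords = np.column_stack(np.nonzero(skel))  # (y, x)
    graph = _skeleton_adjacency(coords)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}

    # prune tips on spur branches: geodesic distance to nearest junction
    nb = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3)), mode="constant")
    junctions = [
        index[(y, x)] for y, x in map(tuple, coords) if nb[y, x] - 1 >= 3
    ]
    if junctions and prune_px > 0:
        d_junc = dijkstra(graph, directed=False, indices=junctions).min(axis=0)
        endpoints = [
            (x, y) for x, y in endpoints if d_junc[index[(y, x)]] >= prune_px
        ]
    # merge tips that are geodesic neighbours (thick line ends)
    if len(endpoints) > 1 and prune_px > 0:
        ep_idx = [index[(y, x)] for x, y in endpoints]
        d_ep = dijkstra(graph, directed=False, indices=ep_idx)[:, ep_idx]
        merged: list[tuple[int, int]] = []
        taken = np.zeros(len(endpoints), dtype=bool)
        for i, ep in enumerate(endpoints):
            if taken[i]:
                continue
            close = np.flatnonzero(d_ep[i] < prune_px)
            taken[close] = True
            merged.append(ep)
        endpoints = merged
    if not endpoints:
        return SkeletonGraph(centroid=(float(cx), float(cy)), endpoints=(), edges=())

    comp_labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    comp_areas = np.bincount(comp_labels.ravel())
    tips_per_comp = np.bincount(
        [comp_labels[y, x] for x, y in endpoints], minlength=len(comp_areas)
    )

    # geodesic distances from the skeleton pixel nearest the centroid,
    # computed per skeleton component (sources: nearest pixel in each)
    d_to_centroid = np.hypot(coords[:, 0] - cy, coords[:, 1] - cx)
    skel_comp, n_skel_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    sources = []
    comp_of_coord = skel_comp[coords[:, 0], coords[:, 1]]
    for c in range(1, n_skel_comp + 1):
        members = np.flatnonzero(comp_of_coord == c)
        sources.append(members[np.argmin(d_to_centroid[members])])
    dist = dijkstra(graph, directed=False, indices=sources).min(axis=0)

    edges = []
    for x, y in endpoints:
        length_mm = scale.px_to_mm(float(dist[index[(y, x)]]))
        comp = comp_labels[y, x]
        area_mm2 = scale.px2_to_mm2(comp_areas[comp] / max(1, tips_per_comp[comp]))
        edges.append(((x, y), length_mm, area_mm2))
    return SkeletonGraph(
        centroid=(float(cx), float(cy)),
        endpoints=tuple(endpoints),
        edges=tuple(edges),
    )


def classify_large_leaves(
    graph: SkeletonGraph,
    length_thresh_mm: float = LARGE_LEAF_LENGTH_MM,
    area_thresh_mm2: float = LARGE_LEAF_AREA_MM2,
) -> int:
    """Count edges longer than ``length_thresh_mm`` or heavier than ``area_thresh_mm2``."""
    return sum(
        1
        for _, length_mm, area_mm2 in graph.edges
        if length_mm > length_thresh_mm or area_mm2 > area_thresh_mm2
    )


def outline_distance_series(
    pot: PotMask | np.ndarray, sigma: float = SWEEP_SIGMA_DEG
) -> DistanceSeries:
    """Squared centroid-to-contour distance per degree (0-359), smoothed.

    For each 1° bin the series takes the maximum squared distance among
    boundary pixels whose polar angle about the mask centroid falls in
    that bin (robust to concavities); empty bins are interpolated
    circularly, then the series is smoothed with a wrap-around Gaussian.
    """
    mask = pot.mask if isinstance(pot, PotMask) else np.asarray(pot, dtype=bool)
    if mask.sum() == 0:
        raise InvalidInputError("distance series of an empty mask is undefined")
    cy, cx = ndimage.center_of_mass(mask)

    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    ys, xs = np.nonzero(boundary)
    ang = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    d2 = (ys - cy) ** 2 + (xs - cx) ** 2

    bins = np.minimum(ang.astype(int), 359)
    values = np.full(360, -1.0)
    np.maximum.at(values, bins, d2)

    missing = values < 0
    if missing.any():
        filled = np.flatnonzero(~missing)
        # circular linear interpolation over empty bins
        values = np.interp(
            np.arange(360), filled, values[filled], period=360
        )

    smoothed = ndimage.gaussian_filter1d(values, sigma=sigma, mode="wrap")
    return DistanceSeries(values=values, smoothed=smoothed, sigma=sigma)


def detect_leaf_tip_peaks(
    series: DistanceSeries,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> int:
    """Count circular local maxima of the smoothed series.

    Peaks must clear a prominence floor of ``prominence_fraction`` of the
    smoothed range.  A flat series (a round seedling) counts as a single
    leaf object.

    Contour pixels carry ~±1 px quantisation, which on a squared distance
    d² perturbs samples by up to ~2·d·Δ ≈ 2·sqrt(mean); both the flatness
    guard and the prominence floor include that term so raster wobble on
    a near-circular outline cannot masquerade as leaf tips.
    """
    s = series.smoothed
    rng = float(s.max() - s.min())
    mean = float(max(s.mean(), 1e-9))
    quant = 2.0 * np.sqrt(mean)
    if rng < max(FLAT_RANGE_FRACTION * mean, 2.0 * quant):
        return 1
    floor = max(prominence_fraction * rng, quant)
    tiled = np.concatenate([s, s, s])
    peaks, _ = find_peaks(tiled, prominence=floor)
    return int(np.sum((peaks >= 360) & (peaks < 720)))


def combined_leaf_count(skeleton_tips: int, sweep_peaks: int) -> int:
    """Combine the two detectors: each under-counts, so take the maximum."""
    if skeleton_tips < 0 or sweep_peaks < 0:
        raise InvalidInputError("counts must be non-negative")
    return max(skeleton_tips, sweep_peaks)


def count_leaves(pot: PotMask, scale: ImageScale) -> LeafCountResult:
    """Full leaf-number pipeline for one pot (zero counts for empty pots)."""
    if pot.count == 0:
        return LeafCountResult(0, 0, 0, 0)
    graph = build_skeleton_graph(pot, scale)
    tips = len(graph.endpoints)
    series = outline_distance_series(pot)
    peaks = detect_leaf_tip_peaks(series)
    return LeafCountResult(
        skeleton_tips=tips,
        sweep_peaks=peaks,
        combined=combined_leaf_count(tips, peaks),
        large_leaves=classify_large_leaves(graph),
    )
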