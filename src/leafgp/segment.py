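"""Image-level leaf segmentation.

Two complementary detectors are fused to produce the global leaf mask:

* a vegetative-greenness route — the RGB image is collapsed to the
  greenness index G_V = ExG - ExR (ExG = 2g - r - b, ExR = 1.4r - b),
  k-means-clustered, and thresholded with Otsu's method.  Robust for
  medium-sized rosettes and detects harvested (emptied) pots because
  their colour population differs from soil and leaves;
* a Lab colour-opponent route — Otsu thresholding on the green side of
  the a* (green-red) channel, which picks up tiny leaves the clustering
  route misses.

The union of the two masks, cleaned of sub-millimetre specks, is the
image-level leaf region passed on to pot-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, morphology
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .calibrate import CalibratedImage
from .errors import InvalidInputError

#: Greenish pixels have a* well below zero; this guard keeps Otsu from
#: splitting a green-free image (e.g. bare soil) into a spurious "leaf" half.
_LAB_GREEN_CEILING = -5.0
_LAB_MIN_RANGE = 1.0

#: Pixel budget for k-means fitting; full images are predicted, not fitted.
KMEANS_SUBSAMPLE = 50_000


@dataclass(frozen=True)
class ClusteringConfig:
    """Colour-group estimation settings.

    ``probe_k`` colour groups are fitted on the series' midpoint sample
    image; the number of groups at least as populous as the median group
    becomes ``k``, clamped to [``k_min``, ``k_max``].
    """

    k_min: int = 3
    k_max: int = 10
    probe_k: int = 8
    seed: int = 42


@dataclass(frozen=True)
class GreennessImage:
    """Per-pixel vegetative greenness G_V, clipped to [0, 255]."""

    values: np.ndarray
    clip_range: tuple[float, float] = (0.0, 255.0)


@dataclass(frozen=True)
class LeafMask:
    """Binary leaf-pixel mask aligned to a calibrated image or pot crop."""

    mask: np.ndarray
    origin: str = "global"  # "global" or "pot"

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def compute_greenness_img(img: CalibratedImage | np.ndarray) -> GreennessImage:
    """Map an RGB image to the vegetative greenness index G_V.

    G_V = ExG - ExR with ExG = 2g - r - b (excess green) and
    ExR = 1.4r - b (excess red); the raw value is clipped to [0, 255] so
    that greenness reads on the usual 8-bit intensity range.
    """
    pixels = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    p = pixels.astype(np.float64)
    r, g, b = p[..., 0], p[..., 1], p[..., 2]
    exg = 2.0 * g - r - b
    exr = 1.4 * r - b
    gv = np.clip(exg - exr, 0.0, 255.0)
    return GreennessImage(values=gv)


def select_sample_image(series: list):
    """Return the midpoint element of an ordered image series.

    The sample used for colour-group estimation is the 1-based element
    ``floor((n + 1) / 2)`` — the 5th image of a 10-image series.
    """
    n = len(series)
    if n == 0:
        raise InvalidInputError("cannot pick a sample image from an empty series")
    return series[(n + 1) // 2 - 1]


def _subsample(arr: np.ndarray, limit: int, seed: int) -> np.ndarray:
    if arr.shape[0] <= limit:
        return arr
    rng = np.random.default_rng(seed)
    idx = rng.choice(arr.shape[0], size=limit, replace=False)
    return arr[idx]


def estimate_colour_groups(
    sample: CalibratedImage, cfg: ClusteringConfig = ClusteringConfig()
) -> int:
    """Estimate the number of representative colour groups in a sample image.

    RGB pixels (subsampled to at most 50 000) are clustered into
    ``probe_k`` = 8 groups; clusters whose population reaches the median
    cluster size count as representative, and the census is clamped to
    [3, 10].  Deterministic for a fixed seed.
    """
    pixels = sample.pixels.reshape(-1, 3).astype(np.float64)
    pixels = _subsample(pixels, KMEANS_SUBSAMPLE, cfg.seed)
    km = KMeans(n_clusters=cfg.probe_k, random_state=cfg.seed, n_init=4)
    labels = km.fit_predict(pixels)
    sizes = np.bincount(labels, minlength=cfg.probe_k)
    k = int(np.sum(sizes >= np.median(sizes)))
    return clamp_k(k, cfg)


def clamp_k(k: int, cfg: ClusteringConfig = ClusteringConfig()) -> int:
    """Clamp a user-supplied or estimated colour-group count to [k_min, k_max]."""
    return max(cfg.k_min, min(cfg.k_max, int(k)))


def kmeans_leaf_mask(
    gv: GreennessImage, k: int, seed: int = 42
) -> LeafMask:
    """Leaf mask from k-means clustering of the greenness image.

    G_V values are clustered into ``k`` groups; pixels belonging to
    clusters whose mean greenness exceeds the global Otsu level of the
    G_V image form the mask.  A constant G_V image yields an empty mask.
    """
    if not 3 <= k <= 10:
        raise InvalidInputError(f"k must lie in [3, 10], got {k}")
    values = gv.values
    flat = values.reshape(-1, 1)
    if np.ptp(flat) == 0:
        return LeafMask(np.zeros(values.shape, dtype=bool), origin="global")
    level = threshold_otsu(values)
    fit = _subsample(flat, KMEANS_SUBSAMPLE, seed)
    km = KMeans(n_clusters=min(k, len(np.unique(fit))), random_state=seed, n_init=4)
    km.fit(fit)
    labels = km.predict(flat).reshape(values.shape)
    bright = np.flatnonzero(km.cluster_centers_.ravel() > level)
    mask = np.isin(labels, bright)
    return LeafMask(mask, origin="global")


def lab_leaf_mask(img: CalibratedImage | np.ndarray) -> LeafMask:
    """Leaf mask from the Lab green-red opponent channel.

    The image is converted to Lab; Otsu's threshold on a* selects the
    green (negative) side.  Pixels must also be genuinely greenish
    (a* < -5) so grey or green-free scenes give an empty mask.
    """
    pixels = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    a = color.rgb2lab(pixels.astype(np.uint8))[..., 1]
    if np.ptp(a) < _LAB_MIN_RANGE:
        return LeafMask(np.zeros(a.shape, dtype=bool), origin="global")
    level = threshold_otsu(a)
    mask = (a < level) & (a < _LAB_GREEN_CEILING)
    return LeafMask(mask, origin="global")


def combine_masks(a: LeafMask, b: LeafMask, min_area_px: int = 4) -> LeafMask:
    """Union of two leaf masks with small-object removal.

    The union maximises recall (Lab catches tiny leaves, clustering
    handles harvested pots); connected components smaller than
    ``min_area_px`` (default the pixel equivalent of ~1 mm² at low
    magnification) are dropped to suppress speckle.
    """
    if a.mask.shape != b.mask.shape:
        raise InvalidInputError(
            f"mask dimensions differ: {a.mask.shape} vs {b.mask.shape}"
        )
    union = a.mask | b.mask
    if min_area_px > 1:
        union = morphology.remove_small_objects(union, max_size=min_area_px - 1)
    return LeafMask(union, origin="global")


def global_leaf_mask(
    img: CalibratedImage, k: int, seed: int = 42, min_area_px: int | None = None
) -> LeafMask:
    """Full image-level segmentation: greenness k-means ∪ Lab opponent."""
    gv = compute_greenness_img(img)
    km_mask = kmeans_leaf_mask(gv, k, seed=seed)
    lab_mask = lab_leaf_mask(img)
    if min_area_px is None:
        min_area_px = max(1, round(img.scale.px_per_mm**2))
    return combine_masks(km_mask, lab_mask, min_area_px=min_area_px)
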