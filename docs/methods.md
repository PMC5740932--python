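# Methods

This note documents the measurement model behind `leafgp`, the defaults
and units of every tunable parameter, what the synthetic-data generator
does and does not emulate, and the numerical conventions adopted where
the procedure left genuine design freedom.

## Measurement model

The pipeline estimates per-pot growth traits from uncalibrated RGB
photographs by exploiting two pieces of scene structure: four red
circular fiducial stickers of known physical radius at the tray corners,
and the strong colour separation between leaves and soil.

**Working frame.** Every image is first resized to a 1024-px height
(width scaled to preserve aspect ratio within a pixel). All pixel-space
processing — marker detection, scale estimation, segmentation,
measurement — happens in this one frame, so the derived px/mm scale is
valid for every downstream quantity. The original image object is never
modified.

**Calibration.** Red-sticker pixels satisfy
`r > 125 ∧ b < 225 ∧ (r − g) > 50`. Connected components of this mask
are screened as circular-marker candidates by solidity ≥ 0.9,
eccentricity ≤ 0.6 and area within [0.25×, 4×] the median candidate area
(components under 9 px are never plausible stickers); if more than four
survive, the four nearest the image corners win. The numeric bounds are
this package's choices — the screening features (area, eccentricity,
solidity) are standard, but no canonical values exist. The scale is
`px_per_mm = mean marker radius (px) / marker radius (mm)`; marker radii
are equivalent-circle radii from component areas. Marker radius defaults
to 4 mm (Arabidopsis stickers) with a 5 mm wheat preset; it is a CLI
parameter. The marker quadrilateral (corner centres ordered by angle
about their centroid, rotated so the top-left extreme leads) is warped
projectively onto an axis-aligned rectangle whose width/height are the
means of the opposing edge lengths — this minimises anisotropic
distortion and makes the axis-aligned case an exact pixel crop. Collinear
or duplicate centres raise a degenerate-geometry error. The ROI is then
smoothed with a 3×3 per-channel median filter: edge-preserving,
parameter-free and deterministic; a uniform image passes through
unchanged and flat-region variance never increases.

**Global segmentation.** The greenness index is
`G_V = ExG − ExR = (2g − r − b) − (1.4r − b)`, clipped to [0, 255]. The
clip is this package's normalisation choice: it preserves order and maps
greenness onto the familiar 8-bit range. Two detectors run per image:

* *k-means route*: 1-D k-means over G_V values (fitting subsampled to
  50 000 pixels, fixed seed, default 42), keeping pixels of clusters
  whose mean G_V exceeds the image's global Otsu level. Robust for
  medium-sized plants and, because harvested pots populate their own
  colour clusters, handles destructively harvested pots without special
  cases.
* *Lab route*: Otsu threshold on the a\* (green–red opponent) channel,
  green side, with a guard requiring a\* < −5 so that green-free scenes
  (bare soil, greyscale input) yield an empty mask instead of an
  arbitrary Otsu split. Catches tiny leaves the clustering route drops.

The global mask is the union of the two, cleaned of components smaller
than 1 mm² (scale-equivalent pixels; configurable). Union was chosen
because each route misses what the other finds — recall is maximised
globally and precision restored per pot.

The colour-group count k is estimated once per series: the series'
midpoint image (1-based index ⌊(n+1)/2⌋) is clustered into 8 RGB groups
and k is the number of groups at least as populous as the median group,
clamped to [3, 10]. The "median" statistic is over cluster sizes; the
count (rather than, say, mean greenness) is the natural census of
"representative" colour groups. k is held fixed across a series so all
images share one segmentation regime.

**Pot-level refinement.** The ROI is tiled exactly (boundaries at
`round(i·W/cols)`, `round(j·H/rows)`; row-major 1-based indices), leaves
crossing a border are clipped at it (no double counting), and each pot's
mask is filtered by three deterministic rules applied in a single pass
(hence idempotent, and pixels are only ever removed): drop components
under 1 mm²; drop components whose mean G_V falls below the pot-level
Otsu level of G_V; keep survivors whose centroid lies in the central 90%
of the pot or within 20% of the pot width of the largest survivor. These
rules are stand-ins for pot-level contrast/texture/position heuristics
whose exact form is not canonically defined; they are deliberately
simple and are validated against the generator's ground truth
(precision ≥ 0.95, recall ≥ 0.90 per pot) rather than claimed optimal.
An emptied (harvested) pot legitimately refines to an empty mask.

## Traits

| trait | definition | units |
|---|---|---|
| projected leaf area | foreground pixel count / (px/mm)² | mm² |
| leaf perimeter | weighted boundary-configuration estimate, all components | mm |
| hull area | convex-hull-image pixel count / (px/mm)² | mm² |
| hull length / width | Feret (max vertex-pair) diameter of the hull; extent perpendicular to it | mm |
| stockiness | 100·(4π·Area)/(2π·R)², R = hull length / 2, capped at 100 | % |
| compactness | 100 · Area / HullArea | % |
| greenness | mean clipped G_V over the hull region | 0–255 |
| daily RGR | (ln A₂ − ln A₁) / ln A₁ / Δt for consecutive images | day⁻¹ |

Numerical conventions worth noting:

* **Hull axes are Feret extents, not moment axes.** An ellipse fit
  through second moments reads ~2× too long for bimodal masks (two
  distant leaves); the max pairwise vertex distance is rotation-invariant
  and degrades gracefully. Hull *area* uses the rasterised hull image, so
  `area ≤ hull_area` holds exactly and compactness never exceeds 100%.
* **Stockiness of a circle is 100% by construction** (area πR², Feret
  diameter 2R); the cap at 100 absorbs sub-pixel rasterisation excess.
* **The RGR formula divides by ln A₁.** This differs from the classical
  relative growth rate (which divides by Δt only); it is implemented
  exactly as defined, and A₁ = 1 mm² (ln A₁ = 0) is recorded as an
  absent value rather than an error. Δt comes from capture-time
  metadata; without metadata consecutive images are 1 day apart.
* **Perimeter raster tolerance.** The boundary-configuration estimator
  under-reads components below ~5 px radius by up to 10%; the
  isoperimetric invariant `perimeter ≥ 2√(π·area)` is therefore enforced
  in tests with a 10% tolerance. Perimeter is additive over disjoint
  components.
* Empty pots yield all-zero traits and empty hulls, never errors.

## Leaf counting

Two detectors, combined by `max`:

* **Skeleton end points.** The mask is thinned; end points are pixels
  matching one of four hit-or-miss templates (foreground centre,
  background on both laterals and the entire far side, the continuation
  side unconstrained). Thinning a rasterised mask sprouts short spurious
  side branches, so tips within 3 px (geodesic) of a skeleton junction
  are pruned and surviving tips within 3 px of each other merge — the
  spur scale is set by the 8-neighbour lattice, an order of magnitude
  below any genuine leaf branch. The skeleton is then read as a star
  graph from the mask centroid; each tip edge carries the geodesic
  skeleton length to the tip (mm) and the area of the mask component
  behind the tip divided by its tip count (mm²). Edges longer than
  15 mm or heavier than 100 mm² count as large/long leaves (both
  thresholds configurable).
* **Outline sweeping.** Squared Euclidean distance from the mask
  centroid (not the hull centroid — it tracks the leafy mass) to the
  boundary, sampled per integer degree as the maximum over boundary
  pixels falling in each 1° bin (robust to concavities; empty bins
  interpolated circularly), smoothed with a wrap-around Gaussian
  (σ = 3°). Peaks are circular local maxima clearing a prominence floor
  of 5% of the smoothed range. Boundary pixels carry ~±1 px
  quantisation, which perturbs a squared distance by ~2√(mean); the
  flatness guard (→ 1 leaf object for a round seedling) and the
  prominence floor both include this term so raster wobble on a
  near-circular outline cannot read as leaf tips.

`max` is the combination rule because each detector under-counts in a
known regime (skeletons miss small central leaves; sweeping merges
overlapping tips) and neither over-counts after spur pruning. Counts are
suppressed (empty CSV fields) in wheat mode, where overlapping blades
make tip counting meaningless.

## Batch semantics

Series are discovered by the naming convention
`<ExpRef>_<TrayNo>_<YYYY-MM-DD[_HH-MM]>.<ext>` (JPEG/PNG,
case-insensitive extensions), grouped by (ExpRef, TrayNo); folder mode
applies the pattern to the directory name; no-metadata mode forms one
arbitrary series. The convention is this package's own documented
protocol — files that do not match are routed to an "unparsed" series
with a warning, never crashed on. Images are ordered by capture time
when available, else by name. Unreadable or uncalibratable images are
logged, counted as declined and skipped; a series fails only if no image
survives.

Up to 3 series process concurrently by default (configurable; a warning
notes the memory cost of more). The clustering stage runs under a lock —
the one stage not assumed thread-safe — and results are invariant to
worker count and job order (verified byte-for-byte on the CSV output).
CSV floats carry 3 decimals (6 for RGR); absent values are empty fields.

## Synthetic data

The generator renders what the pipeline expects to see: a
soil-coloured background (warm brown base, low-frequency mottling,
Gaussian grain, zero clipped greenness), four red corner discs (default
20 px radius declared as 4 mm, i.e. a true scale of 5 px/mm at the
1024-px working height, matching tray photographs rescaled from
~2592×1944), and one rosette per pot drawn as an n-petalled rose curve
`r(θ) = r_out·(0.55 + 0.45·cos n(θ−φ))` whose petal count is the exact
leaf count. Defaults model a 4×6-pot tray; options add algae speckle
(1–2 px green dots) and harvested pots. Everything is deterministic
given a seed, and the returned ground truth (full leaf mask, per-pot
counts, marker geometry, true scale) is exact by construction.

What it does **not** emulate: perspective distortion and lens effects,
specular soil highlights, overlapping or occluding leaves across pots,
petioles distinct from blades, diurnal colour drift, and camera noise
beyond i.i.d. Gaussian grain. Passing the recovery tests therefore
demonstrates the pipeline's geometric and radiometric correctness under
controlled conditions — not field robustness, which the validation
thresholds (area within 5%, compactness within 3 pp, exact leaf counts
in ≥ 90% of instances) should not be read as promising for real imagery.

Validation problem sizes were chosen to exercise every code path at
desk scale: 50 seeded two-pot trays sweeping petal counts 2–12 for
trait recovery, 100 random ≤ 64×64 skeletons for the end-point oracle,
and 2-image series for scheduler-invariance checks.

## Known limitations

* Leaf counts assume a rosette habit; wheat mode reports none.
* No lens-distortion or white-balance correction; scenes lit strongly
  enough to clip the red channel can defeat marker detection.
* The pot-refinement greenness rule can misjudge pots almost entirely
  covered by leaf (the pot-level Otsu split then falls inside the leaf
  distribution); at that growth stage plants typically span pot borders
  anyway, which the lattice clip handles.
* The RGR definition (see above) is not the classical one; values are
  comparable within this tool but not directly against classical RGR.
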