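"""Batch orchestration: series discovery, per-series processing, CSV output.

Image series are discovered on disk and grouped by experiment/tray
metadata parsed from file names (``<ExpRef>_<TrayNo>_<YYYY-MM-DD[_HH-MM]>``),
from folder names, or not at all (one arbitrary series).  Each series runs
through the full chain — rescale, marker calibration, ROI, denoise, global
segmentation, pot split and refinement, traits, leaf counts, growth rate —
and lands in one CSV per series.  A thread pool bounded at three workers
by default processes several series concurrently; a lock serialises the
clustering stage so results are independent of scheduling.
"""

from __future__ import annotations

import logging
import re
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import calibrate as _cal
from . import leafcount as _lc
from . import segment as _seg
from .errors import InvalidInputError, LeafGPError
from .pots import PotMask, TrayLayout, build_pot_layout, refine_pot_mask, split_into_pots
from .synthetic import generate_synthetic_tray  # noqa: F401  (re-export)
from .traits import GrowthPair, TraitRecord, daily_rgr, measure_pot

logger = logging.getLogger("leafgp")

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}

#: KMeans/BLAS interplay is the one stage we do not assume thread-safe.
_CLUSTER_LOCK = threading.Lock()

_NAME_RE = re.compile(
    r"^(?P<exp>.+)_(?P<tray>[^_]+)_(?P<date>\d{4}-\d{2}-\d{2})(?:_(?P<hm>\d{2}-\d{2}))?$"
)
_FOLDER_RE = re.compile(
    r"^(?P<exp>.+?)_(?P<tray>[^_]+?)(?:_(?P<date>\d{4}-\d{2}-\d{2}))?$"
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one batch run needs beyond the input directory."""

    rows: int = 4
    cols: int = 6
    ref_radius_mm: float = 4.0
    species: str = "arabidopsis"  # or "wheat"
    k: int | str = "auto"  # "auto" or an integer in [3, 10]
    workers: int = 3
    seed: int = 42
    min_component_area_mm2: float = 1.0
    metadata_mode: str = "name"  # "name", "folder" or "none"
    save_debug_images: bool = False
    out_dir: Path | None = None

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("rows and cols must be >= 1")
        if self.ref_radius_mm <= 0:
            raise InvalidInputError("ref_radius_mm must be positive")
        if self.species not in ("arabidopsis", "wheat"):
            raise InvalidInputError(f"unknown species {self.species!r}")
        if self.metadata_mode not in ("name", "folder", "none"):
            raise InvalidInputError(f"unknown metadata mode {self.metadata_mode!r}")
        if self.workers < 1:
            raise InvalidInputError("workers must be >= 1")
        if self.k != "auto":
            k = int(self.k)
            if not 3 <= k <= 10:
                raise InvalidInputError("k must be 'auto' or an integer in [3, 10]")


@dataclass
class SeriesMetadata:
    exp_ref: str = ""
    tray_no: str = ""
    mode: str = "none"  # from_image_name / from_folder_name / none
    capture_times: dict[str, datetime | None] = field(default_factory=dict)


@dataclass
class SeriesJob:
    metadata: SeriesMetadata
    images: list[Path]
    status: str = "not_processed"  # not_processed, processing(i/n), done, failed


@dataclass
class TraitTable:
    """All (image, pot) trait rows for one completed series."""

    metadata: SeriesMetadata
    rows: list[TraitRecord] = field(default_factory=list)
    declined: int = 0

    CSV_HEADER = (
        "image_name,capture_time,exp_ref,tray_no,pot_id,px_per_mm,"
        "projected_leaf_area_mm2,leaf_perimeter_mm,hull_area_mm2,hull_length_mm,"
        "hull_width_mm,stockiness_pct,compactness_pct,leaf_count,large_leaf_count,"
        "greenness,daily_rgr"
    )


def _parse_stem(stem: str):
    m = _NAME_RE.match(stem)
    if not m:
        return None
    ts = m.group("date") + (" " + m.group("hm").replace("-", ":") if m.group("hm") else "")
    fmt = "%Y-%m-%d %H:%M" if m.group("hm") else "%Y-%m-%d"
    return m.group("exp"), m.group("tray"), datetime.strptime(ts, fmt)


def _find_images(input_dir: Path) -> list[Path]:
    return sorted(
        p
        for p in input_dir.rglob("*")
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def parse_series_metadata(input_dir, mode: str = "name") -> list[SeriesJob]:
    """Group the images under ``input_dir`` into processing series.

    ``mode='name'`` parses ``<ExpRef>_<TrayNo>_<date>`` from file names
    and groups by (ExpRef, TrayNo); ``mode='folder'`` applies the pattern
    to the containing folder name instead; ``mode='none'`` returns all
    images as one arbitrary series.  Files that do not match the pattern
    are routed to an "unparsed" series with a warning rather than
    crashing the run.
    """
    input_dir = Path(input_dir)
    paths = _find_images(input_dir)
    if not paths:
        raise InvalidInputError(f"no JPEG/PNG images found under {input_dir}")

    groups: dict[tuple[str, str], SeriesJob] = {}

    def job_for(key: tuple[str, str], meta_mode: str) -> SeriesJob:
        if key not in groups:
            groups[key] = SeriesJob(
                metadata=SeriesMetadata(exp_ref=key[0], tray_no=key[1], mode=meta_mode),
                images=[],
            )
        return groups[key]

    if mode == "none":
        job = job_for(("", ""), "none")
        job.images = paths
        job.metadata.capture_times = {p.name: None for p in paths}
        return [job]

    for p in paths:
        parsed = _parse_stem(p.stem)
        if mode == "name":
            if parsed is None:
                logger.warning("unparsed image name: %s", p.name)
                job = job_for(("unparsed", ""), "from_image_name")
                job.metadata.capture_times[p.name] = None
                job.images.append(p)
                continue
            exp, tray, when = parsed
            job = job_for((exp, tray), "from_image_name")
        else:  # folder mode
            fm = _FOLDER_RE.match(p.parent.name)
            if fm is None:
                logger.warning("unparsed folder name: %s", p.parent.name)
                job = job_for(("unparsed", ""), "from_folder_name")
                job.metadata.capture_times[p.name] = None
                job.images.append(p)
                continue
            job = job_for((fm.group("exp"), fm.group("tray")), "from_folder_name")
            when = parsed[2] if parsed else None
        job.metadata.capture_times[p.name] = when
        job.images.append(p)

    jobs = list(groups.values())
    for job in jobs:
        times = job.metadata.capture_times
        if all(times.get(p.name) is not None for p in job.images):
            job.images.sort(key=lambda p: (times[p.name], p.name))
        else:
            job.images.sort(key=lambda p: p.name)
    return jobs


def _load_raw(path: Path, capture_time: datetime | None) -> _cal.RawImage:
    pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return _cal.RawImage(pixels=pixels, source_name=path.name, capture_time=capture_time)


def _series_k(job: SeriesJob, cfg: RunConfig) -> int:
    """Colour-group count for a series: user override or midpoint estimate."""
    ccfg = _seg.ClusteringConfig(seed=cfg.seed)
    if cfg.k != "auto":
        return _seg.clamp_k(int(cfg.k), ccfg)
    sample_path = _seg.select_sample_image(job.images)
    raw = _load_raw(sample_path, None)
    roi = _cal.calibrate_image(raw, cfg.ref_radius_mm)
    with _CLUSTER_LOCK:
        return _seg.estimate_colour_groups(roi, ccfg)


def _save_debug(out_dir: Path, name: str, roi, mask, regions):
    from PIL import Image, ImageDraw

    debug = out_dir / "debug"
    debug.mkdir(parents=True, exist_ok=True)
    iio.imwrite(debug / f"{name}_mask.png", (mask.mask * 255).astype(np.uint8))
    overlay = roi.pixels.copy()
    for reg in regions:
        x0, y0, x1, y1 = reg.bbox
        overlay[y0:y1, [x0, x1 - 1]] = (255, 255, 0)
        overlay[[y0, y1 - 1], x0:x1] = (255, 255, 0)
    overlay[mask.mask] = (255, 0, 0)
    im = Image.fromarray(overlay)
    draw = ImageDraw.Draw(im)
    for reg in regions:
        draw.text((reg.bbox[0] + 4, reg.bbox[1] + 2), str(reg.index),
                  fill=(255, 255, 0))
    im.save(debug / f"{name}_overlay.png")


def process_series(job: SeriesJob, cfg: RunConfig) -> TraitTable:
    """Run the full pipeline over one image series.

    Unreadable or uncalibratable images are logged, counted as declined
    and skipped; the series continues.  Daily growth rate is computed per
    pot between consecutive successfully processed images, with Δt from
    capture times when available, else 1 day per step.
    """
    table = TraitTable(metadata=job.metadata)
    layout = TrayLayout(cfg.rows, cfg.cols)
    n = len(job.images)

    try:
        k = _series_k(job, cfg)
    except LeafGPError as exc:
        logger.warning("series %s: colour-group estimation failed (%s); using k=5",
                       job.metadata.exp_ref, exc)
        k = 5

    count_leaves = cfg.species == "arabidopsis"
    per_image_records: list[list[TraitRecord]] = []
    for i, path in enumerate(job.images, start=1):
        job.status = f"processing({i}/{n})"
        when = job.metadata.capture_times.get(path.name)
        try:
            raw = _load_raw(path, when)
            roi = _cal.calibrate_image(raw, cfg.ref_radius_mm)
            min_area_px = max(
                1, round(cfg.min_component_area_mm2 * roi.scale.px_per_mm**2)
            )
            with _CLUSTER_LOCK:
                mask = _seg.global_leaf_mask(roi, k, seed=cfg.seed, min_area_px=min_area_px)
            regions = build_pot_layout(mask.mask.shape, layout)
            pots = split_into_pots(mask, regions)
            records = []
            for pot in pots:
                refined = refine_pot_mask(pot, roi, min_area_px=min_area_px)
                rec = measure_pot(refined, roi, image_name=path.name, capture_time=when)
                if count_leaves:
                    res = _lc.count_leaves(refined, roi.scale)
                    rec.leaf_count = res.combined
                    rec.large_leaf_count = res.large_leaves
                else:
                    rec.leaf_count = None
                    rec.large_leaf_count = None
                records.append(rec)
            if cfg.save_debug_images and cfg.out_dir is not None:
                _save_debug(Path(cfg.out_dir), path.stem, roi, mask, regions)
            per_image_records.append(records)
        except Exception as exc:  # decline the image, keep the series alive
            table.declined += 1
            logger.warning("declined image %s: %s", path.name, exc)

    if not per_image_records:
        job.status = "failed"
        logger.error("series %s/%s: no image processed successfully",
                     job.metadata.exp_ref, job.metadata.tray_no)
        return table

    _fill_growth_rates(per_image_records)
    for records in per_image_records:
        table.rows.extend(records)
    job.status = "done"
    return table


def _fill_growth_rates(per_image_records: list[list[TraitRecord]]) -> None:
    """Daily RGR between consecutive successful images, per pot, in place."""
    for prev, curr in zip(per_image_records, per_image_records[1:]):
        for p_rec, c_rec in zip(prev, curr):
            if p_rec.area_mm2 <= 0 or c_rec.area_mm2 <= 0:
                continue
            if p_rec.capture_time and c_rec.capture_time:
                dt = (c_rec.capture_time - p_rec.capture_time).total_seconds() / 86400.0
                if dt <= 0:
                    dt = 1.0
            else:
                dt = 1.0
            pair = GrowthPair(p_rec.area_mm2, c_rec.area_mm2, dt)
            c_rec.daily_rgr = daily_rgr(pair)


def run_batch(
    jobs: list[SeriesJob],
    cfg: RunConfig,
    workers: int | None = None,
    _process=process_series,
) -> list[TraitTable]:
    """Process several series with bounded concurrency (default 3 workers).

    Results are returned in job order and are byte-identical whatever the
    worker count or scheduling; ``_process`` is injectable for testing.
    """
    workers = cfg.workers if workers is None else workers
    if workers < 1:
        raise InvalidInputError("workers must be >= 1")
    if len(jobs) <= 1 or workers == 1:
        return [_process(job, cfg) for job in jobs]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda j: _process(j, cfg), jobs))


def _fmt(value, decimals: int = 3) -> str:
    if value is None:
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.{decimals}f}"


def write_trait_csv(table: TraitTable, out_dir) -> Path:
    """Write one series' trait table as CSV; returns the written path.

    Header and column order are fixed; floats carry 3 decimals; absent
    values (undefined RGR, wheat leaf counts) are empty fields.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = table.metadata
    stem = "_".join(x for x in (meta.exp_ref, meta.tray_no) if x) or "series"
    path = out / f"{stem}_traits.csv"
    lines = [TraitTable.CSV_HEADER]
    for r in table.rows:
        when = r.capture_time.isoformat() if r.capture_time else ""
        lines.append(
            ",".join(
                [
                    r.image_name,
                    when,
                    meta.exp_ref,
                    meta.tray_no,
                    str(r.pot_index),
                    _fmt(r.px_per_mm),
                    _fmt(r.area_mm2),
                    _fmt(r.perimeter_mm),
                    _fmt(r.hull_area_mm2),
                    _fmt(r.hull_length_mm),
                    _fmt(r.hull_width_mm),
                    _fmt(r.stockiness_pct),
                    _fmt(r.compactness_pct),
                    _fmt(r.leaf_count),
                    _fmt(r.large_leaf_count),
                    _fmt(r.greenness),
                    _fmt(r.daily_rgr, 6),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(input_dir, cfg: RunConfig) -> list[Path]:
    """Discover series, process them, write CSVs and a run log; return CSV paths."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else Path(input_dir) / "results"
    cfg = replace(cfg, out_dir=out_dir)
    jobs = parse_series_metadata(input_dir, cfg.metadata_mode)
    tables = run_batch(jobs, cfg)
    paths = [write_trait_csv(t, out_dir) for t in tables if t.rows]
    processed = sum(len({r.image_name for r in t.rows}) for t in tables)
    declined = sum(t.declined for t in tables)
    log_path = out_dir / "run_log.txt"
    log_lines = [
        f"series discovered: {len(jobs)}",
        f"images processed: {processed}",
        f"images declined: {declined}",
    ] + [f"{j.metadata.exp_ref}/{j.metadata.tray_no}: {j.status}" for j in jobs]
    log_path.write_text("\n".join(log_lines) + "\n")
    return paths
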