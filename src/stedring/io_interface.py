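"""Readers, writers, run configuration, and the batch pipeline driver.

The pipeline consumes a manifest of two-channel TIFF image pairs (one
high-resolution membrane channel, one confocal companion channel), a table of
manually clicked approximate ring centers, and a run configuration.  For
every seeded center it fits the membrane ring, extracts the dual arc-length
profile, computes the moving-average Pearson R, labels the arc samples
Between/Outside against the other rings of the image, and accumulates
per-peroxisome, per-cell, summary and test tables.  Per-ring failures are
recorded with a failure code and never abort the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colocalization import DEFAULT_WINDOW, ring_correlation
from .contact_classification import (
    ArcLabeling,
    CellRecord,
    ContactConfig,
    PeroxisomeRecord,
    between_outside_means,
    classify_cell,
    label_arc_samples,
    outside_percentage,
)
from .errors import FormatError, StedringError, ValidationError
from .population_stats import summarize_conditions
from .profile_extraction import MembraneProfile, ProfileConfig, extract_dual_profiles
from .ring_fitting import FitConfig, ImagePlane, fit_ring, refine_ring_fits
from .synthetic_scenes import SceneConfig, SceneGroundTruth, generate_scene, render_scene

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "ResultsTable",
    "read_image_pair",
    "write_image",
    "read_centers",
    "write_scene",
    "build_demo_dataset",
    "analyze_image_pair",
    "run_pipeline",
]

SCHEMA_VERSION = "stedring-results-v1"
CENTER_COLUMNS = ["image_id", "cell_id", "row_px", "col_px"]

log = logging.getLogger("stedring")


@dataclass
class RunConfig:
    """Batch run configuration (mirrors the YAML/JSON config file)."""

    images: list[dict]                 # image_id, condition, replicate, sted_path, conf_path
    centers_path: str
    output_dir: str = "results"
    pixel_size_nm: float | None = None  # overrides TIFF metadata when set
    fit: FitConfig = field(default_factory=FitConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    correlation_window: int = DEFAULT_WINDOW
    anova_level: str = "ring"
    cell_rule: str = "pooled"
    paired_conditions: tuple[str, str] | None = None
    paired_direction: str = "greater"
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        for key, klass in (("fit", FitConfig), ("profile", ProfileConfig),
                           ("contact", ContactConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if kwargs.get("paired_conditions") is not None:
            kwargs["paired_conditions"] = tuple(kwargs["paired_conditions"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValidationError(f"bad run config: {exc}") from exc


@dataclass
class ResultsTable:
    """All output tables of one batch run."""

    per_ring: pd.DataFrame
    per_cell: pd.DataFrame
    outside_pcts: pd.DataFrame
    summary: pd.DataFrame
    tests: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("per_peroxisome", self.per_ring),
            ("per_cell", self.per_cell),
            ("outside_percentages", self.outside_pcts),
            ("summary", self.summary),
            ("tests", self.tests),
        ):
            p = outdir / f"{name}.csv"
            with open(p, "w", newline="") as fh:
                fh.write(f"# {SCHEMA_VERSION}\n")
                df.to_csv(fh, index=False)
            paths[name] = p
        return paths


def write_image(path: str | Path, plane: ImagePlane) -> None:
    """Write one channel as 16-bit grayscale TIFF, pixel size in the description."""
    data = np.clip(np.round(plane.pixels), 0, 65535).astype(np.uint16)
    desc = json.dumps(
        {
            "pixel_size_nm": plane.pixel_size_nm,
            "channel_name": plane.channel_name,
            "resolution_class": plane.resolution_class,
        }
    )
    tifffile.imwrite(str(path), data, description=desc)


def _read_plane(path: str | Path, pixel_size_nm: float | None,
                resolution_class: str) -> ImagePlane:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise FormatError(f"{path}: expected a single-plane TIFF, got {len(tf.pages)} pages")
        page = tf.pages[0]
        arr = page.asarray()
        desc = page.description or ""
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2D grayscale, got shape {arr.shape}")
    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise FormatError(
            f"{path}: no pixel size in TIFF metadata and no override configured"
        )
    return ImagePlane(
        arr.astype(float), float(px),
        channel_name=str(meta.get("channel_name", path.stem)),
        resolution_class=resolution_class,
    )


def read_image_pair(
    entry: dict, pixel_size_nm: float | None = None
) -> tuple[ImagePlane, ImagePlane]:
    """Read one manifest entry's STED + confocal TIFFs and enforce congruence."""
    sted = _read_plane(entry["sted_path"], pixel_size_nm, "sted")
    conf = _read_plane(entry["conf_path"], pixel_size_nm, "confocal")
    if sted.shape != conf.shape:
        raise FormatError(
            f"channel rasters of image {entry.get('image_id')} differ in shape: "
            f"{sted.shape} vs {conf.shape}"
        )
    return sted, conf


def read_centers(path: str | Path) -> pd.DataFrame:
    """Read and validate the clicked-centers CSV (image_id,cell_id,row_px,col_px).

    Extra columns are passed through.  Duplicate (image_id, row_px, col_px)
    rows are dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"centers file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in CENTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in ("row_px", "col_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise FormatError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = coerced
    n0 = len(df)
    df = df.drop_duplicates(subset=["image_id", "row_px", "col_px"]).reset_index(drop=True)
    if len(df) < n0:
        log.warning("read_centers: dropped %d duplicate center rows", n0 - len(df))
    return df


def write_scene(
    outdir: str | Path,
    name: str,
    truth: SceneGroundTruth,
    noise: bool = True,
) -> dict:
    """Render a scene and write TIFFs, centers CSV, truth JSON and a sidecar config.

    Returns a manifest entry usable in :class:`RunConfig`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sted, conf, centers = render_scene(truth, noise=noise)
    sted_path = outdir / f"{name}_ch1_sted.tif"
    conf_path = outdir / f"{name}_ch2_conf.tif"
    write_image(sted_path, sted)
    write_image(conf_path, conf)
    centers = centers.assign(image_id=name)
    centers_path = outdir / f"{name}_centers.csv"
    centers.to_csv(centers_path, index=False)
    (outdir / f"{name}_truth.json").write_text(truth.to_json())
    (outdir / f"{name}_config.json").write_text(json.dumps(dataclasses.asdict(truth.params)))
    return {
        "image_id": name,
        "sted_path": str(sted_path),
        "conf_path": str(conf_path),
        "centers_path": str(centers_path),
    }


def build_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    conditions: dict[str, dict] | None = None,
    n_replicates: int = 2,
    noise: bool = True,
) -> RunConfig:
    """Simulate a small multi-condition dataset and return its RunConfig.

    ``conditions`` maps a condition label to SceneConfig overrides; the
    default pair mimics a proliferation-like state (high channel coupling, no
    Outside enrichment) versus a degradation-like state (low coupling,
    Outside-enriched companion signal).
    """
    outdir = Path(outdir)
    if conditions is None:
        conditions = {
            "growth": {"coupling_alpha": 0.8, "outside_enrichment_beta": 1.0},
            "shift": {"coupling_alpha": 0.3, "outside_enrichment_beta": 2.0},
        }
    images = []
    all_centers = []
    i = 0
    for cond, overrides in conditions.items():
        for rep in range(n_replicates):
            cfg = SceneConfig(rng_seed=int(seed * 1000 + i) % (2**31 - 1), **overrides)
            truth = generate_scene(cfg)
            name = f"{cond}_rep{rep}"
            entry = write_scene(outdir, name, truth, noise=noise)
            centers = pd.read_csv(entry.pop("centers_path"))
            all_centers.append(centers)
            entry.update(condition=cond, replicate=f"rep{rep}")
            images.append(entry)
            i += 1
    centers_path = outdir / "centers.csv"
    pd.concat(all_centers, ignore_index=True).to_csv(centers_path, index=False)
    return RunConfig(
        images=images,
        centers_path=str(centers_path),
        output_dir=str(outdir / "results"),
        rng_seed=seed,
    )


def analyze_image_pair(
    sted: ImagePlane,
    conf: ImagePlane,
    centers: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[PeroxisomeRecord]:
    """Fit, profile, correlate, and label every seeded ring of one image.

    ``centers`` needs ``cell_id``, ``row_px`` and ``col_px`` columns.  Rings
    that fail any stage are returned as failure-coded records.
    """
    if config is None:
        config = RunConfig(images=[], centers_path="")
    fits: list = []
    meta: list[dict] = []
    for _, row in centers.iterrows():
        rec = {"cell_id": int(row["cell_id"]), "seed": (row["row_px"], row["col_px"])}
        try:
            rec["fit"] = fit_ring(sted, rec["seed"], config.fit)
        except StedringError as exc:
            rec["fit"] = None
            rec["failure"] = type(exc).__name__
            log.info("ring at %s failed: %s: %s", rec["seed"], type(exc).__name__, exc)
        meta.append(rec)

    good = [m for m in meta if m.get("fit") is not None]
    for pos, m in enumerate(good):
        m["good_idx"] = pos
    good_fits = refine_ring_fits(sted, [m["fit"] for m in good], config.fit)
    for m in good:
        m["fit"] = good_fits[m["good_idx"]]
    records: list[PeroxisomeRecord] = []
    ring_id = 0
    for m in meta:
        if m.get("fit") is None:
            records.append(
                PeroxisomeRecord(ring_id=ring_id, cell_id=m["cell_id"],
                                 failure=m["failure"])
            )
            ring_id += 1
            continue
        fit = m["fit"]
        rec = PeroxisomeRecord(
            ring_id=ring_id,
            cell_id=m["cell_id"],
            radius_nm=fit.radius_nm,
            circumference_nm=fit.circumference_nm,
            n_points=fit.n_points,
            method=fit.method,
            quality=fit.quality,
        )
        try:
            profile = extract_dual_profiles(sted, conf, fit, config.profile)
            corr = ring_correlation(profile, config.correlation_window, ring_id)
            labeling = label_arc_samples(
                m["good_idx"], good_fits, profile.angles, config.contact
            )
            mb, mo, nb, no = between_outside_means(profile, labeling)
            rec.mean_ch1 = float(profile.intensities_ch1.mean())
            rec.mean_ch2 = float(profile.intensities_ch2.mean())
            rec.R = corr.R
            rec.window = corr.window
            rec.mean_between_ch2 = mb
            rec.mean_outside_ch2 = mo
            rec.n_between = nb
            rec.n_outside = no
            mask = labeling.is_between
            ch1 = profile.intensities_ch1
            rec.mean_between_ch1 = float(ch1[mask].mean()) if nb else None
            rec.mean_outside_ch1 = float(ch1[~mask].mean()) if no else None
        except StedringError as exc:
            rec.failure = type(exc).__name__
            log.info("ring %d analysis failed: %s: %s", ring_id, type(exc).__name__, exc)
        records.append(rec)
        ring_id += 1
    return records


def run_pipeline(config: RunConfig) -> ResultsTable:
    """Run the full analysis batch.

    Deterministic for fixed inputs and configuration; per-ring failures are
    isolated into failure-coded rows (rows in = rows out).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.images:
        raise ValidationError("empty image manifest")
    centers_all = read_centers(config.centers_path)

    ring_rows: list[dict] = []
    cell_records: list[CellRecord] = []
    for entry in config.images:
        image_id = entry["image_id"]
        condition = entry.get("condition", "")
        replicate = entry.get("replicate", "")
        sted, conf = read_image_pair(entry, config.pixel_size_nm)
        centers = centers_all[centers_all["image_id"].astype(str) == str(image_id)]
        if centers.empty:
            log.warning("image %s has no seeded centers; skipped", image_id)
            continue
        records = analyze_image_pair(sted, conf, centers, config)
        for rec in records:
            rec.condition = condition
            rec.replicate = replicate
            row = dataclasses.asdict(rec)
            row["image_id"] = image_id
            ring_rows.append(row)
        by_cell: dict[int, list[PeroxisomeRecord]] = {}
        for rec in records:
            if rec.failure == "":
                by_cell.setdefault(rec.cell_id, []).append(rec)
        for cell_id, recs in sorted(by_cell.items()):
            cell_records.append(classify_cell(recs, rule=config.cell_rule))

    per_ring = pd.DataFrame(ring_rows)
    lead = ["image_id", "ring_id", "cell_id", "condition", "replicate"]
    if len(per_ring):
        per_ring = per_ring[lead + [c for c in per_ring.columns if c not in lead]]
    per_cell = pd.DataFrame([dataclasses.asdict(c) for c in cell_records])

    pct_rows = []
    if len(per_cell):
        for (cond, rep), sub in per_cell.groupby(["condition", "replicate"]):
            cells = [CellRecord(**r) for r in sub.to_dict("records")]
            pct, n_excl = outside_percentage(cells)
            pct_rows.append(
                {"condition": cond, "replicate": rep, "outside_pct": pct,
                 "n_cells": len(cells), "n_indeterminate": n_excl}
            )
            if n_excl:
                log.info("condition %s/%s: %d indeterminate cells excluded",
                         cond, rep, n_excl)
    outside_pcts = pd.DataFrame(
        pct_rows, columns=["condition", "replicate", "outside_pct",
                           "n_cells", "n_indeterminate"]
    )

    summary, tests = summarize_conditions(
        per_ring if len(per_ring) else pd.DataFrame(columns=["condition", "replicate"]),
        cells=per_cell if len(per_cell) else None,
        outside_pcts=outside_pcts if len(outside_pcts) else None,
        anova_level=config.anova_level,
        paired_conditions=config.paired_conditions,
        paired_direction=config.paired_direction,
    )
    return ResultsTable(
        per_ring=per_ring,
        per_cell=per_cell,
        outside_pcts=outside_pcts,
        summary=summary,
        tests=tests,
    )
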