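"""Raster/cube readers and writers, pipeline configuration and orchestration.

Rasters are stored as TIFF (via :mod:`tifffile`) with georeferencing and
calendar metadata serialized as JSON in the ImageDescription tag, so a
write/read round-trip is bit-exact on values, mask, transform and calendar.
Cubes live either as one multi-page TIFF per index or as a directory of
per-month files named ``<index>_YYYY-MM.tif``. Missing cells are NaN.

``run_pipeline`` chains the full analysis: indices/scene -> ICONA hazard ->
stratified point sample -> per-point breakpoint detection -> pre-break
truncation -> temporal EWS -> spatial tau maps -> validation, emitting all
artifacts plus a machine-readable JSON report. Given fixed seeds the report
is bit-identical across runs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .containers import IconaLayers, IndexCube, MonthlyTimeSeries
from .breakpoints import detect_largest_break, decompose, truncate_pre_break
from .ews import DetrendSpec, ews_suite
from .icona import default_tables, icona_map, load_tables
from .spatial import hotspot_mask, pixel_kendall_map
from .synthetic import ScenarioConfig, SyntheticScene, generate_scene
from .validation import LOW_CLASSES, SEVERE_CLASSES, stratified_sample, validate_map

__all__ = [
    "read_raster",
    "write_raster",
    "read_cube",
    "write_cube",
    "write_scene",
    "PipelineConfig",
    "run_pipeline",
]

_MONTH_FILE = re.compile(r"^(?P<index>[A-Za-z0-9]+)_(?P<year>\d{4})-(?P<month>\d{2})\.tif$")


def write_raster(path, array, transform=(1.0, 0.0, 0.0, 0.0, -1.0, 0.0), crs="", meta=None):
    """Write a single 2-D raster as TIFF with JSON georeferencing metadata."""
    array = np.asarray(array)
    desc = {"transform": list(transform), "crs": crs}
    if meta:
        desc.update(meta)
    tifffile.imwrite(str(path), array, description=json.dumps(desc, sort_keys=True))


def read_raster(path):
    """Read a raster written by :func:`write_raster`; returns (array, meta)."""
    with tifffile.TiffFile(str(path)) as tif:
        array = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    meta.setdefault("transform", [1.0, 0.0, 0.0, 0.0, -1.0, 0.0])
    meta.setdefault("crs", "")
    return array, meta


def write_cube(cube: IndexCube, path) -> None:
    """Write a cube as one multi-page TIFF (``*.tif``) or a per-month directory."""
    path = Path(path)
    values = np.where(cube.mask, np.nan, cube.values)
    if path.suffix == ".tif":
        meta = {
            "transform": list(cube.transform),
            "crs": cube.crs,
            "index_name": cube.index_name,
            "months": [str(p) for p in cube.calendar],
        }
        tifffile.imwrite(str(path), values, photometric="minisblack",
                         description=json.dumps(meta, sort_keys=True))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, period in enumerate(cube.calendar):
            fname = f"{cube.index_name}_{period.year:04d}-{period.month:02d}.tif"
            write_raster(path / fname, values[i], cube.transform, cube.crs,
                         meta={"index_name": cube.index_name})


def read_cube(path, index_name: str | None = None) -> IndexCube:
    """Read a cube from a multi-page TIFF or a ``<index>_YYYY-MM.tif`` directory.

    Validates that the calendar is strictly monthly with no duplicates or
    gaps and that all files agree on CRS and transform.
    """
    path = Path(path)
    if path.is_file():
        with tifffile.TiffFile(str(path)) as tif:
            values = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        months = pd.PeriodIndex(meta["months"], freq="M")
        _validate_calendar(months)
        first = months[0]
        return IndexCube(
            values=values,
            index_name=meta.get("index_name", index_name or ""),
            start=(first.year, first.month),
            transform=tuple(meta["transform"]),
            crs=meta.get("crs", ""),
        )

    entries = []
    for f in sorted(path.iterdir()):
        m = _MONTH_FILE.match(f.name)
        if not m:
            continue
        if index_name is not None and m.group("index").upper() != index_name.upper():
            continue
        entries.append((pd.Period(year=int(m.group("year")), month=int(m.group("month")), freq="M"), f,
                        m.group("index").upper()))
    if not entries:
        raise FileNotFoundError(f"no '<index>_YYYY-MM.tif' files under {path}")
    names = {e[2] for e in entries}
    if len(names) > 1:
        raise ValueError(f"multiple indices in {path} ({sorted(names)}); pass index_name")
    entries.sort(key=lambda e: e[0])
    months = pd.PeriodIndex([e[0] for e in entries], freq="M")
    _validate_calendar(months)

    arrays, metas = zip(*(read_raster(f) for _, f, _ in entries))
    crss = {m["crs"] for m in metas}
    if len(crss) > 1:
        raise ValueError(f"mixed CRS across monthly files: {sorted(crss)}")
    transforms = {tuple(m["transform"]) for m in metas}
    if len(transforms) > 1:
        raise ValueError("mixed geotransforms across monthly files")
    first = months[0]
    return IndexCube(
        values=np.stack(arrays),
        index_name=entries[0][2],
        start=(first.year, first.month),
        transform=tuple(metas[0]["transform"]),
        crs=metas[0]["crs"],
    )


def _validate_calendar(months: pd.PeriodIndex) -> None:
    if months.duplicated().any():
        dup = months[months.duplicated()][0]
        raise ValueError(f"duplicate month {dup} in cube")
    diffs = np.diff(months.asi8)
    if (diffs <= 0).any():
        raise ValueError("cube calendar is not strictly increasing")
    if (diffs != 1).any():
        gap_at = months[int(np.argmax(diffs != 1))]
        raise ValueError(f"cube calendar has a gap after {gap_at}")


def write_scene(scene: SyntheticScene, out_dir) -> None:
    """Write a synthetic scene: per-index cube dirs, ancillary rasters, truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, cube in scene.index_cubes.items():
        write_cube(cube, out / name.lower())
    lyr = scene.layers
    write_raster(out / "slope_pct.tif", lyr.slope_pct, lyr.transform, lyr.crs)
    write_raster(out / "litho_class.tif", lyr.litho_class, lyr.transform, lyr.crs)
    write_raster(out / "landuse_class.tif", lyr.landuse_class, lyr.transform, lyr.crs)
    write_raster(out / "cover_pct.tif", lyr.cover_pct, lyr.transform, lyr.crs)
    rows, cols = np.indices(scene.truth_labels.shape)
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "eroded": scene.truth_labels.ravel().astype(int),
            "break_month": scene.truth_break_month.ravel(),
        }
    ).to_csv(out / "truth_labels.csv", index=False)


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    In synthetic mode (default) a scene is generated from ``scenario``;
    in real mode ``cube_paths`` (index name -> path) and ``layer_paths``
    (slope/litho/landuse/cover -> path) point at existing rasters and
    ``expert_path`` at an expert-class raster for validation.
    """

    scenario: ScenarioConfig | None = None
    cube_paths: dict | None = None
    layer_paths: dict | None = None
    expert_path: str | None = None
    indices: tuple = ("NDVI", "NDSI", "TGSI")
    break_confidence: float = 0.95
    exclusion_months: int = 24
    min_segment: int = 12
    n_boot: int = 199
    detrend_method: str = "gaussian_kernel"
    detrend_bandwidth: float = 0.1
    window_frac: float = 0.5
    n_validation_points: int = 100
    sampling_seed: int = 0
    tau_threshold: float = 0.5
    icona_tables_path: str | None = None
    out_dir: str = "soilews_out"

    def to_dict(self) -> dict:
        """JSON/YAML-safe dict (tuples become lists); round-trips via from_yaml."""
        return _jsonable(asdict(self))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            if "start" in sc:
                sc["start"] = tuple(sc["start"])
            raw["scenario"] = ScenarioConfig(**sc)
        if "indices" in raw:
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        scene = generate_scene(config.scenario)
        cubes = {k: v for k, v in scene.index_cubes.items() if k in config.indices}
        expert = np.where(scene.truth_labels, 5, 1)
        return cubes, scene.layers, expert
    if not config.cube_paths or not config.layer_paths:
        raise ValueError("real mode needs cube_paths and layer_paths")
    cubes = {name.upper(): read_cube(p, name) for name, p in config.cube_paths.items()}
    arrays = {}
    for key in ("slope", "litho", "landuse", "cover"):
        arr, meta = read_raster(config.layer_paths[key])
        arrays[key] = (arr, meta)
    layers = IconaLayers(
        slope_pct=arrays["slope"][0],
        litho_class=arrays["litho"][0],
        landuse_class=arrays["landuse"][0],
        cover_pct=arrays["cover"][0],
        transform=tuple(arrays["slope"][1]["transform"]),
        crs=arrays["slope"][1]["crs"],
    )
    expert = None
    if config.expert_path:
        expert, _ = read_raster(config.expert_path)
    return cubes, layers, expert


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serializable report.

    Artifacts (hazard raster, class-area CSV, per-point CSVs, tau rasters,
    ``report.json``) are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = load_tables(config.icona_tables_path) if config.icona_tables_path else default_tables()
    cubes, layers, expert = _load_inputs(config)
    if not cubes:
        raise ValueError("pipeline stage 'indices': no index cubes selected")

    report: dict = {
        "meta": {
            "soilews_version": __version__,
            "config": _jsonable(config.to_dict()),
            "icona_tables_hash": tables.content_hash(),
        }
    }

    # indices stage: cube inventory
    report["indices"] = {
        name: {"n_months": cube.n_months, "shape": list(cube.shape)}
        for name, cube in sorted(cubes.items())
    }

    # icona stage
    icona = icona_map(layers, tables)
    write_raster(out / "hazard.tif", icona.hazard, layers.transform, layers.crs)
    icona.class_areas.to_csv(out / "hazard_class_areas.csv", index=False)
    report["icona"] = {
        "class_areas_percent": {
            str(int(r.hazard_class)): round(float(r.percent), 6)
            for r in icona.class_areas.itertuples()
        },
        "tables_hash": icona.tables_hash,
    }

    # sampling stage
    points = stratified_sample(
        icona.hazard, n_total=config.n_validation_points,
        seed=config.sampling_seed, mask=icona.mask,
    )
    report["sampling"] = {
        "n_points": len(points),
        "n_severe": sum(1 for p in points if p.stratum == "severe"),
        "n_low": sum(1 for p in points if p.stratum == "low"),
        "severe_classes": list(SEVERE_CLASSES),
        "low_classes": list(LOW_CLASSES),
    }

    # breakpoint + EWS stages, per index per sampled point
    spec = DetrendSpec(config.detrend_method, config.detrend_bandwidth)
    break_rows, ews_rows = [], []
    rng = np.random.default_rng(config.sampling_seed)
    for name, cube in sorted(cubes.items()):
        for pt in points:
            series = cube.pixel(pt.row, pt.col)
            boot_seed = int(rng.integers(2**31))
            try:
                res = detect_largest_break(
                    series, min_segment=config.min_segment,
                    confidence=config.break_confidence,
                    n_boot=config.n_boot, seed=boot_seed,
                )
            except ValueError:
                res = None
            row = {
                "index": name, "row": pt.row, "col": pt.col, "stratum": pt.stratum,
                "significant": bool(res is not None),
                "break_month": res.break_month if res else "",
                "break_year": res.break_year if res else "",
                "magnitude": res.magnitude if res else "",
                "p_value": res.p_value if res else "",
            }
            break_rows.append(row)

            try:
                if res is not None:
                    sub = truncate_pre_break(series, res, config.exclusion_months)
                else:
                    sub = series
                _, seasonal, _ = decompose(sub)
                deseasoned = MonthlyTimeSeries(sub.values - seasonal, start=sub.start)
                ews = ews_suite(deseasoned, spec, config.window_frac)
                for ind, (tau, p) in sorted(ews.taus.items()):
                    ews_rows.append(
                        {
                            "index": name, "row": pt.row, "col": pt.col,
                            "stratum": pt.stratum, "indicator": ind,
                            "tau": tau, "p": p,
                            "n_months_used": sub.n, "window_len": ews.window_len,
                        }
                    )
            except ValueError:
                continue

    breaks_df = pd.DataFrame(break_rows)
    breaks_df.to_csv(out / "breakpoints.csv", index=False)
    ews_df = pd.DataFrame(ews_rows)
    ews_df.to_csv(out / "ews_taus.csv", index=False)

    report["breakpoints"] = {}
    for name, grp in breaks_df.groupby("index"):
        sig = grp[grp["significant"]]
        months = pd.to_numeric(sig["break_month"], errors="coerce").dropna()
        report["breakpoints"][name] = {
            "n_points": int(len(grp)),
            "n_significant": int(len(sig)),
            "median_break_month": float(months.median()) if len(months) else None,
        }

    report["ews"] = {}
    if len(ews_df):
        for (name, ind), grp in ews_df.groupby(["index", "indicator"]):
            entry = {}
            for stratum, sgrp in grp.groupby("stratum"):
                entry[stratum] = {
                    "median_tau": round(float(sgrp["tau"].median()), 6),
                    "n_points": int(len(sgrp)),
                }
            report["ews"].setdefault(name, {})[ind] = entry

    # spatial stage
    report["spatial"] = {}
    for name, cube in sorted(cubes.items()):
        tau_map = pixel_kendall_map(cube)
        hot = hotspot_mask(tau_map, threshold=config.tau_threshold)
        write_raster(out / f"tau_{name.lower()}.tif", tau_map.tau, cube.transform, cube.crs)
        write_raster(out / f"hotspots_{name.lower()}.tif", hot.astype(np.uint8),
                     cube.transform, cube.crs)
        summary = tau_map.summary()
        summary["hotspot_fraction"] = round(float(hot.mean()), 6)
        summary["mean_abs_tau"] = round(summary["mean_abs_tau"], 6)
        summary["median_abs_tau"] = round(summary["median_abs_tau"], 6)
        summary["max_abs_tau"] = round(summary["max_abs_tau"], 6)
        report["spatial"][name] = summary

    # validation stage
    if expert is not None:
        val = validate_map(
            icona.hazard, expert, n_total=config.n_validation_points,
            seed=config.sampling_seed, mask=icona.mask,
        )
        val["points"].to_csv(out / "validation_points.csv", index=False)
        report["validation"] = {
            "U": val["U"], "p": round(val["p"], 6),
            "mean_agreement": round(val["mean_agreement"], 6),
        }
    else:
        report["validation"] = {"skipped": "no expert raster provided"}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
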