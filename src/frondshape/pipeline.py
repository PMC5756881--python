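"""End-to-end orchestration: images -> outlines -> measures -> statistics.

``run_measure`` turns a directory of single-frond photographs into a
measurements CSV (one row per image, failed extractions flagged as
excluded rather than dropped, so the exclusion analysis stays a
first-class output).  ``run_analysis`` runs the two-stage model selection
for every response plus the exclusion logistic, writing Table-style model
CSVs, prediction curves with confidence bands, and residual diagnostics.
Every run writes a JSON manifest (config, content hashes) so identical
inputs give byte-identical, auditable outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics, stats
from .csm import csm as compute_csm
from .csm import csm_forced as compute_csm_forced
from .io import read_image
from .outline import extract_outline, normalize

MEASURE_COLUMNS = [
    "frond_id", "csm", "csm_forced", "axis_angle",
    "area_mm2", "perimeter_mm", "circularity", "area_px",
    "excluded", "error",
]


@dataclass
class RunConfig:
    """Pipeline configuration; ``reference_points`` must be even >= 4 and
    the calibration positive when absolute units are wanted."""

    image_dir: str | Path | None = None
    cohort_csv: str | Path | None = None
    metadata_csv: str | Path | None = None
    out_dir: str | Path = "frondshape_out"
    reference_points: int = 200
    calibration_mm_per_px: float | None = None
    seed: int = 0
    responses: tuple[str, ...] = tuple(stats.RESPONSE_TRANSFORMS)
    age_grid: tuple[float, ...] | None = None
    run_stats: bool = True

    def __post_init__(self) -> None:
        if self.reference_points % 2 or self.reference_points < 4:
            raise ValueError("reference_points must be even and >= 4")
        if self.calibration_mm_per_px is not None and not self.calibration_mm_per_px > 0:
            raise ValueError("calibration must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: dict, files: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "config": config,
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def measure_image(image: np.ndarray, L: int = 200, calibration: float | None = None) -> dict:
    """All measures for one image: symmetry (CSM, CSM_forced, axis angle) on
    the normalized outline, size (area, perimeter, circularity) on the
    pre-normalized one."""
    poly, info = extract_outline(image, L=L, calibration=calibration)
    sizes = morphometrics.measure(poly)
    norm = normalize(poly)
    r = compute_csm(norm)
    rf = compute_csm_forced(norm)
    mask_px = info["foreground_pixels"]
    cal = calibration if calibration is not None else 1.0
    return {
        "csm": r.csm,
        "csm_forced": rf.csm,
        "axis_angle": r.best_axis.angle,
        "area_mm2": sizes.area,
        "perimeter_mm": sizes.perimeter,
        "circularity": sizes.circularity,
        "area_px": mask_px * cal * cal,
        "excluded": False,
        "error": "",
        **{f"log_{k}": v for k, v in info.items()},
    }


def run_measure(config: RunConfig) -> Path:
    """Measure every image in ``config.image_dir``; returns the path of the
    written measurements CSV.  Unreadable or unsegmentable images yield
    flagged excluded rows and the run continues."""
    image_dir = Path(config.image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images in {image_dir}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in paths:
        row = {"frond_id": p.stem}
        try:
            img = read_image(p)
            row.update(measure_image(img, config.reference_points, config.calibration_mm_per_px))
        except Exception as exc:  # one bad image must not kill the run
            row.update({c: np.nan for c in MEASURE_COLUMNS if c not in ("frond_id", "excluded", "error")})
            row["excluded"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    if config.metadata_csv is not None:
        meta = pd.read_csv(config.metadata_csv)
        df = meta.merge(df, on="frond_id", how="left")
        if "excluded_x" in df.columns:  # metadata exclusion flag wins when set
            df["excluded"] = df.pop("excluded_x").fillna(False) | df.pop("excluded_y").fillna(True)
    csv_path = out_dir / "measurements.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    _write_manifest(out_dir, "measure", _config_dict(config), [csv_path])
    return csv_path


def run_analysis(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Two-stage model selection for every response plus the exclusion
    logistic; writes model tables, prediction curves and diagnostics under
    ``config.out_dir`` and returns the in-memory results."""
    if cohort is None:
        cohort = pd.read_csv(config.cohort_csv)
    required = {"parent_id", "parental_age_days", "shelf", "excluded"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing column(s): {sorted(missing)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}
    n_shelves = int(cohort["shelf"].nunique())
    if config.age_grid is not None:
        grid = np.asarray(config.age_grid, dtype=float)
    else:
        ages = cohort["parental_age_days"]
        grid = np.arange(float(ages.min()), float(ages.max()) + 1)
    for response in config.responses:
        if response not in cohort.columns:
            raise ValueError(f"cohort table is missing column(s): ['{response}']")
        res = stats.analyze_response(cohort, response, n_shelves=n_shelves)
        tbl_path = out_dir / f"model_table_{response}.csv"
        res["table"].to_csv(tbl_path, index=False, float_format="%.6g")
        written.append(tbl_path)
        curve = stats.predict_with_bands(res["best_fit"], grid)
        curve_path = out_dir / f"prediction_{response}.csv"
        curve.to_csv(curve_path, index=False, float_format="%.6g")
        written.append(curve_path)
        res["diagnostics"] = stats.residual_diagnostics(res["best_fit"], out_dir, response)
        res["curve"] = curve
        results[response] = res
    excl = stats.fit_exclusion(cohort, grid=grid)
    excl_tbl = out_dir / "model_table_exclusion.csv"
    excl["table"].to_csv(excl_tbl, index=False, float_format="%.6g")
    excl_curve = out_dir / "prediction_exclusion.csv"
    excl["curve"].to_csv(excl_curve, index=False, float_format="%.6g")
    written += [excl_tbl, excl_curve]
    results["exclusion"] = excl
    _write_manifest(out_dir, "analysis", _config_dict(config), written)
    return results


def _config_dict(config: RunConfig) -> dict:
    return {k: v for k, v in config.__dict__.items()}
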