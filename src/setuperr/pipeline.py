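"""End-to-end registration pipeline and batch evaluation.

``run_pipeline`` takes the four image paths (frontal/lateral DR captures
and their DRRs) plus a config and produces a ``RunReport``:
overlay detection -> inpainting -> Sobel/collimator masking -> weighted
ZNCC best match per view -> couch-space error.  ``batch_evaluate`` applies
it over a manifest of couch positions and writes a pattern table plus a
summary with the aggregate conventions of the accuracy experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import MatchConfig, load_config
from .geometry import (
    CouchShift,
    aggregate_pattern,
    couch_error,
)
from .io import RunReport, file_sha256, read_captured
from .matcher import best_match
from .preprocess import preprocess_captured
from .types import (
    CapturedImage,
    Displacement,
    ImageIOError,
    MatchError,
    ReferenceDisplacement,
)

__all__ = ["run_pipeline", "batch_evaluate"]


def _register_view(
    dr_path: str | Path,
    drr_path: str | Path,
    view: str,
    cfg: MatchConfig,
    isocenter_px: tuple[float, float] | None,
    warnings: list[str],
) -> tuple[Displacement, dict[str, Any]]:
    ic = isocenter_px
    probe = read_captured(dr_path, view, cfg.pixel_spacing_mm, (0, 0))  # type: ignore[arg-type]
    if ic is None:
        h, w = probe.pixels.shape[:2]
        ic = ((w - 1) / 2.0, (h - 1) / 2.0)
    dr_cap = CapturedImage(probe.pixels, view, cfg.pixel_spacing_mm, ic)  # type: ignore[arg-type]
    drr_cap = read_captured(drr_path, view, cfg.pixel_spacing_mm, ic)  # type: ignore[arg-type]

    prep_dr = preprocess_captured(dr_cap, cfg)
    prep_drr = preprocess_captured(drr_cap, cfg) if drr_cap.channels == 3 else None
    drr_rad = prep_drr.radiograph if prep_drr else _as_radiograph(drr_cap)

    disp = best_match(prep_dr.radiograph, drr_rad, cfg, valid=prep_dr.valid_mask)
    window_px = cfg.N * cfg.N
    if disp.n_valid_px < 0.25 * window_px:
        warnings.append(f"{view}: low valid-pixel count ({disp.n_valid_px}/{window_px})")
    if disp.at_search_border:
        warnings.append(f"{view}: correlation peak at the search-window border")
    dx_mm, dy_mm = disp.to_mm(cfg.pixel_spacing_mm)
    detail = {
        "dx_px": disp.dx_px,
        "dy_px": disp.dy_px,
        "dx_mm": dx_mm,
        "dy_mm": dy_mm,
        "peak_correlation": disp.peak_correlation,
        "n_valid_pixels": disp.n_valid_px,
        "at_search_border": disp.at_search_border,
    }
    return disp, detail


def _as_radiograph(cap: CapturedImage):
    from .types import Radiograph

    return Radiograph(cap.to_gray(), cap.view, cap.pixel_spacing_mm, cap.isocenter_px)


def run_pipeline(
    frontal_path: str | Path,
    lateral_path: str | Path,
    frontal_drr_path: str | Path,
    lateral_drr_path: str | Path,
    config_path: str | Path | None = None,
    *,
    cfg: MatchConfig | None = None,
    couch: CouchShift | None = None,
    reference: ReferenceDisplacement | None = None,
    isocenter_px: tuple[float, float] | None = None,
) -> RunReport:
    """Full frontal+lateral registration of one captured pair.

    With no couch shift and no reference the reported couch-space error is
    simply the residual displacement mapped onto the couch axes (reference
    and movement both zero).  Inputs are never mutated.
    """
    if cfg is None:
        cfg = load_config(config_path)
    warnings: list[str] = []
    f_disp, f_detail = _register_view(
        frontal_path, frontal_drr_path, "frontal", cfg, isocenter_px, warnings
    )
    l_disp, l_detail = _register_view(
        lateral_path, lateral_drr_path, "lateral", cfg, isocenter_px, warnings
    )
    couch = couch or CouchShift(0.0, 0.0, 0.0, label="")
    if reference is None:
        zero_f = Displacement(0.0, 0.0, 1.0, "frontal")
        zero_l = Displacement(0.0, 0.0, 1.0, "lateral")
        reference = ReferenceDisplacement(zero_f, zero_l)
    err = couch_error(
        reference,
        ReferenceDisplacement(f_disp, l_disp),
        couch,
        cfg.pixel_spacing_mm,
    )
    return RunReport(
        frontal=f_detail,
        lateral=l_detail,
        error_mm={
            "lat": err.e_lat_mm,
            "vert": err.e_vert_mm,
            "long": err.e_long_mm,
            "rmse": err.rmse_mm,
        },
        config=cfg.to_dict(),
        inputs={
            "frontal_dr": file_sha256(frontal_path),
            "lateral_dr": file_sha256(lateral_path),
            "frontal_drr": file_sha256(frontal_drr_path),
            "lateral_drr": file_sha256(lateral_drr_path),
        },
        warnings=warnings,
    )


_MANIFEST_COLS = [
    "label",
    "lat_mm",
    "vert_mm",
    "long_mm",
    "frontal_dr",
    "lateral_dr",
    "frontal_drr",
    "lateral_drr",
]


def batch_evaluate(
    manifest_csv: str | Path,
    cfg: MatchConfig,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Evaluate a manifest of couch positions into a pattern table.

    The manifest needs columns ``label, lat_mm, vert_mm, long_mm`` and the
    four image paths per row (relative paths resolve against the manifest
    directory).  The row labeled ``0`` is the reference registration.
    Failing rows are recorded and skipped; the run continues.  Returns the
    per-position table (plus a Total row) and a JSON-ready summary.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv, dtype={"label": str})
    if df.empty:
        raise ValueError("empty manifest")
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    base = manifest_csv.parent

    def _paths(row) -> dict[str, Path]:
        return {k: base / row[k] for k in ("frontal_dr", "lateral_dr", "frontal_drr", "lateral_drr")}

    ref_rows = df[df["label"] == "0"]
    if ref_rows.empty:
        raise ValueError("manifest must contain a reference row with label '0'")
    ref_row = ref_rows.iloc[0]
    p = _paths(ref_row)
    ref_report = run_pipeline(
        p["frontal_dr"], p["lateral_dr"], p["frontal_drr"], p["lateral_drr"], cfg=cfg
    )
    reference = ReferenceDisplacement(
        Displacement(ref_report.frontal["dx_px"], ref_report.frontal["dy_px"],
                     ref_report.frontal["peak_correlation"], "frontal"),
        Displacement(ref_report.lateral["dx_px"], ref_report.lateral["dy_px"],
                     ref_report.lateral["peak_correlation"], "lateral"),
    )

    records: list[dict[str, Any]] = []
    errors = []
    failures: list[dict[str, str]] = []
    for _, row in df[df["label"] != "0"].iterrows():
        couch = CouchShift(row["lat_mm"], row["vert_mm"], row["long_mm"], label=str(row["label"]))
        p = _paths(row)
        try:
            rep = run_pipeline(
                p["frontal_dr"], p["lateral_dr"], p["frontal_drr"], p["lateral_drr"],
                cfg=cfg, couch=couch, reference=reference,
            )
        except (ImageIOError, MatchError, ValueError) as exc:
            failures.append({"label": str(row["label"]), "error": str(exc)})
            continue
        e = rep.error_mm
        errors.append(e)
        records.append(
            {
                "label": row["label"],
                "setup_lat_mm": couch.lat_mm,
                "setup_vert_mm": couch.vert_mm,
                "setup_long_mm": couch.long_mm,
                "e_lat_mm": e["lat"],
                "e_vert_mm": e["vert"],
                "e_long_mm": e["long"],
                "rmse_mm": e["rmse"],
                "warnings": "; ".join(rep.warnings),
            }
        )
    if not records:
        raise MatchError("every manifest row failed")

    from .geometry import PositioningError

    perrs = [
        PositioningError.from_axes(r["e_lat_mm"], r["e_vert_mm"], r["e_long_mm"], str(r["label"]))
        for r in records
    ]
    summary_stats = aggregate_pattern(perrs)
    table = pd.DataFrame.from_records(records)
    total = {
        "label": "Total",
        "e_lat_mm": summary_stats.mean_lat_mm,
        "e_vert_mm": summary_stats.mean_vert_mm,
        "e_long_mm": summary_stats.mean_long_mm,
        "rmse_mm": summary_stats.mean_rmse_mm,
    }
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    summary = {
        "n_positions": summary_stats.n,
        "mean_rmse_mm": summary_stats.mean_rmse_mm,
        "sd_rmse_mm": summary_stats.sd_rmse_mm,
        "mean_lat_mm": summary_stats.mean_lat_mm,
        "sd_lat_mm": summary_stats.sd_lat_mm,
        "mean_vert_mm": summary_stats.mean_vert_mm,
        "sd_vert_mm": summary_stats.sd_vert_mm,
        "mean_long_mm": summary_stats.mean_long_mm,
        "sd_long_mm": summary_stats.sd_long_mm,
        "failures": failures,
    }
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table, summary
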