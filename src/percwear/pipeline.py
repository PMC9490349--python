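"""End-to-end pipeline driver: surfaces in, CSV report bundle out.

A run reads every surface scan in the input directory (PLY/OBJ/XYZ),
orients each tool, detects and measures pits, summarises each active
surface, and — when tool metadata with a ``tool_type`` column is present —
compares the hammer and anvil groups.  All effective parameter values and
any row exclusions are logged, and identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage_stats, pit_morphometry, planform, surface_io
from .errors import ParameterError, PercwearError

log = logging.getLogger("percwear")

SURFACE_SUFFIXES = (".ply", ".obj", ".xyz")


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run (lengths in mm)."""

    input_dir: str = "."
    output_dir: str = "percwear_out"
    tpi_radius: float = 20.0
    roughness_window: float = 0.5
    gradient_fit_radius: float = 2.0
    min_pit_length: float = 10.0
    depression_threshold: float | str = "auto"
    outline_alpha: float | str = "auto"
    pit_alpha: float | str = "auto"
    alpha_level: float = 0.05
    seed: int = 0
    adaptive_windows: bool = True     # widen windows on sparse scans
    metadata_csv: str | None = None   # per-tool table with tool_type column

    def validate(self) -> None:
        for name in ("tpi_radius", "roughness_window", "gradient_fit_radius",
                     "min_pit_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.alpha_level < 1:
            raise ParameterError("alpha_level must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _auto(value, fallback):
    return fallback if value == "auto" else value


def analyse_surface(model: surface_io.OrientedSurfaceModel,
                    config: PipelineConfig,
                    ) -> tuple[list[pit_morphometry.PitRegion],
                               planform.PlanformSummary]:
    """Detect, measure and summarise pits on one oriented model's plane A."""
    spacing = model.median_point_spacing("A")
    rough_w = config.roughness_window
    grad_r = config.gradient_fit_radius
    if config.adaptive_windows:
        rough_w = max(rough_w, 2.5 * spacing)
        grad_r = max(grad_r, 2.5 * spacing)
    hull = surface_io.compute_convex_hull(model)
    tpi = pit_morphometry.compute_tpi(model, radius=config.tpi_radius)
    thr = None if config.depression_threshold == "auto" \
        else float(config.depression_threshold)
    regions = pit_morphometry.detect_pit_regions(
        tpi, model, threshold=thr, min_length=config.min_pit_length)
    pit_morphometry.measure_regions(regions, model, hull,
                                    fit_radius=grad_r,
                                    roughness_window=rough_w)
    summary = planform.summarize_plane(
        model, regions,
        outline_alpha=_auto(config.outline_alpha, None),
        pit_alpha=_auto(config.pit_alpha, None))
    return regions, summary


def _configure_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full workflow over a directory of surface scans.

    Writes ``pits.csv`` (one row per pit), ``surfaces.csv`` (one row per
    active surface), optionally ``comparison.csv``/``pca_scores.csv`` (when
    metadata splits the tools into two groups), and ``pipeline.log``.
    Returns the paths keyed by artefact name.
    """
    config.validate()
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise IOError(f"input directory not found: {in_dir}")
    paths = sorted(p for p in in_dir.iterdir()
                   if p.suffix.lower() in SURFACE_SUFFIXES)
    if not paths:
        raise IOError(f"no PLY/OBJ/XYZ surfaces in {in_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _configure_log(out_dir)
    try:
        log.info("config: %s", {f.name: getattr(config, f.name)
                                for f in fields(config)})
        pit_rows, surf_rows = [], []
        for path in paths:
            try:
                model = surface_io.read_surface(path)
                if not model.oriented:
                    model = surface_io.orient_model(model)
                regions, summary = analyse_surface(model, config)
            except PercwearError as exc:
                raise PercwearError(
                    f"stage failure on tool {path.stem!r}: {exc}") from exc
            log.info("tool %s: %d pits, PA=%.2f%%", model.tool_id,
                     summary.n_pits, summary.pa_percent)
            for r in regions:
                pit_rows.append({
                    "tool_id": r.tool_id, "plane": r.plane,
                    "pit_id": r.pit_id, "area_cm2": r.area_cm2,
                    "length_mm": r.length_mm, "width_mm": r.width_mm,
                    "depth_mm": r.depth_mm, "depth_max_mm": r.depth_max_mm,
                    "gradient": r.gradient, "roughness_mm": r.roughness_mm,
                    "dac_mm": r.dac_mm, "dae_mm": r.dae_mm})
            surf_rows.append({
                "tool_id": summary.tool_id, "plane": summary.plane,
                "n_use_wear": summary.n_pits,
                "surface_area_cm2": summary.surface_area_cm2,
                "pa_percent": summary.pa_percent,
                "density_per_cm2": summary.density_per_cm2,
                "dac_min_mm": summary.dac_min_mm,
                "dac_mean_mm": summary.dac_mean_mm,
                "dac_max_mm": summary.dac_max_mm,
                "dae_min_mm": summary.dae_min_mm,
                "dae_mean_mm": summary.dae_mean_mm,
                "dae_max_mm": summary.dae_max_mm})
        pits = pd.DataFrame(pit_rows, columns=[
            "tool_id", "plane", "pit_id", "area_cm2", "length_mm",
            "width_mm", "depth_mm", "depth_max_mm", "gradient",
            "roughness_mm", "dac_mm", "dae_mm"])
        surfaces = pd.DataFrame(surf_rows)
        outputs = {"pits": out_dir / "pits.csv",
                   "surfaces": out_dir / "surfaces.csv",
                   "log": out_dir / "pipeline.log"}
        pits.to_csv(outputs["pits"], index=False)
        surfaces.to_csv(outputs["surfaces"], index=False)

        if config.metadata_csv:
            meta = pd.read_csv(config.metadata_csv)
            merged = surfaces.merge(meta[["tool_id", "tool_type"]],
                                    on="tool_id", how="left")
            dropped = int(merged.tool_type.isna().sum())
            if dropped:
                log.info("excluded %d surfaces without metadata", dropped)
            merged = merged.dropna(subset=["tool_type"])
            types = sorted(merged.tool_type.unique())
            if len(types) == 2:
                a = merged[merged.tool_type == types[0]]
                b = merged[merged.tool_type == types[1]]
                try:
                    results, pca = assemblage_stats.compare_assemblages(
                        a, b, label_a=types[0], label_b=types[1])
                except PercwearError as exc:
                    log.info("group comparison skipped: %s", exc)
                else:
                    rep = assemblage_stats.comparison_report(results)
                    outputs["comparison"] = out_dir / "comparison.csv"
                    rep.to_csv(outputs["comparison"], index=False)
                    sc = pd.DataFrame(
                        pca.scores[:, :2], columns=["PC1", "PC2"])
                    sc["group"] = pca.labels
                    outputs["pca_scores"] = out_dir / "pca_scores.csv"
                    sc.to_csv(outputs["pca_scores"], index=False)
                    log.info("PC1+PC2 variance: %.2f%%",
                             pca.percent_variance[:2].sum())
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()


def main_cli_entry(config_path: str, **overrides) -> dict[str, Path]:
    config = PipelineConfig.from_toml(config_path, **overrides)
    return run_pipeline(config)
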