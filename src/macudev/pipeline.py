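"""End-to-end orchestration: simulate -> classify -> render -> parse ->
annulus/Hough -> extents -> sectors -> statistics.

A run is fully described by a :class:`RunConfig`; the SHA-256 hash of its
canonical JSON form, together with the seed, is recorded in the header of
every CSV the run emits, so any table can be traced to the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AnnulusSpec, DeviationMap, RasterGeometry
from .devmap import (
    HoughConfig,
    extent_summary,
    fit_annulus,
    parse_colors,
    remove_overlay_lines,
)
from .normative import compose_gcipl, default_gcl_model, default_ipl_model
from .sectors import (
    SectorMap,
    ThicknessGrid,
    default_sector_map,
    gcipl_grid,
    global_mean,
    mirror_grid,
    sector_means,
    write_grid_csv,
)
from .simulate import (
    CohortSpec,
    SimulatedEye,
    cohort_manifest,
    desk_geometry,
    render_deviation_map,
    save_png,
    sector_line_segments,
    simulate_cohort,
)
from .stats import cohort_tables
from . import normative

log = logging.getLogger("macudev")

__all__ = ["RunConfig", "run_pipeline", "write_table"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    raster_px: int = 64
    n_normal: int = 20
    n_suspect: int = 0
    n_glaucoma: int = 20
    glaucoma_median_um: float = 10.0
    suspect_median_um: float = 3.0
    noise_sd_scale: float = 1.0
    eye_offset_sd: float = 2.0
    rho: float = 0.5
    denominator: str = "exclude"   # 'exclude' drops overlay pixels, 'raw' keeps them
    cumulative_extents: bool = False
    fit_annulus_from_image: bool = True
    draw_sector_lines: bool = True
    parse_tolerance: int = 10
    hough: dict = field(default_factory=lambda: asdict(HoughConfig()))
    sector_map_csv: str | None = None
    save_maps: bool = False
    out_dir: str = "macudev_run"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """Write a CSV with a commented run-metadata header."""
    header = (
        f"# macudev run config_hash={config.hash()} seed={config.seed}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-10s %.2fs", name, t1 - t0)
    return t1


def eye_features(
    eye: SimulatedEye,
    models: dict,
    config: RunConfig,
    annulus_prior: AnnulusSpec,
    sector_map,
    maps_dir: Path | None,
) -> dict:
    """All per-eye scalar features: sector/global means and extents."""
    feats: dict = {"eye_id": eye.eye_id, "group": eye.spec.group,
                   "laterality": eye.spec.laterality}
    # --- grid measures (analysis in OD orientation; grids already OD) ---
    grids = {"gcl": eye.grid_gcl, "gcipl": gcipl_grid(eye.grid_gcl, eye.grid_ipl)}
    for lay, grid in grids.items():
        for sector, value in sector_means(grid, sector_map).items():
            feats[f"{lay}_{sector}"] = value
        feats[f"{lay}_global"] = global_mean(grid)
    # --- deviation-map measures -----------------------------------------
    geometry = models["gcl"].geometry
    hough = HoughConfig(**config.hough)
    for lay in ("gcl", "gcipl"):
        if lay == "gcl":
            thickness = eye.thickness_gcl
        else:
            thickness = eye.thickness_gcl + eye.thickness_ipl
        if eye.spec.laterality == "OS":  # analyze in right-eye orientation
            thickness = thickness[:, ::-1]
        devmap = normative.classify_thickness(models[lay], thickness)
        lines = (
            sector_line_segments(annulus_prior, geometry)
            if config.draw_sector_lines
            else None
        )
        image = render_deviation_map(devmap, annulus=annulus_prior, sector_lines=lines)
        if maps_dir is not None:
            save_png(image, maps_dir / f"{eye.eye_id}_{lay}.png")
        parsed = parse_colors(image, tolerance=config.parse_tolerance, geometry=geometry)
        if config.fit_annulus_from_image:
            annulus = fit_annulus(image, annulus_prior, geometry, hough=hough)
        else:
            annulus = annulus_prior
        cleaned = remove_overlay_lines(parsed, hough)
        for region, tag in ((annulus, "ellipse"), ("ENTIRE_SCAN", "scan")):
            summ = extent_summary(
                cleaned,
                region,
                denominator=config.denominator,
                cumulative=config.cumulative_extents,
            )
            for key, pct in summ.pct.items():
                feats[f"{lay}_{tag}_{key}_pct"] = pct
            feats[f"{lay}_{tag}_n_total_px"] = summ.n_total_px
            feats[f"{lay}_{tag}_n_excluded_px"] = summ.n_excluded_px
    return feats


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic study and write the output bundle.

    Emits under ``config.out_dir``: the cohort manifest, the per-eye
    feature table, per-eye grid CSVs, optionally rendered PNG maps, and
    the three summary tables.  Identical config + seed reproduce the
    bundle exactly.  Returns the tables and feature frame in memory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    geometry = desk_geometry(config.raster_px)
    model_gcl = default_gcl_model(geometry)
    model_ipl = default_ipl_model(geometry)
    models = {
        "gcl": model_gcl,
        "ipl": model_ipl,
        "gcipl": compose_gcipl(model_gcl, model_ipl, rho=config.rho),
    }
    annulus_prior = AnnulusSpec(center_px=geometry.fovea_px)
    sector_map = (
        default_sector_map()
        if config.sector_map_csv is None
        else SectorMap.from_csv(config.sector_map_csv)
    )
    cohort_spec = CohortSpec(
        glaucoma_median_um=config.glaucoma_median_um,
        suspect_median_um=config.suspect_median_um,
        noise_sd_scale=config.noise_sd_scale,
        eye_offset_sd=config.eye_offset_sd,
        rho=config.rho,
    )
    t0 = _stage("setup", t0)

    eyes = simulate_cohort(
        model_gcl,
        model_ipl,
        {"NORMAL": config.n_normal, "SUSPECT": config.n_suspect,
         "GLAUCOMA": config.n_glaucoma},
        cohort_spec,
        seed=config.seed,
    )
    manifest = cohort_manifest(eyes)
    write_table(manifest, out / "manifest.csv", config)
    t0 = _stage("simulate", t0)

    grids_dir = out / "grids"
    grids_dir.mkdir(exist_ok=True)
    maps_dir = None
    if config.save_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)

    rows = []
    for eye in eyes:
        try:
            rows.append(
                eye_features(eye, models, config, annulus_prior, sector_map, maps_dir)
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at feature extraction for eye {eye.eye_id}: {exc}"
            ) from exc
        write_grid_csv(eye.grid_gcl, grids_dir / f"{eye.eye_id}_gcl.csv")
        write_grid_csv(eye.grid_ipl, grids_dir / f"{eye.eye_id}_ipl.csv")
    features = pd.DataFrame(rows)
    write_table(features, out / "features.csv", config)
    t0 = _stage("features", t0)

    control_groups = ("NORMAL", "SUSPECT") if config.n_suspect else ("NORMAL",)
    tables = cohort_tables(features, control_groups=control_groups)
    for name, df in tables.items():
        write_table(df, out / f"{name}.csv", config)
    _stage("stats", t0)
    return {"manifest": manifest, "features": features, **tables}
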