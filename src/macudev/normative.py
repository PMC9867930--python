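"""Normative thickness model and percentile classification.

The commercial deviation map compares each pixel of a macular layer
thickness raster with a normative database and flags it by percentile
category.  This module represents the normative database as per-pixel
Gaussian distributions (mean and SD surfaces on the scan raster) and
derives the percentile cutoffs as ``mean + z * SD`` with the standard
normal quantiles ``z`` for 1%, 5%, 95% and 99%.

A composed GCIPL model is built from GCL and IPL models: means add
exactly; SDs combine as correlated sums,
``SD_gcipl = sqrt(SD_gcl^2 + SD_ipl^2 + 2*rho*SD_gcl*SD_ipl)``
with a configurable inter-layer correlation ``rho`` (the two layers are
anatomically coupled, so independence would understate the combined
variance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
import tifffile
from scipy import stats

from .core import MISSING, DeviationCategory, DeviationMap, RasterGeometry

__all__ = [
    "Z_01",
    "Z_05",
    "RadialSurface",
    "NormativeModel",
    "build_normative",
    "compose_gcipl",
    "classify_thickness",
    "default_gcl_model",
    "default_ipl_model",
]

#: Standard normal quantiles bounding the flagged categories.
Z_01 = float(stats.norm.ppf(0.01))   # -2.3263...
Z_05 = float(stats.norm.ppf(0.05))   # -1.6449...

SurfaceSpec = Union[float, Callable[[np.ndarray], np.ndarray], "RadialSurface"]


@dataclass(frozen=True)
class RadialSurface:
    """Radially symmetric parametric thickness surface.

    ``value(r) = base + amplitude * exp(-(r - ridge_r_mm)^2 / (2 w^2))
    * (1 - exp(-r^2 / (2 p^2)))``

    i.e. a peripheral baseline plus a perifoveal Gaussian ridge peaking
    near ``ridge_r_mm`` eccentricity, multiplied by a foveal-pit factor
    that suppresses thickness in the foveola (ganglion cells are absent
    at the foveal center).  ``pit_radius_mm = 0`` disables the pit.

    All lengths in mm, thicknesses in micrometres.
    """

    base: float
    amplitude: float = 0.0
    ridge_r_mm: float = 1.0
    ridge_width_mm: float = 0.8
    pit_radius_mm: float = 0.0

    def __call__(self, r_mm: np.ndarray) -> np.ndarray:
        r = np.asarray(r_mm, dtype=float)
        out = np.full_like(r, self.base)
        if self.amplitude:
            ridge = np.exp(-((r - self.ridge_r_mm) ** 2) / (2 * self.ridge_width_mm**2))
            if self.pit_radius_mm > 0:
                ridge = ridge * (1.0 - np.exp(-(r**2) / (2 * self.pit_radius_mm**2)))
            out = out + self.amplitude * ridge
        return out


def _evaluate(spec: SurfaceSpec, geometry: RasterGeometry) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(geometry.radius_mm()), dtype=float)
    return np.full(geometry.shape, float(spec))


@dataclass
class NormativeModel:
    """Per-pixel Gaussian normative thickness distributions for one layer."""

    layer: str
    mean_surface: np.ndarray
    sd_surface: np.ndarray
    geometry: RasterGeometry
    percentile_model: str = "gaussian"

    def __post_init__(self) -> None:
        self.mean_surface = np.asarray(self.mean_surface, dtype=float)
        self.sd_surface = np.asarray(self.sd_surface, dtype=float)
        shape = tuple(self.geometry.shape)
        if self.mean_surface.shape != shape or self.sd_surface.shape != shape:
            raise ValueError("mean/SD surfaces must match the raster geometry shape")
        if self.layer not in ("GCL", "IPL", "GCIPL"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.percentile_model != "gaussian":
            raise ValueError("only the gaussian percentile model is implemented")
        if not np.all(np.isfinite(self.mean_surface)) or np.any(self.mean_surface < 0):
            raise ValueError("mean surface must be finite and non-negative")
        bad = ~(self.sd_surface > 0) | ~np.isfinite(self.sd_surface)
        if np.any(bad):
            rr, cc = np.nonzero(bad)
            raise ValueError(
                "SD surface must be strictly positive and finite; first offending "
                f"pixel at (row={rr[0]}, col={cc[0]})"
            )

    # -- percentile cutoffs ----------------------------------------------
    def quantile_surface(self, q: float) -> np.ndarray:
        """Pixelwise thickness at normative quantile ``q`` (Gaussian)."""
        z = float(stats.norm.ppf(q))
        return self.mean_surface + z * self.sd_surface

    # -- serialization ----------------------------------------------------
    def save(self, stem: Path | str) -> None:
        """Write ``<stem>.tif`` (2-page float32: mean, SD) + ``<stem>.json``."""
        stem = Path(stem)
        tifffile.imwrite(
            stem.with_suffix(".tif"),
            np.stack([self.mean_surface, self.sd_surface]).astype(np.float32),
        )
        meta = {
            "layer": self.layer,
            "percentile_model": self.percentile_model,
            "shape": list(self.geometry.shape),
            "pitch_mm": list(self.geometry.pitch_mm),
            "fovea_px": list(self.geometry.fovea_px),
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, stem: Path | str) -> "NormativeModel":
        stem = Path(stem)
        arr = tifffile.imread(stem.with_suffix(".tif")).astype(float)
        meta = json.loads(stem.with_suffix(".json").read_text())
        geom = RasterGeometry(
            tuple(meta["shape"]), tuple(meta["pitch_mm"]), tuple(meta["fovea_px"])
        )
        return cls(meta["layer"], arr[0], arr[1], geom, meta["percentile_model"])


def build_normative(
    mean_spec: SurfaceSpec,
    sd_spec: SurfaceSpec,
    geometry: RasterGeometry,
    layer: str = "GCL",
) -> NormativeModel:
    """Evaluate parametric mean/SD surfaces on the raster.

    ``mean_spec`` and ``sd_spec`` may each be a constant (micrometres), a
    :class:`RadialSurface`, or any callable of the eccentricity raster.
    Deterministic for a fixed spec; rejects specs that yield non-positive
    SD anywhere.
    """
    mean = _evaluate(mean_spec, geometry)
    sd = _evaluate(sd_spec, geometry)
    return NormativeModel(layer, mean, sd, geometry)


def compose_gcipl(
    gcl: NormativeModel, ipl: NormativeModel, rho: float = 0.5
) -> NormativeModel:
    """GCIPL model from GCL + IPL: means add; SDs combine with correlation."""
    if {gcl.layer, ipl.layer} != {"GCL", "IPL"}:
        raise ValueError(f"expected one GCL and one IPL model, got {gcl.layer}/{ipl.layer}")
    if gcl.geometry != ipl.geometry:
        raise ValueError("GCL and IPL models must share raster geometry")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("inter-layer correlation must lie in [-1, 1]")
    mean = gcl.mean_surface + ipl.mean_surface
    var = (
        gcl.sd_surface**2
        + ipl.sd_surface**2
        + 2.0 * rho * gcl.sd_surface * ipl.sd_surface
    )
    return NormativeModel("GCIPL", mean, np.sqrt(var), gcl.geometry)


def classify_thickness(model: NormativeModel, thickness: np.ndarray) -> DeviationMap:
    """Classify a thickness raster against the normative model.

    Category assignment partitions the real line per pixel:

    * ``z < z01``            -> ABNORMAL_1 (red, P < 1%)
    * ``z01 <= z < z05``     -> BORDERLINE_5 (yellow, P < 5%)
    * ``z05 <= z <= -z05``   -> WNL (green, 5-95% prediction interval)
    * ``-z05 < z <= -z01``   -> SUPER_95 (blue, P > 95%)
    * ``z > -z01``           -> SUPER_99 (pink, P > 99%)

    Values exactly at a cutoff fall on the less-extreme side (flagging uses
    strict inequalities).  Negative thickness is the missing sentinel and
    maps to EXCLUDED.
    """
    thickness = np.asarray(thickness, dtype=float)
    if thickness.shape != tuple(model.geometry.shape):
        raise ValueError(
            f"thickness shape {thickness.shape} does not match model raster "
            f"{model.geometry.shape}"
        )
    missing = (thickness < 0) | ~np.isfinite(thickness)
    z = np.where(missing, 0.0, (thickness - model.mean_surface) / model.sd_surface)
    cats = np.full(thickness.shape, DeviationCategory.WNL, dtype=np.int8)
    cats[z < Z_05] = DeviationCategory.BORDERLINE_5
    cats[z < Z_01] = DeviationCategory.ABNORMAL_1
    cats[z > -Z_05] = DeviationCategory.SUPER_95
    cats[z > -Z_01] = DeviationCategory.SUPER_99
    cats[missing] = DeviationCategory.EXCLUDED
    return DeviationMap(cats, model.geometry)


# ---------------------------------------------------------------------------
# Default normative surfaces
#
# Shapes follow macular anatomy: the GCL is a thin layer that is nearly
# absent in the foveola, peaks in a perifoveal ridge around 1 mm
# eccentricity (~50 um) and thins toward the periphery; the IPL follows the
# same pattern with a shallower pit and a broader, lower ridge.  The
# resulting central-field averages are in the range reported for normal
# eyes on posterior-pole scans (GCL roughly 25-30 um, GCIPL roughly
# 55-65 um over the central 18 degrees).
# ---------------------------------------------------------------------------

GCL_MEAN_DEFAULT = RadialSurface(
    base=12.0, amplitude=38.0, ridge_r_mm=1.0, ridge_width_mm=0.9, pit_radius_mm=0.35
)
IPL_MEAN_DEFAULT = RadialSurface(
    base=18.0, amplitude=22.0, ridge_r_mm=1.1, ridge_width_mm=1.1, pit_radius_mm=0.30
)
GCL_SD_DEFAULT = 3.0   # um, population SD per pixel
IPL_SD_DEFAULT = 3.0   # um


def default_gcl_model(geometry: RasterGeometry) -> NormativeModel:
    """Default GCL normative model on the given raster."""
    return build_normative(GCL_MEAN_DEFAULT, GCL_SD_DEFAULT, geometry, layer="GCL")


def default_ipl_model(geometry: RasterGeometry) -> NormativeModel:
    """Default IPL normative model on the given raster."""
    return build_normative(IPL_MEAN_DEFAULT, IPL_SD_DEFAULT, geometry, layer="IPL")
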