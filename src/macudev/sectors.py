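"""8 x 8 posterior-pole superpixel grids and macular sector aggregation.

Posterior-pole scans export layer thickness as an 8 x 8 grid of 64
superpixels (3 x 3 degrees each, 24 x 24 degrees total) centered on the
fovea.  The central 48 superpixels are grouped into 5 superior and 5
inferior macular sectors; the grid's central 6 x 6 window (18 x 18
degrees) defines the global thickness average.

The exact superpixel membership of the published sectors is only available
as a figure, so the shipped :func:`default_sector_map` is a documented
approximation: the outermost temporal and nasal columns are unused (48
cells remain), and within each hemifield the cells are grouped into five
angular wedges about the fovea, numbered S1/I1 (most temporal) through
S5/I5 (most nasal), so that sector 3 sits directly above/below the fovea.
The map is mirror-symmetric about the horizontal midline and is a plain
8 x 8 label matrix, so alternative sectorizations can be supplied as data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RasterGeometry

__all__ = [
    "ThicknessGrid",
    "SectorMap",
    "default_sector_map",
    "gcipl_grid",
    "sector_means",
    "global_mean",
    "grid_from_raster",
    "mirror_grid",
    "read_grid_csv",
    "write_grid_csv",
]

SECTOR_LABELS = [f"S{i}" for i in range(1, 6)] + [f"I{i}" for i in range(1, 6)]
UNUSED = "UNUSED"


@dataclass
class ThicknessGrid:
    """8 x 8 superpixel thickness matrix (um) for one eye and layer.

    Orientation is the fixed right-eye convention: row 0 most superior,
    column 0 most temporal.  Missing superpixels are NaN.
    """

    values: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (8, 8):
            raise ValueError(f"grid must be 8 x 8, got {self.values.shape}")
        if self.layer not in ("GCL", "IPL", "GCIPL"):
            raise ValueError(f"unknown layer {self.layer!r}")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValueError("grid thickness must be non-negative (missing = NaN)")


@dataclass(frozen=True)
class SectorMap:
    """8 x 8 assignment of superpixels to sectors S1-S5 / I1-I5 / UNUSED."""

    assignment: tuple[tuple[str, ...], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = self.as_array()
        if arr.shape != (8, 8):
            raise ValueError("sector map must be 8 x 8")
        labels = set(arr.ravel().tolist())
        if not labels <= set(SECTOR_LABELS) | {UNUSED}:
            raise ValueError(f"unknown sector labels {labels - set(SECTOR_LABELS) - {UNUSED}}")
        n_used = int(np.sum(arr != UNUSED))
        if n_used != 48:
            raise ValueError(f"sector map must label exactly 48 cells, labels {n_used}")
        if any(lab.startswith("S") and lab != UNUSED for lab in arr[4:].ravel()):
            raise ValueError("superior sectors may occupy rows 0-3 only")
        if any(lab.startswith("I") for lab in arr[:4].ravel()):
            raise ValueError("inferior sectors may occupy rows 4-7 only")
        def _swap(lab: str) -> str:
            if lab in (f"S{i}" for i in range(1, 6)):
                return "I" + lab[1:]
            if lab in (f"I{i}" for i in range(1, 6)):
                return "S" + lab[1:]
            return lab

        mirrored = np.vectorize(_swap)(np.flipud(arr))
        if not np.array_equal(arr, mirrored):
            raise ValueError("sector map must mirror about the horizontal midline")

    def as_array(self) -> np.ndarray:
        return np.array([list(row) for row in self.assignment], dtype="U6")

    def members(self, label: str) -> list[tuple[int, int]]:
        """Cells ``(row, col)`` assigned to ``label``."""
        arr = self.as_array()
        return [tuple(rc) for rc in np.argwhere(arr == label)]

    @classmethod
    def from_array(cls, arr: np.ndarray, provenance: str = "") -> "SectorMap":
        return cls(tuple(tuple(str(x) for x in row) for row in np.asarray(arr)), provenance)

    @classmethod
    def from_csv(cls, path: Path | str) -> "SectorMap":
        arr = pd.read_csv(path, header=None, dtype=str).to_numpy()
        return cls.from_array(arr, provenance=str(path))

    def to_csv(self, path: Path | str) -> None:
        pd.DataFrame(self.as_array()).to_csv(path, header=False, index=False)


def default_sector_map() -> SectorMap:
    """Shipped 5+5 sector approximation (angular wedges, see module docs)."""
    arr = np.full((8, 8), UNUSED, dtype="U6")
    center = 3.5
    for r in range(8):
        for c in range(1, 7):
            y_up = center - r            # >0 superior
            x = c - center               # >0 nasal
            # wedge angle from the nasal horizontal, in the upper half-plane
            phi = np.degrees(np.arctan2(abs(y_up), x))  # 0 = nasal, 180 = temporal
            idx = min(int(phi // 36), 4)                # 5 wedges of 36 deg
            number = 5 - idx                            # S1 temporal ... S5 nasal
            arr[r, c] = f"S{number}" if y_up > 0 else f"I{number}"
    return SectorMap.from_array(arr, provenance="macudev default angular wedges")


def gcipl_grid(gcl: ThicknessGrid, ipl: ThicknessGrid) -> ThicknessGrid:
    """Elementwise GCL + IPL sum; missing in either layer stays missing."""
    if gcl.layer != "GCL" or ipl.layer != "IPL":
        raise ValueError(f"expected GCL and IPL grids, got {gcl.layer}/{ipl.layer}")
    return ThicknessGrid(gcl.values + ipl.values, "GCIPL")


def sector_means(grid: ThicknessGrid, sector_map: SectorMap | None = None) -> dict[str, float]:
    """Unweighted mean thickness of each sector's non-missing superpixels.

    A sector whose members are all missing is reported as NaN.
    """
    if sector_map is None:
        sector_map = default_sector_map()
    arr = sector_map.as_array()
    out: dict[str, float] = {}
    for label in SECTOR_LABELS:
        vals = grid.values[arr == label]
        vals = vals[np.isfinite(vals)]
        out[label] = float(np.mean(vals)) if vals.size else float("nan")
    return out


def global_mean(grid: ThicknessGrid) -> float:
    """Mean over the central 6 x 6 superpixels (the 18 x 18 degree field).

    Raises if every central superpixel is missing (the average is then
    undefined, which must surface rather than propagate silently).
    """
    central = grid.values[1:7, 1:7]
    vals = central[np.isfinite(central)]
    if vals.size == 0:
        raise ValueError("global mean undefined: all central superpixels missing")
    return float(np.mean(vals))


def mirror_grid(grid: ThicknessGrid) -> ThicknessGrid:
    """Left-right mirror (OS acquisition -> OD orientation)."""
    return ThicknessGrid(grid.values[:, ::-1].copy(), grid.layer)


def grid_from_raster(
    thickness: np.ndarray, geometry: RasterGeometry, window_mm: float = 7.2,
    layer: str = "GCL",
) -> ThicknessGrid:
    """Average a thickness raster into the fovea-centered 8 x 8 grid.

    ``window_mm`` is the full width/height of the grid footprint (7.2 mm =
    24 degrees at 0.3 mm/degree).  Pixels are binned by the position of
    their centers; negative raster values (missing sentinel) are left out
    of the block averages, and a block with no valid pixel is NaN.
    """
    thickness = np.asarray(thickness, dtype=float)
    if thickness.shape != tuple(geometry.shape):
        raise ValueError("thickness raster does not match geometry")
    x, y = geometry.xy_mm()
    half = window_mm / 2.0
    cell = window_mm / 8.0
    col_idx = np.floor((x + half) / cell).astype(int)
    row_idx = np.floor((half - y) / cell).astype(int)  # row 0 superior
    valid = (
        (col_idx >= 0) & (col_idx < 8) & (row_idx >= 0) & (row_idx < 8)
        & np.isfinite(thickness) & (thickness >= 0)
    )
    flat = row_idx[valid] * 8 + col_idx[valid]
    sums = np.bincount(flat, weights=thickness[valid], minlength=64)
    counts = np.bincount(flat, minlength=64)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ThicknessGrid(means.reshape(8, 8), layer)


def read_grid_csv(path: Path | str, layer: str) -> ThicknessGrid:
    """Read an 8-row comma-separated grid (um; empty field = missing)."""
    df = pd.read_csv(path, header=None)
    return ThicknessGrid(df.to_numpy(dtype=float), layer)


def write_grid_csv(grid: ThicknessGrid, path: Path | str) -> None:
    pd.DataFrame(grid.values).to_csv(path, header=False, index=False, na_rep="")
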