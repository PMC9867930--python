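"""Shared domain types for macular deviation-map analysis.

Coordinate conventions (right-eye / OD orientation, used everywhere):

* raster indexing is row-major, 0-based, with row 0 the most **superior**
  row and column 0 the most **temporal** column;
* physical coordinates are millimetres relative to the fovea, with ``x``
  increasing nasally (with column index) and ``y`` increasing superiorly
  (against row index);
* pixel positions are pixel **centers** (pixel ``(r, c)`` sits at raster
  coordinate ``(r, c)`` exactly).

Left (OS) eyes are mirrored into this orientation before any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "DeviationCategory",
    "RasterGeometry",
    "DeviationMap",
    "AnnulusSpec",
    "CATEGORY_KEYS",
    "DEFAULT_PALETTE",
    "OVERLAY_RGB",
    "MISSING",
]

#: Sentinel for "not measured" thickness (any negative value is missing).
MISSING: float = -1.0


class DeviationCategory(IntEnum):
    """Five-color percentile category of a deviation-map pixel.

    Thickness below the pixelwise 1st normative percentile is ``ABNORMAL_1``
    (red), below the 5th ``BORDERLINE_5`` (yellow), within the 5%-95%
    prediction interval ``WNL`` (green), above the 95th ``SUPER_95`` (blue)
    and above the 99th ``SUPER_99`` (pink).  ``EXCLUDED`` marks pixels that
    carry no thickness category: background, overlay graphics, or missing
    measurements.
    """

    EXCLUDED = 0
    ABNORMAL_1 = 1
    BORDERLINE_5 = 2
    WNL = 3
    SUPER_95 = 4
    SUPER_99 = 5


#: Short column keys used in extent tables for the four flagged categories.
CATEGORY_KEYS: dict[DeviationCategory, str] = {
    DeviationCategory.ABNORMAL_1: "abn1",
    DeviationCategory.BORDERLINE_5: "abn5",
    DeviationCategory.SUPER_95: "sup95",
    DeviationCategory.SUPER_99: "sup99",
}

#: Default rendering palette (RGB). Chosen close to the clinical map colors
#: and mutually separated by a per-channel distance far above the default
#: parse tolerance.
DEFAULT_PALETTE: dict[DeviationCategory, tuple[int, int, int]] = {
    DeviationCategory.ABNORMAL_1: (237, 28, 36),     # red
    DeviationCategory.BORDERLINE_5: (255, 242, 0),   # yellow
    DeviationCategory.WNL: (34, 177, 76),            # green
    DeviationCategory.SUPER_95: (0, 162, 232),       # blue
    DeviationCategory.SUPER_99: (255, 174, 201),     # pink
    DeviationCategory.EXCLUDED: (255, 255, 255),     # background
}

#: Reserved color for overlay graphics (annulus boundaries, sector lines).
OVERLAY_RGB: tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class RasterGeometry:
    """Geometry of a fovea-centered thickness raster.

    Parameters
    ----------
    shape
        ``(rows, cols)`` of the raster.
    pitch_mm
        ``(row_mm_per_px, col_mm_per_px)``; both strictly positive.  Row and
        column pitch may differ (the scan field need not be square).
    fovea_px
        ``(row, col)`` raster coordinate of the fovea; may be fractional and
        must lie inside the raster bounds.
    """

    shape: tuple[int, int]
    pitch_mm: tuple[float, float]
    fovea_px: tuple[float, float]

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError(f"raster shape must be positive, got {self.shape}")
        if self.pitch_mm[0] <= 0 or self.pitch_mm[1] <= 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pitch_mm}")
        fr, fc = self.fovea_px
        if not (0 <= fr <= rows - 1 and 0 <= fc <= cols - 1):
            raise ValueError(
                f"fovea {self.fovea_px} outside raster bounds {self.shape}"
            )

    # -- physical coordinate helpers -------------------------------------
    def xy_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates ``(x, y)`` in mm relative to the fovea.

        ``x`` grows nasally (with column), ``y`` grows superiorly (against
        row). Both arrays have the raster shape.
        """
        rows, cols = self.shape
        r = np.arange(rows, dtype=float)[:, None]
        c = np.arange(cols, dtype=float)[None, :]
        y = (self.fovea_px[0] - r) * self.pitch_mm[0]
        x = (c - self.fovea_px[1]) * self.pitch_mm[1]
        return np.broadcast_to(x, (rows, cols)).copy(), np.broadcast_to(
            y, (rows, cols)
        ).copy()

    def radius_mm(self) -> np.ndarray:
        """Eccentricity (mm from the fovea) of every pixel center."""
        x, y = self.xy_mm()
        return np.hypot(x, y)

    def __eq__(self, other: object) -> bool:  # tolerant float comparison
        if not isinstance(other, RasterGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.pitch_mm, other.pitch_mm)
            and np.allclose(self.fovea_px, other.fovea_px)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.pitch_mm, self.fovea_px))


@dataclass
class DeviationMap:
    """Raster of :class:`DeviationCategory` labels plus scan geometry."""

    categories: np.ndarray
    geometry: RasterGeometry

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=np.int8)
        if self.categories.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"category raster shape {self.categories.shape} does not match "
                f"geometry shape {self.geometry.shape}"
            )
        valid = {int(c) for c in DeviationCategory}
        present = set(np.unique(self.categories).tolist())
        if not present <= valid:
            raise ValueError(f"unknown category codes {sorted(present - valid)}")

    def counts(self) -> dict[DeviationCategory, int]:
        """Number of pixels in each category (all six labels)."""
        binc = np.bincount(self.categories.ravel(), minlength=6)
        return {cat: int(binc[cat]) for cat in DeviationCategory}

    def copy(self) -> "DeviationMap":
        return DeviationMap(self.categories.copy(), self.geometry)


@dataclass(frozen=True)
class AnnulusSpec:
    """Axis-parameterized perifoveal elliptical annulus.

    The clinical region of interest is an ellipse 4.8 x 4.0 mm in size
    (full diameters) centered on the fovea, with a central 1.2 x 1.0 mm
    oval (the foveola) excluded; the defaults below are the corresponding
    semi-axes.  ``a`` is the horizontal (x / nasotemporal) semi-axis and
    ``b`` the vertical (y / supero-inferior) one.
    """

    center_px: tuple[float, float]
    outer_semiaxes_mm: tuple[float, float] = (2.4, 2.0)
    inner_semiaxes_mm: tuple[float, float] = (0.6, 0.5)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        ao, bo = self.outer_semiaxes_mm
        ai, bi = self.inner_semiaxes_mm
        if min(ao, bo, ai, bi) <= 0:
            raise ValueError("ellipse semi-axes must be strictly positive")
        if not (ao > ai and bo > bi):
            raise ValueError(
                "outer semi-axes must exceed inner semi-axes componentwise: "
                f"outer={self.outer_semiaxes_mm} inner={self.inner_semiaxes_mm}"
            )

    def _quad(
        self, geometry: RasterGeometry, semiaxes: tuple[float, float]
    ) -> np.ndarray:
        """Normalized quadratic form (x/a)^2 + (y/b)^2 at pixel centers."""
        rows, cols = geometry.shape
        r = np.arange(rows, dtype=float)[:, None]
        c = np.arange(cols, dtype=float)[None, :]
        # mm offsets from the annulus center (pixel-center rule)
        y = (self.center_px[0] - r) * geometry.pitch_mm[0]
        x = (c - self.center_px[1]) * geometry.pitch_mm[1]
        if self.rotation_deg:
            th = np.deg2rad(self.rotation_deg)
            x, y = x * np.cos(th) + y * np.sin(th), -x * np.sin(th) + y * np.cos(th)
        a, b = semiaxes
        return (x / a) ** 2 + (y / b) ** 2

    def membership(self, geometry: RasterGeometry) -> np.ndarray:
        """Boolean mask of pixels inside the annulus.

        A pixel belongs to the annulus when its center lies inside (or on)
        the outer ellipse and strictly outside the inner one.
        """
        qo = self._quad(geometry, self.outer_semiaxes_mm)
        qi = self._quad(geometry, self.inner_semiaxes_mm)
        return (qo <= 1.0) & (qi > 1.0)

    def area_mm2(self) -> float:
        """Analytic annulus area pi*(a1*b1 - a2*b2)."""
        ao, bo = self.outer_semiaxes_mm
        ai, bi = self.inner_semiaxes_mm
        return float(np.pi * (ao * bo - ai * bi))
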