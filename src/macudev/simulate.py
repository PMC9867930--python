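"""Synthetic eyes, cohorts and rendered deviation-map images.

The generator produces macular layer thickness rasters with the
statistical structure the downstream analysis assumes:

* per-pixel thickness = normative mean - defect field + eye-level offset
  + pixel noise, clipped at zero;
* the eye-level offset (one draw per eye per layer) models between-subject
  differences in overall layer thickness, and the pixel noise models the
  residual within-eye variation; their variances sum to the normative SD,
  so for a healthy eye with ``noise_sd_scale = 1`` every pixel's marginal
  distribution is exactly the normative Gaussian and the deviation map
  flags ~5% of pixels at each tail;
* GCL and IPL share a latent component with correlation ``rho`` so that a
  composed GCIPL model (same ``rho``) is calibrated as well;
* glaucomatous defects are smooth anisotropic bumps along an arcuate path
  (or hemifield / diffuse patterns), mimicking the shape of macular
  retinal-nerve-fiber-bundle loss; the combined GCL+IPL loss at the defect
  core equals ``defect_magnitude`` and is split between the layers;
* left (OS) eyes are generated in right-eye orientation and mirrored.

Rendered deviation maps reproduce the five-color coding with overlay
graphics (elliptical annulus boundaries and straight sector lines) drawn
in a reserved overlay color, so that color-based parsing recovers every
non-overlay pixel's category exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line as draw_line

from .core import (
    DEFAULT_PALETTE,
    OVERLAY_RGB,
    AnnulusSpec,
    DeviationCategory,
    DeviationMap,
    RasterGeometry,
)
from .normative import NormativeModel, default_gcl_model, default_ipl_model
from .sectors import ThicknessGrid, grid_from_raster

__all__ = [
    "MM_PER_DEGREE",
    "EyeSpec",
    "DefectParams",
    "CohortSpec",
    "SimulatedEye",
    "default_geometry",
    "desk_geometry",
    "defect_field",
    "simulate_eye",
    "simulate_cohort",
    "render_deviation_map",
    "sector_line_segments",
    "save_png",
    "cohort_manifest",
]

#: Degrees of scan angle to millimetres on the retina (configurable).
MM_PER_DEGREE = 0.3

GROUPS = ("NORMAL", "SUSPECT", "GLAUCOMA")
SHAPES = ("arcuate_superior", "arcuate_inferior", "hemifield", "diffuse")


def default_geometry(rows: int = 384, cols: int = 384) -> RasterGeometry:
    """Full-map geometry: a fovea-centered raster covering 30 x 25 degrees."""
    width_mm = 30.0 * MM_PER_DEGREE
    height_mm = 25.0 * MM_PER_DEGREE
    return RasterGeometry(
        (rows, cols),
        (height_mm / rows, width_mm / cols),
        ((rows - 1) / 2.0, (cols - 1) / 2.0),
    )


def desk_geometry(n: int = 64) -> RasterGeometry:
    """Square desk-scale geometry covering the 24 x 24 degree grid window."""
    side_mm = 24.0 * MM_PER_DEGREE
    return RasterGeometry(
        (n, n), (side_mm / n, side_mm / n), ((n - 1) / 2.0, (n - 1) / 2.0)
    )


@dataclass(frozen=True)
class DefectParams:
    """Shape parameters of the simulated structural defect.

    The arcuate bump follows an arc of eccentricity ``arc_r_mm`` with
    radial width ``radial_sd_mm``; the angular profile is Gaussian about
    ``arc_center_deg`` (angles measured from the nasal horizontal, so 90
    deg is straight above the fovea and larger angles are more temporal)
    with SD ``angular_sd_deg``.  ``gcl_fraction`` splits the combined loss
    between GCL and IPL.  ``hemifield_tau_mm`` is the softness of the
    hemifield step at the horizontal raphe.
    """

    arc_r_mm: float = 1.5
    radial_sd_mm: float = 0.6
    arc_center_deg: float = 115.0
    angular_sd_deg: float = 40.0
    hemifield_tau_mm: float = 0.25
    gcl_fraction: float = 0.5


@dataclass(frozen=True)
class EyeSpec:
    """Recipe for one synthetic eye."""

    group: str = "NORMAL"
    defect_magnitude: float = 0.0          # um combined GCL+IPL loss at core
    defect_shape: str = "arcuate_superior"
    noise_sd_scale: float = 1.0
    laterality: str = "OD"
    seed: int = 0
    eye_offset_sd: float = 2.0             # um between-eye component of the SD
    rho: float = 0.5                       # GCL-IPL correlation
    defect: DefectParams = field(default_factory=DefectParams)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.defect_shape not in SHAPES:
            raise ValueError(f"defect shape must be one of {SHAPES}")
        if self.defect_magnitude < 0:
            raise ValueError("defect magnitude must be >= 0")
        if self.group == "NORMAL" and self.defect_magnitude != 0:
            raise ValueError("NORMAL eyes must have defect_magnitude = 0")
        if self.noise_sd_scale <= 0:
            raise ValueError("noise_sd_scale must be > 0")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")
        if self.eye_offset_sd < 0:
            raise ValueError("eye_offset_sd must be >= 0")
        if not 0.0 <= self.defect.gcl_fraction <= 1.0:
            raise ValueError("gcl_fraction must lie in [0, 1]")


def defect_field(
    geometry: RasterGeometry, shape: str, params: DefectParams = DefectParams()
) -> np.ndarray:
    """Unit-peak smooth defect field of the requested shape (OD orientation)."""
    x, y = geometry.xy_mm()
    r = np.hypot(x, y)
    if shape == "diffuse":
        f = np.ones(geometry.shape)
    elif shape == "hemifield":
        # superior hemifield loss with a soft edge at the horizontal raphe
        f = 1.0 / (1.0 + np.exp(-y / params.hemifield_tau_mm))
    elif shape in ("arcuate_superior", "arcuate_inferior"):
        y_eff = y if shape == "arcuate_superior" else -y
        alpha = np.degrees(np.arctan2(y_eff, x))  # 0 nasal, 90 up, 180 temporal
        radial = np.exp(-((r - params.arc_r_mm) ** 2) / (2 * params.radial_sd_mm**2))
        angular = np.where(
            alpha > 0,
            np.exp(-((alpha - params.arc_center_deg) ** 2) / (2 * params.angular_sd_deg**2)),
            0.0,
        )
        f = radial * angular
    else:  # pragma: no cover - guarded by EyeSpec validation
        raise ValueError(f"unknown defect shape {shape!r}")
    peak = float(f.max())
    if peak > 0:
        f = f / peak
    return f


def _correlated_pair(
    rng: np.random.Generator, shape: tuple[int, ...], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal fields with correlation rho."""
    shared = rng.standard_normal(shape)
    a = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(shape)
    b = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(shape)
    return a, b


def simulate_eye(
    model_gcl: NormativeModel,
    model_ipl: NormativeModel,
    spec: EyeSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one eye's GCL and IPL thickness rasters.

    Deterministic for a fixed spec (the spec carries the seed).  The
    between-eye offset SD must stay below the smallest normative SD so the
    variance decomposition is well defined.
    """
    if model_gcl.geometry != model_ipl.geometry:
        raise ValueError("GCL and IPL normative models must share geometry")
    geometry = model_gcl.geometry
    min_sd = min(model_gcl.sd_surface.min(), model_ipl.sd_surface.min())
    if spec.eye_offset_sd >= min_sd:
        raise ValueError(
            f"eye_offset_sd ({spec.eye_offset_sd}) must be below the smallest "
            f"normative SD ({min_sd})"
        )
    rng = np.random.default_rng(spec.seed)
    s = spec.noise_sd_scale
    # eye-level offsets, correlated across layers
    u_g, u_i = _correlated_pair(rng, (), spec.rho)
    off_g = s * spec.eye_offset_sd * float(u_g)
    off_i = s * spec.eye_offset_sd * float(u_i)
    # pixel noise, correlated across layers, scaled so the marginal per-pixel
    # SD (offset + noise) equals noise_sd_scale * normative SD
    z_g, z_i = _correlated_pair(rng, geometry.shape, spec.rho)
    noise_g = s * np.sqrt(model_gcl.sd_surface**2 - spec.eye_offset_sd**2) * z_g
    noise_i = s * np.sqrt(model_ipl.sd_surface**2 - spec.eye_offset_sd**2) * z_i
    f = defect_field(geometry, spec.defect_shape, spec.defect)
    loss_g = spec.defect.gcl_fraction * spec.defect_magnitude * f
    loss_i = (1.0 - spec.defect.gcl_fraction) * spec.defect_magnitude * f
    gcl = np.clip(model_gcl.mean_surface - loss_g + off_g + noise_g, 0.0, None)
    ipl = np.clip(model_ipl.mean_surface - loss_i + off_i + noise_i, 0.0, None)
    if spec.laterality == "OS":
        gcl = gcl[:, ::-1].copy()
        ipl = ipl[:, ::-1].copy()
    return gcl, ipl


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distribution of eye specs within a cohort.

    Glaucoma defect magnitudes are lognormal with the given median and
    log-SD; suspects draw from a smaller-median lognormal mixed with
    exact zeros (structurally normal suspects).
    """

    glaucoma_median_um: float = 10.0
    glaucoma_log_sd: float = 0.6
    suspect_median_um: float = 3.0
    suspect_log_sd: float = 0.6
    suspect_zero_prob: float = 0.5
    shape_probs: tuple[float, float, float, float] = (0.35, 0.35, 0.15, 0.15)
    noise_sd_scale: float = 1.0
    os_prob: float = 0.5
    eye_offset_sd: float = 2.0
    rho: float = 0.5
    defect: DefectParams = field(default_factory=DefectParams)


@dataclass
class SimulatedEye:
    """One simulated eye: provenance spec, rasters and superpixel grids."""

    eye_id: str
    spec: EyeSpec
    thickness_gcl: np.ndarray
    thickness_ipl: np.ndarray
    grid_gcl: ThicknessGrid
    grid_ipl: ThicknessGrid


def simulate_cohort(
    model_gcl: NormativeModel,
    model_ipl: NormativeModel,
    n_per_group: dict[str, int],
    cohort_spec: CohortSpec = CohortSpec(),
    seed: int = 0,
) -> list[SimulatedEye]:
    """Generate a reproducible cohort of synthetic eyes.

    Each eye gets its own sub-seed drawn from the master seed, and the
    spec actually used (magnitude, shape, laterality, seed) is returned
    with the eye, so any eye can be regenerated in isolation.
    """
    for g, n in n_per_group.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError("group counts must be >= 0")
    rng = np.random.default_rng(seed)
    eyes: list[SimulatedEye] = []
    for group in GROUPS:
        n = int(n_per_group.get(group, 0))
        for k in range(n):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if group == "GLAUCOMA":
                mag = cohort_spec.glaucoma_median_um * np.exp(
                    cohort_spec.glaucoma_log_sd * rng.standard_normal()
                )
            elif group == "SUSPECT":
                if rng.random() < cohort_spec.suspect_zero_prob:
                    mag = 0.0
                else:
                    mag = cohort_spec.suspect_median_um * np.exp(
                        cohort_spec.suspect_log_sd * rng.standard_normal()
                    )
            else:
                mag = 0.0
            shape = SHAPES[
                int(rng.choice(len(SHAPES), p=np.asarray(cohort_spec.shape_probs)))
            ]
            lat = "OS" if rng.random() < cohort_spec.os_prob else "OD"
            spec = EyeSpec(
                group=group,
                defect_magnitude=float(mag),
                defect_shape=shape,
                noise_sd_scale=cohort_spec.noise_sd_scale,
                laterality=lat,
                seed=sub_seed,
                eye_offset_sd=cohort_spec.eye_offset_sd,
                rho=cohort_spec.rho,
                defect=cohort_spec.defect,
            )
            gcl, ipl = simulate_eye(model_gcl, model_ipl, spec)
            # grids are built in analysis (OD) orientation
            gcl_od = gcl[:, ::-1] if lat == "OS" else gcl
            ipl_od = ipl[:, ::-1] if lat == "OS" else ipl
            geometry = model_gcl.geometry
            eyes.append(
                SimulatedEye(
                    eye_id=f"{group[:2]}{k:04d}",
                    spec=spec,
                    thickness_gcl=gcl,
                    thickness_ipl=ipl,
                    grid_gcl=grid_from_raster(gcl_od, geometry, layer="GCL"),
                    grid_ipl=grid_from_raster(ipl_od, geometry, layer="IPL"),
                )
            )
    return eyes


def cohort_manifest(eyes: list[SimulatedEye]) -> pd.DataFrame:
    """Provenance table: one row per eye with the spec actually used."""
    rows = []
    for e in eyes:
        rows.append(
            {
                "eye_id": e.eye_id,
                "group": e.spec.group,
                "laterality": e.spec.laterality,
                "seed": e.spec.seed,
                "defect_magnitude_um": e.spec.defect_magnitude,
                "defect_shape": e.spec.defect_shape,
                "noise_sd_scale": e.spec.noise_sd_scale,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_perimeter_px(
    annulus: AnnulusSpec, semiaxes: tuple[float, float], geometry: RasterGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Raster pixels on an ellipse boundary (dense parametric sampling)."""
    a_px = semiaxes[0] / geometry.pitch_mm[1]
    b_px = semiaxes[1] / geometry.pitch_mm[0]
    n = max(int(16 * max(a_px, b_px)), 360)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = semiaxes[0] * np.cos(t)
    y = semiaxes[1] * np.sin(t)
    if annulus.rotation_deg:
        th = np.deg2rad(annulus.rotation_deg)
        x, y = x * np.cos(th) - y * np.sin(th), x * np.sin(th) + y * np.cos(th)
    rr = np.round(annulus.center_px[0] - y / geometry.pitch_mm[0]).astype(int)
    cc = np.round(annulus.center_px[1] + x / geometry.pitch_mm[1]).astype(int)
    keep = (rr >= 0) & (rr < geometry.shape[0]) & (cc >= 0) & (cc < geometry.shape[1])
    return rr[keep], cc[keep]


def sector_line_segments(
    annulus: AnnulusSpec,
    geometry: RasterGeometry,
    angles_deg: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Straight radial segments from the inner to the outer ellipse.

    Mimics the sector-dividing lines drawn on clinical deviation maps.
    Angles are in map coordinates (0 = nasal horizontal, CCW).
    """
    segs = []
    for ang in angles_deg:
        th = np.deg2rad(ang)
        for semiaxes, store in (
            (annulus.inner_semiaxes_mm, "p0"),
            (annulus.outer_semiaxes_mm, "p1"),
        ):
            a, b = semiaxes
            # radius of the (axis-aligned) ellipse along direction th
            rad = (a * b) / np.hypot(b * np.cos(th), a * np.sin(th))
            x, y = rad * np.cos(th), rad * np.sin(th)
            r = int(round(annulus.center_px[0] - y / geometry.pitch_mm[0]))
            c = int(round(annulus.center_px[1] + x / geometry.pitch_mm[1]))
            if store == "p0":
                p0 = (r, c)
            else:
                p1 = (r, c)
        segs.append((p0, p1))
    return segs


def render_deviation_map(
    devmap: DeviationMap,
    palette: dict[DeviationCategory, tuple[int, int, int]] | None = None,
    annulus: AnnulusSpec | None = None,
    sector_lines: list[tuple[tuple[int, int], tuple[int, int]]] | None = None,
    overlay_rgb: tuple[int, int, int] = OVERLAY_RGB,
) -> np.ndarray:
    """Render a category raster as an 8-bit RGB image.

    Every pixel receives exactly the palette color of its category; the
    annulus boundaries and sector lines are then over-drawn in the
    reserved overlay color.  Because palette colors are written without
    blending, parsing the image by color recovers the category of every
    non-overlay pixel exactly.
    """
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    colors = list(palette.values())
    if len({tuple(c) for c in colors}) != len(colors):
        raise ValueError("palette assigns the same color to two categories")
    if tuple(overlay_rgb) in {tuple(c) for c in colors}:
        raise ValueError("overlay color collides with a palette color")
    lut = np.zeros((6, 3), dtype=np.uint8)
    for cat, rgb in palette.items():
        lut[int(cat)] = rgb
    img = lut[devmap.categories]
    geometry = devmap.geometry
    if annulus is not None:
        for semiaxes in (annulus.outer_semiaxes_mm, annulus.inner_semiaxes_mm):
            rr, cc = _ellipse_perimeter_px(annulus, semiaxes, geometry)
            img[rr, cc] = overlay_rgb
    if sector_lines:
        rows, cols = geometry.shape
        for (r0, c0), (r1, c1) in sector_lines:
            rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
            keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            img[rr[keep], cc[keep]] = overlay_rgb
    return img


def save_png(image: np.ndarray, path: Path | str) -> None:
    """Write an 8-bit RGB image to PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)
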