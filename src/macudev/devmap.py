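"""Deviation-map quantification: color parsing, annulus fitting, overlay
line removal, and pixel-class extent summaries.

The quantification mirrors the image-analysis chain used on exported
deviation-map images: pixels are classified by their palette color; the
perifoveal elliptical annulus drawn on the map is recovered by direct
least-squares ellipse fitting of its boundary pixels (outer and inner
boundaries fitted separately); straight sector-dividing lines are detected
with a Hough transform and their pixels excluded; finally the percentage
of pixels in each flagged category is computed over the entire scan and
over the annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import hough_line, hough_line_peaks

from .core import (
    CATEGORY_KEYS,
    DEFAULT_PALETTE,
    AnnulusSpec,
    DeviationCategory,
    DeviationMap,
    RasterGeometry,
)

__all__ = [
    "HoughConfig",
    "ExtentSummary",
    "parse_colors",
    "fit_ellipse_direct",
    "fit_annulus",
    "detect_lines",
    "remove_overlay_lines",
    "extent_summary",
]


# ---------------------------------------------------------------------------
# Color parsing
# ---------------------------------------------------------------------------

def parse_colors(
    image: np.ndarray,
    palette: dict[DeviationCategory, tuple[int, int, int]] | None = None,
    tolerance: int = 10,
    geometry: RasterGeometry | None = None,
) -> DeviationMap:
    """Classify an RGB deviation-map image into categories by color.

    Each pixel is assigned the category of the nearest palette color when
    the per-channel (Chebyshev) distance is within ``tolerance``; anything
    else — overlay graphics, anti-aliased edges, annotations — becomes
    EXCLUDED.  The palette must be unambiguous: all pairs of palette
    colors farther apart than ``2 * tolerance`` per channel.
    """
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    cats = list(palette.keys())
    colors = np.array([palette[c] for c in cats], dtype=float)
    for i in range(len(colors)):
        for j in range(i + 1, len(colors)):
            d = np.max(np.abs(colors[i] - colors[j]))
            if d <= 2 * tolerance:
                raise ValueError(
                    f"ambiguous palette: colors of {cats[i].name} and "
                    f"{cats[j].name} are within 2 x tolerance ({d} <= {2 * tolerance})"
                )
    px = image.reshape(-1, 1, 3).astype(float)
    dist = np.max(np.abs(px - colors[None, :, :]), axis=2)  # Chebyshev
    best = np.argmin(dist, axis=1)
    within = dist[np.arange(px.shape[0]), best] <= tolerance
    codes = np.array([int(c) for c in cats], dtype=np.int8)
    out = np.where(within, codes[best], int(DeviationCategory.EXCLUDED)).astype(np.int8)
    rows, cols = image.shape[:2]
    if geometry is None:
        geometry = RasterGeometry(
            (rows, cols), (1.0, 1.0), ((rows - 1) / 2.0, (cols - 1) / 2.0)
        )
    return DeviationMap(out.reshape(rows, cols), geometry)


# ---------------------------------------------------------------------------
# Direct least-squares ellipse fitting
# ---------------------------------------------------------------------------

def fit_ellipse_direct(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Fit an ellipse to points by direct algebraic least squares.

    Minimizes the algebraic distance ``ax^2 + bxy + cy^2 + dx + ey + f``
    subject to the ellipse-specific constraint ``4ac - b^2 = 1`` (the
    numerically stable partitioned formulation), which guarantees the
    fitted conic is an ellipse.  Returns ``(cx, cy, a_semi, b_semi,
    theta)`` with ``a_semi`` the semi-axis closest to the x direction and
    ``theta`` the rotation (radians) of that axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ValueError(f"ellipse fit needs at least 6 points, got {x.size}")
    # center/scale for conditioning
    mx, my = x.mean(), y.mean()
    sc = max(x.std(), y.std(), 1e-12)
    xs, ys = (x - mx) / sc, (y - my) / sc

    D1 = np.column_stack([xs**2, xs * ys, ys**2])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    w, v = np.linalg.eig(np.linalg.solve(C, M))
    # the ellipse solution has 4ac - b^2 > 0
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    idx = np.flatnonzero(np.isreal(w) & (cond > 0))
    if idx.size == 0:
        raise ValueError("no elliptical solution found for the given points")
    a1 = np.real(v[:, idx[0]])
    coeffs = np.concatenate([a1, T @ a1])
    A, B, Cc, D, E, F = coeffs
    # undo normalization: substitute x -> (x - mx)/sc
    A2 = A / sc**2
    B2 = B / sc**2
    C2 = Cc / sc**2
    D2c = D / sc - 2 * A * mx / sc**2 - B * my / sc**2
    E2 = E / sc - 2 * Cc * my / sc**2 - B * mx / sc**2
    F2 = (
        F
        + A * mx**2 / sc**2
        + Cc * my**2 / sc**2
        + B * mx * my / sc**2
        - D * mx / sc
        - E * my / sc
    )
    return _conic_to_geometric(A2, B2, C2, D2c, E2, F2)


def _conic_to_geometric(A, B, C, D, E, F) -> tuple[float, float, float, float, float]:
    """Convert conic coefficients to (cx, cy, semi_x, semi_y, theta)."""
    den = 4 * A * C - B**2
    if den <= 0:
        raise ValueError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # value of the quadratic form at the center
    Fc = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
    # eigen-decomposition of the quadratic part
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals * (-Fc) <= 0):
        raise ValueError("degenerate ellipse")
    axes = np.sqrt(-Fc / evals)
    # report the axis closest to x first
    i_x = int(np.argmax(np.abs(evecs[0, :])))
    i_y = 1 - i_x
    theta = float(np.arctan2(evecs[1, i_x], evecs[0, i_x]))
    if theta > np.pi / 2:
        theta -= np.pi
    elif theta < -np.pi / 2:
        theta += np.pi
    return float(cx), float(cy), float(axes[i_x]), float(axes[i_y]), theta


# ---------------------------------------------------------------------------
# Hough line detection / overlay removal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoughConfig:
    """Straight-line Hough transform parameters.

    ``theta_step_deg`` is the angular accumulator resolution (the radial
    resolution is 1 px), ``peak_rel_threshold`` the accumulator peak cut
    relative to the maximum, ``dilation_px`` the half-thickness of the
    excluded band around each detected line, ``min_votes`` an absolute
    floor on peak support.
    """

    theta_step_deg: float = 1.0
    peak_rel_threshold: float = 0.5
    dilation_px: int = 1
    min_votes: int = 20
    max_lines: int = 12


def detect_lines(mask: np.ndarray, config: HoughConfig = HoughConfig()) -> list[tuple[float, float]]:
    """Detect straight lines in a binary mask; returns ``(angle, dist)`` pairs.

    Uses the standard (infinite-line) Hough transform; ``angle`` is the
    normal angle in radians and ``dist`` the signed normal distance from
    the origin, in the convention ``x cos(angle) + y sin(angle) = dist``
    with ``x = col`` and ``y = row``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    n_theta = max(int(round(180.0 / config.theta_step_deg)), 1)
    thetas = np.linspace(-np.pi / 2, np.pi / 2, n_theta, endpoint=False)
    h, angles, dists = hough_line(mask, theta=thetas)
    thr = max(config.peak_rel_threshold * float(h.max()), float(config.min_votes))
    _, peak_angles, peak_dists = hough_line_peaks(
        h, angles, dists, threshold=thr, num_peaks=config.max_lines
    )
    return list(zip(map(float, peak_angles), map(float, peak_dists)))


def _line_band_mask(
    shape: tuple[int, int], lines: list[tuple[float, float]], dilation_px: int
) -> np.ndarray:
    """Pixels within ``dilation_px`` (in normal distance) of any detected line."""
    rows, cols = shape
    band = np.zeros(shape, dtype=bool)
    if not lines:
        return band
    rr = np.arange(rows, dtype=float)[:, None]
    cc = np.arange(cols, dtype=float)[None, :]
    # half-open band: |x cos + y sin - d| <= dilation + 0.5 covers the drawn px
    for ang, dist in lines:
        d = np.abs(cc * np.cos(ang) + rr * np.sin(ang) - dist)
        band |= d <= (dilation_px + 0.5)
    return band


def remove_overlay_lines(
    devmap: DeviationMap,
    config: HoughConfig = HoughConfig(),
    candidate_mask: np.ndarray | None = None,
) -> DeviationMap:
    """Exclude pixels lying on detected straight overlay lines.

    ``candidate_mask`` marks the pixels in which to search for lines (for
    example the dark-ink mask of a grayscale image, as in the original
    image pipeline).  When omitted, the EXCLUDED pixels of the map itself
    are used as candidates, which catches sector lines drawn in the
    reserved overlay color.  Candidate pixels within ``dilation_px`` of a
    detected line are reassigned EXCLUDED; pixels farther from every line,
    and pixels not in the candidate mask, are never modified.  Zero
    detected lines is a valid outcome and returns the map unchanged.
    """
    if candidate_mask is None:
        candidate_mask = devmap.categories == int(DeviationCategory.EXCLUDED)
    else:
        candidate_mask = np.asarray(candidate_mask, dtype=bool)
        if candidate_mask.shape != devmap.categories.shape:
            raise ValueError("candidate mask shape does not match the map")
    lines = detect_lines(candidate_mask, config)
    out = devmap.copy()
    if lines:
        band = _line_band_mask(devmap.categories.shape, lines, config.dilation_px)
        out.categories[band & candidate_mask] = int(DeviationCategory.EXCLUDED)
    return out


# ---------------------------------------------------------------------------
# Annulus fitting
# ---------------------------------------------------------------------------

def _boundary_candidates(image_or_map, ink_threshold: float = 60.0) -> np.ndarray:
    """Binary mask of overlay-ink pixels (dark on the colored map)."""
    if isinstance(image_or_map, DeviationMap):
        return image_or_map.categories == int(DeviationCategory.EXCLUDED)
    img = np.asarray(image_or_map)
    if img.ndim == 3:
        gray = img.astype(float).mean(axis=2)
    else:
        gray = img.astype(float)
    return gray < ink_threshold


def fit_annulus(
    image_or_map,
    prior: AnnulusSpec,
    geometry: RasterGeometry,
    band_rel_width: float = 0.15,
    remove_lines: bool = True,
    hough: HoughConfig = HoughConfig(),
    ink_threshold: float = 60.0,
) -> AnnulusSpec:
    """Recover the drawn elliptical annulus from a rendered map.

    The image is reduced to an overlay-ink mask (grayscale thresholding,
    as the original pipeline converts the map to grayscale first); radial
    sector lines are optionally stripped with the Hough detector; the
    remaining candidates are split into outer- and inner-boundary sets by
    their normalized radius relative to the prior annulus, and each set is
    fitted with direct least-squares.  Semi-axes are returned in mm.
    """
    mask = _boundary_candidates(image_or_map, ink_threshold)
    if remove_lines:
        for ang, dist in detect_lines(mask, hough):
            rows, cols = mask.shape
            rr = np.arange(rows, dtype=float)[:, None]
            cc = np.arange(cols, dtype=float)[None, :]
            d = np.abs(cc * np.cos(ang) + rr * np.sin(ang) - dist)
            mask = mask & ~(d <= (hough.dilation_px + 0.5))
    rr, cc = np.nonzero(mask)
    if rr.size < 12:
        raise ValueError(
            f"annulus fit needs boundary pixels for both ellipses, found {rr.size}"
        )
    # mm coordinates relative to the prior center (x nasal, y superior)
    x = (cc - prior.center_px[1]) * geometry.pitch_mm[1]
    y = (prior.center_px[0] - rr) * geometry.pitch_mm[0]

    fitted: dict[str, tuple] = {}
    for name, semiaxes in (
        ("outer", prior.outer_semiaxes_mm),
        ("inner", prior.inner_semiaxes_mm),
    ):
        a, b = semiaxes
        q = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        sel = np.abs(q - 1.0) <= band_rel_width
        if np.count_nonzero(sel) < 6:
            raise ValueError(
                f"{name} ellipse fit rejected: only {np.count_nonzero(sel)} "
                "candidate boundary pixels near the prior"
            )
        cx, cy, sa, sb, theta = fit_ellipse_direct(x[sel], y[sel])
        fitted[name] = (cx, cy, sa, sb, theta)

    ocx, ocy, oa, ob, otheta = fitted["outer"]
    _, _, ia, ib, _ = fitted["inner"]
    center_px = (
        prior.center_px[0] - ocy / geometry.pitch_mm[0],
        prior.center_px[1] + ocx / geometry.pitch_mm[1],
    )
    return AnnulusSpec(
        center_px=center_px,
        outer_semiaxes_mm=(oa, ob),
        inner_semiaxes_mm=(ia, ib),
        rotation_deg=float(np.degrees(otheta)),
    )


# ---------------------------------------------------------------------------
# Extent summaries
# ---------------------------------------------------------------------------

@dataclass
class ExtentSummary:
    """Percentage of region pixels in each flagged category.

    ``pct`` maps ``abn1/abn5/sup95/sup99`` (disjoint percentile bands by
    default; cumulative when requested) to percentages of ``n_total_px``.
    ``n_total_px`` is the denominator actually used: all region pixels
    when ``denominator='raw'``, region pixels minus EXCLUDED when
    ``denominator='exclude'`` (the default — overlay and background pixels
    carry no thickness information).
    """

    region: str
    pct: dict[str, float]
    n_total_px: int
    n_excluded_px: int
    denominator: str = "exclude"
    cumulative: bool = False


def extent_summary(
    devmap: DeviationMap,
    region: AnnulusSpec | str = "ENTIRE_SCAN",
    denominator: str = "exclude",
    cumulative: bool = False,
) -> ExtentSummary:
    """Quantify flagged-pixel extents over the scan or the annulus.

    Annulus membership uses the pixel-center rule: a pixel belongs when
    its center lies inside (or on) the outer ellipse and strictly outside
    the inner one.  With ``cumulative=True`` ``abn5`` reports P < 5%
    (including the P < 1% pixels) and ``sup95`` reports P > 95% (including
    P > 99%), matching cumulative-cutoff reporting.
    """
    if denominator not in ("exclude", "raw"):
        raise ValueError("denominator must be 'exclude' or 'raw'")
    if isinstance(region, str):
        if region != "ENTIRE_SCAN":
            raise ValueError("region must be 'ENTIRE_SCAN' or an AnnulusSpec")
        member = np.ones(devmap.categories.shape, dtype=bool)
        region_name = "ENTIRE_SCAN"
    else:
        member = region.membership(devmap.geometry)
        region_name = "CENTRAL_ELLIPSE"
    cats = devmap.categories[member]
    n_region = int(cats.size)
    n_excluded = int(np.sum(cats == int(DeviationCategory.EXCLUDED)))
    n_total = n_region if denominator == "raw" else n_region - n_excluded
    if n_total <= 0:
        raise ValueError(
            f"extent undefined over {region_name}: denominator is zero "
            f"({n_region} region pixels, {n_excluded} excluded)"
        )
    counts = {
        key: int(np.sum(cats == int(cat))) for cat, key in CATEGORY_KEYS.items()
    }
    if cumulative:
        counts["abn5"] += counts["abn1"]
        counts["sup95"] += counts["sup99"]
    pct = {key: 100.0 * counts[key] / n_total for key in counts}
    return ExtentSummary(
        region=region_name,
        pct=pct,
        n_total_px=n_total,
        n_excluded_px=n_excluded,
        denominator=denominator,
        cumulative=cumulative,
    )
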