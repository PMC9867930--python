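# Methods

This note documents the models, numerical choices and limitations behind
`macudev`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and what the synthetic-data tests do
and do not demonstrate about real OCT data.

## Coordinate and laterality conventions

All analysis runs in right-eye (OD) orientation: raster row 0 is the most
superior row, column 0 the most temporal column; physical coordinates are
mm relative to the fovea with x increasing nasally and y superiorly, and
pixel positions are pixel centers. Left eyes are mirrored left–right into
this frame before aggregation or classification. The default full-map
raster is 384 × 384 px covering 30° × 25° of scan angle; the desk-scale
geometry used throughout the tests is a square 64 × 64 px window covering
the 24° × 24° superpixel-grid footprint. Degrees convert to millimetres
at 0.3 mm/° (configurable); scan-angle/retinal-distance conversion varies
with axial length in reality, which the package does not model.

## Normative model

The normative database is represented as independent per-pixel Gaussians
N(μ(x), σ²(x)). Category cutoffs are parametric quantiles μ + z·σ with
z ∈ {−2.3263, −1.6449, +1.6449, +2.3263}. Whether the vendor's interval
is pointwise-Gaussian or empirical-quantile is not public; the Gaussian
choice matches the "prediction interval" framing, makes calibration exact
by construction, and is the only variant that can be simulated and
verified without the raw normative scans. Values falling exactly on a
cutoff take the less-extreme category (flagging requires a strict
inequality); negative thickness is the missing-data sentinel and maps to
EXCLUDED.

Default surfaces are radial: μ(r) = base + A·exp(−(r−r₀)²/2w²)·pit(r),
with pit(r) = 1 − exp(−r²/2p²) suppressing the foveola where ganglion
cells are absent. Defaults (GCL: base 12 μm, A 38 μm, r₀ 1.0 mm,
w 0.9 mm, p 0.35 mm; IPL: 18/22/1.1/1.1/0.30) give a perifoveal GCL peak
near 50 μm and central-field averages in the range reported for healthy
eyes on posterior-pole scans (GCL ≈ 25–30 μm, GCIPL ≈ 55–65 μm over the
central 18°). Per-pixel SDs default to a constant 3 μm per layer.

The composed GCIPL model adds means exactly and combines SDs as
σ² = σ²\_g + σ²\_i + 2ρ σ\_g σ\_i. The two layers are anatomically
coupled, so independence (ρ = 0) would understate combined variance;
ρ defaults to 0.5 and is configurable. No age, sex or axial-length
covariate adjustment is modeled.

## Synthetic eyes and cohorts

A simulated thickness raster is

    t(x) = μ(x) − d(x) + b + ε(x),  clipped at 0,

where d is the defect field, b a per-eye scalar offset, and ε per-pixel
noise. The offset SD (default 2 μm) and the pixel-noise SD
√(σ² − σ\_b²) are chosen so that the **marginal** per-pixel SD equals the
normative σ: a healthy eye at noise scale 1 therefore flags exactly 5% of
pixels at each tail in expectation, while eyes still differ realistically
in overall thickness. This between-eye component is essential for the
discrimination experiments — without it the global thickness average has
vanishing within-group variance and every nonzero defect magnitude
produces a saturated AUROC of 1.0. The offset and noise are shared
between GCL and IPL through a latent component with correlation ρ, so
the composed GCIPL model remains calibrated (exactly so when the two
layer SDs are equal, as in the defaults; approximately otherwise).

Defect fields are unit-peak smooth bumps scaled to the requested core
magnitude: arcuate defects follow an arc at eccentricity 1.5 mm (radial
SD 0.6 mm) with a Gaussian angular profile centered 115° from the nasal
horizontal (SD 40°), echoing the shape of macular nerve-fiber-bundle
loss; `hemifield` is a soft logistic step at the horizontal raphe
(superior loss); `diffuse` is uniform. The magnitude parameter is the
**combined GCL+IPL** loss at the defect core, split between the layers
by `gcl_fraction` (default 0.5, both layers thin in glaucoma). Cohorts
draw glaucoma magnitudes from a lognormal (default median 10 μm, log-SD
0.6) and suspect magnitudes from a smaller lognormal mixed with exact
zeros; all randomness derives from one master seed and the spec actually
used for each eye is returned with it.

What the simulator does **not** emulate: OCT speckle, B-scan geometry,
segmentation and alignment error, spatially correlated noise beyond the
single eye-level offset, age-related thinning, or inter-eye correlation
within a patient. Passing tests demonstrate internal consistency of the
analysis chain under the stated generative model, not device-level
accuracy on clinical scans.

## Rendering and parsing

Rendering writes exact palette colors per category (no anti-aliasing)
and then over-draws the annulus boundaries and sector lines in a
reserved overlay color, so parse-by-color recovers every non-overlay
pixel exactly; this round-trip is asserted in the tests. Parsing assigns
the nearest palette color within a per-channel (Chebyshev) tolerance
(default 10) and requires palette colors to be separated by more than
twice the tolerance; everything else becomes EXCLUDED. Real exported
images are anti-aliased and annotated; the tolerance and the Hough
cleanup exist for that case, but pixel-exact recovery is only guaranteed
for images this package rendered.

## Annulus fit and Hough cleanup

The annulus is fitted from the overlay-ink mask of the grayscale image
(intensity < 60 of 255 by default). Straight sector lines are first
detected by a standard infinite-line Hough transform (1° angular and 1 px
radial resolution, peak threshold 0.5 × accumulator maximum with an
absolute floor of 20 votes, at most 12 peaks) and stripped from the mask;
remaining candidates are split into outer- and inner-boundary sets by
normalized radius relative to a prior annulus (band half-width 15%), and
each set is fitted with the numerically stable direct least-squares
ellipse fit (algebraic distance minimized under the ellipse-specific
constraint 4ac − b² = 1, with centering/scaling for conditioning).
Rotation is estimated but expected ≈ 0 for the axis-aligned clinical
annulus. The fit needs at least 6 candidate pixels per boundary and
raises otherwise. The "4.8 × 4.0 mm" and "1.2 × 1.0 mm" region sizes are
interpreted as full diameters, i.e. semi-axes (2.4, 2.0) and (0.6, 0.5)
mm.

Overlay-line removal reassigns to EXCLUDED the candidate-mask pixels
lying within a 1 px band of a detected line; pixels outside the candidate
mask, or farther from every detected line, are never modified. Detecting
zero lines is a valid outcome and leaves the map untouched.

## Extents

Extents are 100 · n\_category / n\_total. The four reported categories
are disjoint percentile bands by default (abn5 means 1% ≤ P < 5%), with a
switch for cumulative reporting. Annulus membership uses the
pixel-center rule: inside-or-on the outer ellipse and strictly outside
the inner one. The denominator excludes EXCLUDED pixels by default —
overlay and background pixels carry no thickness information — with a
`raw` policy available that keeps them; the policy is recorded with every
result. A zero denominator (e.g. an all-missing raster) raises rather
than returning NaN.

## Statistics

AUROC is the normalized Mann–Whitney U (ties count ½), with thickness
measures auto-oriented lower-is-diseased and extent measures
higher-is-diseased, overridable. Its variance, and the covariance of two
AUROCs measured on the same eyes, use the sample (co)variances of the
per-case and per-control placement components V₁₀, V₀₁ computed via
midranks; a single case or control contributes zero component variance.
The paired comparison refers z = ΔAUC/√(var\_A + var\_B − 2 cov) to the
standard normal, two-sided; a non-positive denominator (exact
self-comparison) is flagged degenerate with z = 0, p = 1 instead of
dividing by zero. Wilcoxon comparisons use the rank-sum form between
groups and the signed-rank form for within-eye GCL-vs-GCIPL contrasts,
with exact small-sample p-values when both groups have ≤ 25 tie-free
observations and the tie-corrected normal approximation otherwise;
all-zero paired differences are degenerate with p = 1. No
multiple-testing adjustment is applied by default. Eyes are treated as
independent — inter-eye correlation within patients is a documented
limitation of both the original analysis style and this implementation.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale by design: 64 px
rasters for simulation-heavy checks, 200 px for geometric recovery, 100–
200 eyes per cohort, 2 000 replicates for the null-level check of the
paired AUC test, and 10⁶ pixel draws for Monte-Carlo calibration (asserted
within 3 standard errors). The direct ellipse fit recovers rendered
boundaries to well under one pixel pitch; the acceptance tolerance of one
pitch absorbs rasterization plus ±0.5 px boundary jitter. Exact-at-cutoff
classification is verified exactly where the standardized value is
float-exact (upper cutoffs with a mean-0/SD-1 model) and to ±10 ulps
around all four cutoffs otherwise, since mean + z·σ is generally not
exactly representable.

## Known limitations

* The 5+5 macular sector membership is a documented approximation
  (angular wedges over the central 48 superpixels, mirror-symmetric about
  the horizontal midline); the published sectorization exists only as a
  figure, so the `SectorMap` is data-configurable.
* The global average uses the central 6 × 6 superpixels (18° × 18° at
  3°/superpixel); whether vendor exports average 36 or 64 cells is not
  derivable from text alone.
* Percentile classification is pointwise-Gaussian; quantile-based
  normative databases with skewed pixels would differ in the tails.
* Pixel-exact parsing assumes images rendered by this package; vendor
  exports with anti-aliasing or compression will push edge pixels to
  EXCLUDED and slightly shrink denominators under the default policy.
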