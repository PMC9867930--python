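# macudev

Quantification of macular OCT **deviation maps** and comparison of
**ganglion cell layer (GCL)** versus **ganglion cell / inner plexiform
layer (GCIPL)** thickness measures for early-glaucoma discrimination —
together with a synthetic-cohort simulator so that every stage of the
analysis is testable without patient data.

Glaucoma destroys retinal ganglion cells; their somas concentrate in the
macular GCL, and spectral-domain OCT can segment the GCL and IPL
separately. A *deviation map* compares each pixel of a measured thickness
raster against a normative database and color-codes it by percentile:
red (P < 1%), yellow (P < 5%), green (within the 5–95% interval), blue
(P > 95%), pink (P > 99%). The package is aimed at reading-center and
imaging-research workflows that need reproducible, scriptable versions of
the vendor's map analytics: classify rasters, quantify flagged extents,
aggregate posterior-pole superpixel grids into macular sectors, and
compare the discriminative performance of competing measures.

## What it computes

**Normative model and classification** (`macudev.normative`). The
normative database is modeled as per-pixel Gaussians with mean surface
μ(x) and SD surface σ(x); the category of a pixel with thickness *t* is
determined by z = (t − μ)/σ against the standard normal quantiles
z₀.₀₁ = −2.3263 and z₀.₀₅ = −1.6449:

    z < z₀.₀₁            → abnormal (red)
    z₀.₀₁ ≤ z < z₀.₀₅    → borderline (yellow)
    z₀.₀₅ ≤ z ≤ −z₀.₀₅   → within normal limits (green)
    −z₀.₀₅ < z ≤ −z₀.₀₁  → supernormal (blue)
    z > −z₀.₀₁           → supernormal (pink)

A GCIPL model is composed from GCL + IPL: means add;
σ²\_GCIPL = σ²\_GCL + σ²\_IPL + 2ρ σ\_GCL σ\_IPL with inter-layer
correlation ρ (default 0.5).

**Extent quantification** (`macudev.devmap`). Rendered map images are
parsed back to categories by palette color; the perifoveal elliptical
annulus (outer 4.8 × 4.0 mm, inner exclusion 1.2 × 1.0 mm) is recovered
by direct least-squares ellipse fitting of its drawn boundaries; straight
sector lines are detected with a Hough transform and excluded; extents
are reported as 100 · n\_category / n\_total over the entire scan and
over the annulus.

**Sector aggregation** (`macudev.sectors`). 8 × 8 superpixel grids
(3° × 3° cells) are averaged into 5 superior + 5 inferior macular sectors
and a global mean over the central 6 × 6 window (18° × 18°).

**Statistics** (`macudev.stats`). AUROC by the Mann–Whitney
construction; variance and paired comparison of two correlated AUROCs
from the structural components (placements) V₁₀, V₀₁, with
z = (AUC\_A − AUC\_B)/√(var\_A + var\_B − 2 cov); Wilcoxon rank-sum and
signed-rank tests; cohort summary tables.

**Simulation** (`macudev.simulate`). Synthetic eyes with anatomically
shaped normative surfaces (foveal pit, perifoveal ridge), between-eye
thickness offsets, correlated GCL/IPL noise calibrated so healthy eyes
flag ~5% of pixels at each tail, arcuate / hemifield / diffuse defects of
controllable magnitude, OS mirroring, and pixel-exact rendered map images.

## Worked example

```python
import numpy as np
from macudev import (AnnulusSpec, CohortSpec, EyeSpec, auroc,
                     classify_thickness, default_gcl_model,
                     default_ipl_model, desk_geometry, extent_summary,
                     simulate_cohort, simulate_eye)
from macudev.sectors import global_mean

geometry = desk_geometry(64)                      # 64x64 px over 24x24 deg
gcl = default_gcl_model(geometry)
ipl = default_ipl_model(geometry)

spec = EyeSpec(group="GLAUCOMA", defect_magnitude=20.0,
               defect_shape="arcuate_inferior", seed=7)
thickness, _ = simulate_eye(gcl, ipl, spec)
devmap = classify_thickness(gcl, thickness)

annulus = AnnulusSpec(center_px=geometry.fovea_px)
scan = extent_summary(devmap, "ENTIRE_SCAN")
ell = extent_summary(devmap, annulus)
print(f"abnormal extent (P<1%): scan {scan.pct['abn1']:.1f}%, "
      f"central ellipse {ell.pct['abn1']:.1f}%")

eyes = simulate_cohort(gcl, ipl, {"NORMAL": 100, "GLAUCOMA": 100},
                       CohortSpec(glaucoma_median_um=10.0), seed=1)
scores = {"NORMAL": [], "GLAUCOMA": []}
for eye in eyes:
    scores[eye.spec.group].append(global_mean(eye.grid_gcl))
res = auroc(scores["GLAUCOMA"], scores["NORMAL"],
            "lower_value_indicates_disease")
print(f"global GCL thickness AUROC: {res.auc:.3f} "
      f"(SE {np.sqrt(res.variance):.3f})")
```

prints

```
abnormal extent (P<1%): scan 3.0%, central ellipse 10.2%
global GCL thickness AUROC: 0.684 (SE 0.038)
```

The simulated eye has a 20 μm inferior-arcuate defect: 3.0% of the scan
is below the 1st normative percentile, rising to 10.2% inside the
perifoveal annulus where the defect concentrates. Across a cohort with a
10 μm median defect, global GCL thickness separates glaucoma from
healthy eyes with AUROC 0.684.

A full pipeline run (simulate → classify → render → parse → annulus fit →
Hough cleanup → extents → sectors → tables) is available as a CLI:

```sh
macudev run-all --seed 1 --out my_run
```

which writes `manifest.csv`, `features.csv`, per-eye grid CSVs, and three
summary tables (thickness AUROCs with paired contrasts, extent group
summaries with Wilcoxon p-values, extent AUROCs), each headed by the
run's config hash and seed.

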