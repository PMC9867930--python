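"""Discrimination and group-comparison statistics.

AUROC is computed by the Mann-Whitney construction: the probability that
a randomly chosen diseased eye ranks diseased-ward of a randomly chosen
control, with ties counting one half.  Its variance, and the covariance
between two AUROCs measured on the same eyes, come from the structural
components ``V10`` (one per case) and ``V01`` (one per control); the
paired comparison of two correlated AUROCs is the classical nonparametric
z-test built from those components.  Group comparisons use Wilcoxon
rank-sum (unpaired) or signed-rank (paired, for within-eye layer
contrasts) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AUROCResult",
    "DeLongComparison",
    "WilcoxonResult",
    "auroc",
    "delong_test",
    "wilcoxon_group",
    "cohort_tables",
]

ORIENTATIONS = ("lower_value_indicates_disease", "higher_value_indicates_disease")


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    scores = np.asarray(scores, dtype=float)
    return -scores if orientation == "lower_value_indicates_disease" else scores


def _structural_components(
    cases: np.ndarray, controls: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and structural components via midranks.

    ``V10[i]`` is the placement of case i among the controls (the fraction
    of controls it beats, ties half); ``V01[j]`` the placement of control
    j among the cases, oriented so that ``mean(V10) = mean(V01) = AUC``.
    """
    m, n = len(cases), len(controls)
    allv = np.concatenate([cases, controls])
    r_all = sps.rankdata(allv)
    r_cases = sps.rankdata(cases)
    r_controls = sps.rankdata(controls)
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


@dataclass
class AUROCResult:
    """AUC with its nonparametric (structural-component) variance."""

    auc: float
    variance: float
    n_case: int
    n_control: int
    orientation: str


@dataclass
class DeLongComparison:
    """Paired comparison of two correlated AUROCs."""

    auc_a: float
    auc_b: float
    cov: np.ndarray          # 2 x 2 covariance of (auc_a, auc_b)
    z: float
    p: float
    degenerate: bool = False


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    method: str
    degenerate: bool = False


def auroc(
    case_scores,
    control_scores,
    orientation: str = "higher_value_indicates_disease",
) -> AUROCResult:
    """AUC of a scalar score for cases versus controls.

    Equivalent to brute-force pair counting: the mean over all
    case-control pairs of 1 (case diseased-ward), 1/2 (tied), 0.  The
    variance uses the sample variances of the structural components; with
    a single case or control the corresponding component variance is 0.
    """
    cases = _oriented(case_scores, orientation)
    controls = _oriented(control_scores, orientation)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    auc, v10, v01 = _structural_components(cases, controls)
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    var = s10 / v10.size + s01 / v01.size
    return AUROCResult(auc, var, int(cases.size), int(controls.size), orientation)


def delong_test(
    scores_a,
    scores_b,
    labels,
    orientation: str = "higher_value_indicates_disease",
    orientation_b: str | None = None,
) -> DeLongComparison:
    """Nonparametric comparison of two AUCs measured on the same eyes.

    ``labels`` is a boolean/0-1 vector (1 = case).  The covariance of the
    two AUCs comes from the paired structural components; the z statistic
    is ``(auc_a - auc_b) / sqrt(var_a + var_b - 2 cov)`` referred to the
    standard normal, two-sided.  A non-positive denominator (e.g. the
    self-comparison) is reported as degenerate with z = 0, p = 1.
    """
    labels = np.asarray(labels, dtype=bool)
    a = _oriented(scores_a, orientation)
    b = _oriented(scores_b, orientation_b or orientation)
    if a.shape != labels.shape or b.shape != labels.shape:
        raise ValueError("scores and labels must have equal length (paired design)")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    auc_a, v10a, v01a = _structural_components(a[labels], a[~labels])
    auc_b, v10b, v01b = _structural_components(b[labels], b[~labels])
    m, n = int(labels.sum()), int((~labels).sum())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    denom2 = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if denom2 <= 0 or not np.isfinite(denom2):
        return DeLongComparison(auc_a, auc_b, cov, 0.0, 1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(denom2)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, cov, float(z), p)


def wilcoxon_group(values_1, values_2, paired: bool = False) -> WilcoxonResult:
    """Wilcoxon comparison of two groups of measurements.

    Unpaired: rank-sum (Mann-Whitney U) test, exact for small tie-free
    samples (both groups <= 25), normal approximation with tie correction
    otherwise.  Paired: signed-rank test on the within-eye differences
    with the same exact/approximate switching; all-zero differences are a
    degenerate case reported as p = 1.
    """
    v1 = np.asarray(values_1, dtype=float)
    v2 = np.asarray(values_2, dtype=float)
    if paired:
        if v1.shape != v2.shape:
            raise ValueError("paired comparison requires equal-length vectors")
        d = v1 - v2
        if np.allclose(d, 0.0):
            return WilcoxonResult(0.0, 1.0, "signed_rank", degenerate=True)
        small = d.size <= 25
        has_ties = np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)
        method = "exact" if (small and not has_ties) else "approx"
        res = sps.wilcoxon(v1, v2, zero_method="wilcox", method=method)
        return WilcoxonResult(float(res.statistic), float(res.pvalue), "signed_rank")
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both groups must be non-empty")
    small = max(v1.size, v2.size) <= 25
    has_ties = np.unique(np.concatenate([v1, v2])).size < v1.size + v2.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(v1, v2, alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), "rank_sum")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

SECTOR_COLUMNS = [f"S{i}" for i in range(1, 6)] + [f"I{i}" for i in range(1, 6)]
EXTENT_MEASURES = [
    ("abn1", "CENTRAL_ELLIPSE"),
    ("abn5", "CENTRAL_ELLIPSE"),
    ("abn1", "ENTIRE_SCAN"),
    ("abn5", "ENTIRE_SCAN"),
    ("sup95", "CENTRAL_ELLIPSE"),
    ("sup99", "CENTRAL_ELLIPSE"),
    ("sup95", "ENTIRE_SCAN"),
    ("sup99", "ENTIRE_SCAN"),
]


def _require_columns(features: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing required columns: {missing}")


def _extent_col(layer: str, key: str, region: str) -> str:
    tag = "ellipse" if region == "CENTRAL_ELLIPSE" else "scan"
    return f"{layer.lower()}_{tag}_{key}_pct"


def cohort_tables(
    features: pd.DataFrame,
    case_group: str = "GLAUCOMA",
    control_groups: tuple[str, ...] = ("NORMAL", "SUSPECT"),
    thickness_controls: tuple[str, ...] = ("NORMAL",),
) -> dict[str, pd.DataFrame]:
    """Build the three cohort summary tables from a per-eye feature table.

    Expected wide format: one row per eye with ``eye_id``, ``group``,
    per-layer sector/global thickness columns (``gcl_S1`` ... ``gcl_I5``,
    ``gcl_global``, same for ``gcipl``) and extent columns
    (``gcl_scan_abn1_pct`` etc.).  Returns:

    * ``thickness_auroc`` — per-sector and global AUROC of GCL and GCIPL
      thickness (lower = disease) with the paired z-test p for each
      GCL-vs-GCIPL contrast;
    * ``extent_groups`` — group mean +/- SD of each extent measure per
      layer with the paired signed-rank p for GCL vs GCIPL within group;
    * ``extent_auroc`` — AUROC of the abnormal-extent measures (higher =
      disease) with the paired z-test p.
    """
    _require_columns(features, ["eye_id", "group"])
    groups = set(features["group"])
    if case_group not in groups:
        raise ValueError(f"no eyes in case group {case_group!r}")

    def _mask(control_set: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        present = [g for g in control_set if g in groups]
        if not present:
            raise ValueError(f"no eyes in any control group {control_set!r}")
        keep = features["group"].isin([case_group, *present]).to_numpy()
        labels = (features["group"] == case_group).to_numpy()[keep]
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise ValueError("need at least 2 cases and 2 controls for AUROC tables")
        return keep, labels

    # -- thickness AUROC (sectoral + global) -----------------------------
    keep, labels = _mask(thickness_controls)
    thick_cols = [f"{lay}_{s}" for lay in ("gcl", "gcipl") for s in SECTOR_COLUMNS]
    _require_columns(features, thick_cols + ["gcl_global", "gcipl_global"])
    rows = []
    for name in SECTOR_COLUMNS + ["global"]:
        ga = features.loc[keep, f"gcl_{name}" if name != "global" else "gcl_global"]
        gb = features.loc[keep, f"gcipl_{name}" if name != "global" else "gcipl_global"]
        ra = auroc(ga[labels], ga[~labels], "lower_value_indicates_disease")
        rb = auroc(gb[labels], gb[~labels], "lower_value_indicates_disease")
        cmpres = delong_test(
            ga.to_numpy(), gb.to_numpy(), labels, "lower_value_indicates_disease"
        )
        rows.append(
            {
                "measure": name,
                "auc_gcl": ra.auc,
                "auc_gcipl": rb.auc,
                "z": cmpres.z,
                "p_value": cmpres.p,
            }
        )
    thickness_auroc = pd.DataFrame(rows)

    # -- extent group summaries (GCL vs GCIPL within group) --------------
    ext_cols = [
        _extent_col(lay, key, region)
        for lay in ("gcl", "gcipl")
        for key, region in EXTENT_MEASURES
    ]
    _require_columns(features, ext_cols)
    control_present = [g for g in control_groups if g in groups]
    rows = []
    for key, region in EXTENT_MEASURES:
        for gname, sel in (
            ("control", features["group"].isin(control_present).to_numpy()),
            ("glaucoma", (features["group"] == case_group).to_numpy()),
        ):
            g = features.loc[sel, _extent_col("gcl", key, region)].to_numpy()
            gi = features.loc[sel, _extent_col("gcipl", key, region)].to_numpy()
            w = wilcoxon_group(g, gi, paired=True)
            rows.append(
                {
                    "measure": key,
                    "region": region,
                    "group": gname,
                    "gcl_mean": np.mean(g),
                    "gcl_sd": np.std(g, ddof=1),
                    "gcipl_mean": np.mean(gi),
                    "gcipl_sd": np.std(gi, ddof=1),
                    "p_value": w.p,
                }
            )
    extent_groups = pd.DataFrame(rows)

    # -- extent AUROC (abnormal measures, higher extent = disease) -------
    keep, labels = _mask(control_groups)
    rows = []
    for key, region in EXTENT_MEASURES[:4]:
        ga = features.loc[keep, _extent_col("gcl", key, region)].to_numpy()
        gb = features.loc[keep, _extent_col("gcipl", key, region)].to_numpy()
        ra = auroc(ga[labels], ga[~labels], "higher_value_indicates_disease")
        rb = auroc(gb[labels], gb[~labels], "higher_value_indicates_disease")
        cmpres = delong_test(ga, gb, labels, "higher_value_indicates_disease")
        rows.append(
            {
                "measure": key,
                "region": region,
                "auc_gcl": ra.auc,
                "auc_gcipl": rb.auc,
                "z": cmpres.z,
                "p_value": cmpres.p,
            }
        )
    extent_auroc = pd.DataFrame(rows)

    return {
        "thickness_auroc": thickness_auroc,
        "extent_groups": extent_groups,
        "extent_auroc": extent_auroc,
    }
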