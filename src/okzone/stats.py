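"""Cohort-level statistics and reporting.

The clinical-reporting toolkit: pooled two-sample t-tests, Pearson
correlation with the weak/moderate/strong banding at |R| = 0.3 and 0.7,
Kolmogorov–Smirnov normality testing with estimated parameters (Lilliefors
p-values), decentration/astigmatism cohort summaries with the 0.5 mm
centration threshold and quadrant percentage tables, and violin-plot data
export (values plus Gaussian-kernel density curves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "StatResult",
    "CohortSummary",
    "two_sample_ttest",
    "pearson_r",
    "correlation_band",
    "ks_normality",
    "summarize_cohort",
    "violin_data",
]

ALPHA = 0.05  # the 95% confidence level used throughout
CENTRATION_THRESHOLD_MM = 0.5


@dataclass
class StatResult:
    """A test statistic with its p-value and context."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    test: str
    band: str | None = None  # correlation strength label, Pearson only

    @property
    def reject(self) -> bool:
        return self.p_value < ALPHA


def two_sample_ttest(a, b, equal_var: bool = True) -> StatResult:
    """Two-sided two-sample t-test (pooled variance by default; Welch optional).

    Two identical constant samples yield t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    name = "two-sample t-test" if equal_var else "Welch t-test"
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return StatResult(0.0, 1.0, (a.size, b.size), name)
        return StatResult(np.inf, 0.0, (a.size, b.size), name)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(float(res.statistic), float(res.pvalue), (a.size, b.size), name)


def correlation_band(r: float) -> str:
    """Strength label for |R|: weak below 0.3, moderate 0.3–0.7, strong above 0.7."""
    r = abs(r)
    if r < 0.3:
        return "weak"
    if r <= 0.7:
        return "moderate"
    return "strong"


def pearson_r(x, y) -> StatResult:
    """Pearson linear correlation with strength banding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance sample: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return StatResult(r, float(res.pvalue), (x.size,), "Pearson correlation", correlation_band(r))


def ks_normality(sample) -> StatResult:
    """Kolmogorov–Smirnov normality test against N(sample mean, sample SD).

    Because the reference parameters are estimated from the sample, the
    p-value comes from the Lilliefors distribution of the KS statistic (the
    naive KS p-value would be anti-conservative in the statistic but
    conservative in p, i.e. simply wrong).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 5:
        raise ValueError("need at least 5 observations")
    if np.std(sample) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = lilliefors(sample, dist="norm")
    return StatResult(float(stat), float(p), (sample.size,), "Lilliefors KS normality")


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

_CATEGORIES = ("small", "moderate", "large")


@dataclass
class CohortSummary:
    """Cohort decentration/astigmatism summary tables."""

    records: pd.DataFrame
    per_laterality: pd.DataFrame  # mean/SD radius, circular + arithmetic angle stats
    quadrant_table: pd.DataFrame  # percentage per quarter among decentred eyes + centred share
    category_astigmatism: pd.DataFrame  # astig-change mean/SD per decentration category
    category_tests: pd.DataFrame  # pairwise t-tests between categories
    correlations: pd.DataFrame  # decentration vs pre/post/change astigmatism


def _circular_mean_sd(angles_deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(angles_deg)
    mean = float(np.rad2deg(sps.circmean(rad)) % 360.0)
    sd = float(np.rad2deg(sps.circstd(rad)))
    return mean, sd


def summarize_cohort(records: pd.DataFrame | list[dict]) -> CohortSummary:
    """Summarise per-eye analysis records.

    Expects columns ``laterality``, ``radius_mm``, ``angle_deg_from_nasal``,
    ``quadrant``, ``category``, ``pre_astigmatism_D``, ``post_astigmatism_D``,
    ``astigmatism_change_D``.  Eyes are 'centred' when decentration is at or
    below 0.5 mm; the quadrant percentage table counts only decentred eyes,
    and both shares sum to 100%.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("empty cohort")
    df = df[np.isfinite(df["radius_mm"])].copy()
    if df.empty:
        raise ValueError("no eyes with a detected treatment zone")

    lat_rows = []
    for lat, sub in df.groupby("laterality"):
        cmean, csd = _circular_mean_sd(sub["angle_deg_from_nasal"].to_numpy())
        lat_rows.append(
            {
                "laterality": lat,
                "n": len(sub),
                "radius_mean_mm": sub["radius_mm"].mean(),
                "radius_sd_mm": sub["radius_mm"].std(ddof=1) if len(sub) > 1 else 0.0,
                "angle_circular_mean_deg": cmean,
                "angle_circular_sd_deg": csd,
                "angle_arithmetic_mean_deg": sub["angle_deg_from_nasal"].mean(),
                "angle_arithmetic_sd_deg": (
                    sub["angle_deg_from_nasal"].std(ddof=1) if len(sub) > 1 else 0.0
                ),
            }
        )
    per_lat = pd.DataFrame(lat_rows)

    quad_rows = []
    for lat, sub in df.groupby("laterality"):
        n = len(sub)
        centred = sub["radius_mm"] <= CENTRATION_THRESHOLD_MM
        row = {"laterality": lat, "n": n, "centred_pct": 100.0 * centred.sum() / n}
        dec = sub[~centred]
        for q in (1, 2, 3, 4):
            row[f"quadrant_{q}_pct"] = 100.0 * (dec["quadrant"] == q).sum() / n
        quad_rows.append(row)
    quad = pd.DataFrame(quad_rows)

    cat_rows = []
    for cat in _CATEGORIES:
        sub = df[df["category"] == cat]
        cat_rows.append(
            {
                "category": cat,
                "n": len(sub),
                "astig_change_mean_D": sub["astigmatism_change_D"].mean() if len(sub) else np.nan,
                "astig_change_sd_D": (
                    sub["astigmatism_change_D"].std(ddof=1) if len(sub) > 1 else np.nan
                ),
            }
        )
    cat_table = pd.DataFrame(cat_rows)

    test_rows = []
    for i in range(len(_CATEGORIES)):
        for j in range(i + 1, len(_CATEGORIES)):
            a = df.loc[df["category"] == _CATEGORIES[i], "astigmatism_change_D"].to_numpy()
            b = df.loc[df["category"] == _CATEGORIES[j], "astigmatism_change_D"].to_numpy()
            if a.size >= 2 and b.size >= 2:
                res = two_sample_ttest(a, b)
                test_rows.append(
                    {
                        "group_a": _CATEGORIES[i],
                        "group_b": _CATEGORIES[j],
                        "t": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.reject,
                    }
                )
    cat_tests = pd.DataFrame(test_rows)

    corr_rows = []
    for label, col in (
        ("decentration_vs_pre_astigmatism", "pre_astigmatism_D"),
        ("decentration_vs_post_astigmatism", "post_astigmatism_D"),
        ("decentration_vs_astigmatism_change", "astigmatism_change_D"),
    ):
        try:
            res = pearson_r(df["radius_mm"], df[col])
            corr_rows.append(
                {"pair": label, "R": res.statistic, "p_value": res.p_value, "band": res.band}
            )
        except ValueError:
            corr_rows.append({"pair": label, "R": np.nan, "p_value": np.nan, "band": None})
    corr = pd.DataFrame(corr_rows)

    return CohortSummary(
        records=df,
        per_laterality=per_lat,
        quadrant_table=quad,
        category_astigmatism=cat_table,
        category_tests=cat_tests,
        correlations=corr,
    )


def violin_data(
    records: pd.DataFrame | list[dict],
    field_name: str,
    category_field: str = "category",
    categories: tuple[str, ...] = _CATEGORIES,
    n_density: int = 200,
) -> dict:
    """Per-category raw values, summary statistics, and normalised density curves.

    Densities use a Gaussian kernel with Silverman's bandwidth and integrate
    to 1; categories with fewer than 2 distinct values are emitted with a
    null density.
    """
    df = pd.DataFrame(records)
    out: dict = {"field": field_name, "categories": {}}
    for cat in categories:
        vals = df.loc[df[category_field] == cat, field_name].dropna().to_numpy(dtype=float)
        entry: dict = {
            "values": vals.tolist(),
            "n": int(vals.size),
            "mean": float(np.mean(vals)) if vals.size else None,
            "median": float(np.median(vals)) if vals.size else None,
        }
        if vals.size >= 2 and np.std(vals) > 0:
            kde = sps.gaussian_kde(vals, bw_method="silverman")
            lo = vals.min() - 3 * kde.factor * vals.std(ddof=1)
            hi = vals.max() + 3 * kde.factor * vals.std(ddof=1)
            xs = np.linspace(lo, hi, n_density)
            entry["density_x"] = xs.tolist()
            entry["density_y"] = kde(xs).tolist()
        else:
            entry["density_x"] = None
            entry["density_y"] = None
        out["categories"][cat] = entry
    return out
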