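"""Cohort-level statistics: normality screening, log transform, walking-speed
adjustment and one-way ANOVA across groups or dizziness-handicap subgroups.

The inferential pipeline mirrors standard practice in clinical gait studies:
each feature is screened for normality with a Kolmogorov-Smirnov test
(Lilliefors variant by default, since the comparison normal has its
parameters estimated from the sample), positively skewed features are
log10-transformed, walking-stability features are adjusted for walking speed
by pooled OLS residualisation, and group differences are tested with classic
fixed-effects one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "normality_screen",
    "NormalityResult",
    "speed_adjust",
    "one_way_anova",
    "AnovaResult",
    "assign_dhi_subgroup",
    "group_comparison",
    "DHI_STAGES",
]

#: inclusive DHI score ranges of the three severity stages
DHI_STAGES = {"mild": (0, 30), "moderate": (31, 60), "severe": (61, 100)}


@dataclass
class NormalityResult:
    status: str  # "normal" | "skewed" | "degenerate"
    p_value: float
    transform: str  # "none" | "log10"
    values: np.ndarray  # transformed (or original) values
    flag: str = ""


def normality_screen(
    values, alpha: float = 0.05, method: str = "lilliefors"
) -> NormalityResult:
    """KS-screen a feature and log10-transform it when positively skewed.

    A feature is transformed when the KS test rejects normality at ``alpha``
    AND the sample skewness is positive; a skewed feature containing
    non-positive values cannot be log-transformed and is flagged instead.
    ``method="fitted"`` uses the plain KS test against a normal with the
    sample's mean/SD; the default Lilliefors variant corrects that test for
    the estimated parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for the normality screen")
    if np.ptp(x) < 1e-300:
        return NormalityResult("degenerate", np.nan, "none", x, flag="all values identical")
    if method == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    elif method == "fitted":
        _, p = sp_stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError("method must be 'lilliefors' or 'fitted'")
    skew = sp_stats.skew(x, bias=False)
    if p >= alpha or skew <= 0:
        return NormalityResult("normal" if p >= alpha else "skewed", float(p), "none", x)
    if np.any(x <= 0):
        return NormalityResult(
            "skewed", float(p), "none", x,
            flag="log10 transform skipped: non-positive values",
        )
    return NormalityResult("skewed", float(p), "log10", np.log10(x))


def speed_adjust(values, walking_speeds) -> np.ndarray:
    """Remove the linear influence of walking speed from a feature.

    Fits feature ~ speed by OLS over all subjects pooled and returns the
    residuals re-centred on the grand mean, so adjusted values carry the
    original scale but zero sample correlation with speed.  Idempotent.
    """
    y = np.asarray(values, dtype=float)
    s = np.asarray(walking_speeds, dtype=float)
    if y.shape != s.shape or y.size < 3:
        raise ValueError("values and speeds must be equal-length with >= 3 entries")
    if s.std(ddof=1) < 1e-300:
        import warnings

        warnings.warn("walking speeds have zero variance; returning values unchanged")
        return y.copy()
    slope, intercept = np.polyfit(s, y, 1)
    return y - (slope * s + intercept) + y.mean()


@dataclass
class AnovaResult:
    feature: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict
    group_sds: dict
    transform: str = "none"
    speed_adjusted: bool = False


def _anova_f(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """Classic fixed-effects F = MS_between / MS_within."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n_total - k
    if ss_within < 1e-300:
        f = 0.0 if ss_between < 1e-300 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return f, df_b, df_w


def one_way_anova(*groups, feature: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA over two or more groups of values."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    f, df_b, df_w = _anova_f(arrays)
    if np.isinf(f):
        p = 0.0
    elif f == 0.0:
        p = 1.0
    else:
        p = float(sp_stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        feature=feature,
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_means={i: float(a.mean()) for i, a in enumerate(arrays)},
        group_sds={i: float(a.std(ddof=1)) for i, a in enumerate(arrays)},
    )


def anova_f_vectorized(data: np.ndarray) -> np.ndarray:
    """F statistics for a stack of balanced one-way layouts.

    ``data`` has shape (n_sims, k, n): each slice is one dataset of k groups
    with n observations each.  Used for calibration simulations.
    """
    n_sims, k, n = data.shape
    group_means = data.mean(axis=2)
    grand = data.mean(axis=(1, 2))
    ss_b = n * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    ss_w = ((data - group_means[:, :, None]) ** 2).sum(axis=(1, 2))
    return (ss_b / (k - 1)) / (ss_w / (k * n - k))


def assign_dhi_subgroup(dhi: int) -> str:
    """Stage a dizziness-handicap score: 0-30 mild, 31-60 moderate,
    61-100 severe."""
    if not 0 <= dhi <= 100:
        raise ValueError(f"DHI score {dhi} outside 0-100")
    for stage, (lo, hi) in DHI_STAGES.items():
        if lo <= dhi <= hi:
            return stage
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# cohort-level report

#: features that are adjusted for walking speed before testing
def _is_stability_feature(name: str) -> bool:
    return name.startswith(("trunk_", "head_"))


def group_comparison(
    features: pd.DataFrame,
    group_col: str = "group",
    groups: list[str] | None = None,
    alpha: float = 0.05,
    speed_col: str = "walking_speed",
    ks_method: str = "lilliefors",
    adjust_speed: bool = True,
) -> pd.DataFrame:
    """Run the full statistical pipeline over a subject-level feature table.

    For every numeric feature column: normality screen (with log10 transform
    of positively skewed features), walking-speed adjustment of the
    stability features, then one-way ANOVA across ``groups`` (default: every
    level of ``group_col`` present).  Returns one row per feature with group
    means/SDs on the analysed scale, F, p and the processing flags.
    """
    if groups is None:
        groups = [g for g in ("healthy", "mild", "moderate", "severe") if g in set(features[group_col])]
        if len(groups) < 2:
            groups = sorted(set(features[group_col]))
    sub = features[features[group_col].isin(groups)]
    skip = {group_col, "subject_id", "dhi", "sex"}
    rows = []
    for col in sub.columns:
        if col in skip or not pd.api.types.is_numeric_dtype(sub[col]):
            continue
        vals = sub[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            continue
        screen = normality_screen(vals, alpha=alpha, method=ks_method)
        analysed = screen.values
        adjusted = False
        if adjust_speed and _is_stability_feature(col):
            analysed = speed_adjust(analysed, sub[speed_col].to_numpy(dtype=float))
            adjusted = True
        labels = sub[group_col].to_numpy()
        res = one_way_anova(*[analysed[labels == g] for g in groups], feature=col)
        row = {
            "feature": col,
            "transform": screen.transform,
            "speed_adjusted": adjusted,
            "F": res.f_statistic,
            "p": res.p_value,
        }
        for g in groups:
            gv = analysed[labels == g]
            row[f"mean_{g}"] = gv.mean()
            row[f"sd_{g}"] = gv.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)
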