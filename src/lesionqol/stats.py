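"""Correlation screens, group comparisons and effect-size grading.

The screening layer follows the study design it implements: mass-univariate
rank correlations (tie-corrected Kendall tau-b) between lesion-region
overlap and HRQoL scale scores at alpha = 0.001, Pearson correlations
between within-network connectivity and the scales at alpha = 0.01, and
left-vs-right group comparisons by two-sided Mann-Whitney U tests.  No
multiple-testing correction is applied: these are screens, not confirmatory
inference, and the thresholds themselves act as the (informal) stringency
control.

Effect sizes are graded by Cohen's conventions (d at 0.2 / 0.5 / 0.8,
correlation magnitude at 0.1 / 0.3 / 0.5, lower bounds inclusive) and HRQoL
mean differences by the Osoba clinical-importance bands (5-10 minimal,
10-20 moderate, > 20 very much; boundaries assigned upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ScreenResult",
    "kendall_tau_b",
    "pearson_r",
    "mann_whitney_u",
    "chi_square_2x2",
    "cohens_d",
    "classify_d",
    "classify_r",
    "classify_mcid",
    "stars",
    "lesion_hrqol_screen",
    "rsfc_hrqol_screen",
    "volume_hrqol_correlations",
    "laterality_comparison",
]


STAT_RESULT_FIELDS = (
    "predictor", "outcome", "method", "estimate", "p_value", "n",
    "significant", "undefined",
)


@dataclass
class StatResult:
    """One association or comparison: estimate, two-sided p, and context."""

    predictor: str
    outcome: str
    method: str
    estimate: float
    p_value: float
    n: int
    significant: bool = False
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ScreenResult:
    """Mass-univariate screen output: p and estimate matrices plus hits.

    ``p_values`` and ``estimates`` are predictor x scale DataFrames (NaN for
    undefined cells, e.g. constant predictors); ``significant`` lists the
    cells below ``alpha`` as StatResults.
    """

    p_values: pd.DataFrame
    estimates: pd.DataFrame
    alpha: float
    method: str
    significant: list[StatResult] = field(default_factory=list)


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation, two-sided.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and n1, n2
    the tie terms of the two variables.  The p-value uses the tie-corrected
    normal approximation (exact enumeration for small tie-free samples).
    Missing values are dropped pairwise; a constant input makes the
    denominator zero, which is reported as (nan, nan) for the caller to flag
    rather than silently propagated.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"kendall_tau_b requires n >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    method = "exact" if (n <= 10 and not has_ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Two-sided Pearson correlation on pairwise-complete observations."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 3:
        raise ValueError(f"pearson_r requires n >= 3 complete pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.pearsonr(x, y)
    if np.isnan(res.statistic):
        return float("nan"), float("nan")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with average ranks for ties.

    Uses exact enumeration for small tie-free samples and the tie-corrected
    normal approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("mann_whitney_u requires both groups nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def cohens_d(a, b) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def classify_d(d: float) -> str:
    """Cohen's d magnitude class; lower bounds inclusive."""
    m = abs(d)
    if np.isnan(m):
        return "undefined"
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "medium"
    if m >= 0.2:
        return "small"
    return "negligible"


def classify_r(r: float) -> str:
    """Correlation magnitude class (0.1 / 0.3 / 0.5, lower bounds inclusive)."""
    m = abs(r)
    if np.isnan(m):
        return "undefined"
    if m >= 0.5:
        return "large"
    if m >= 0.3:
        return "medium"
    if m >= 0.1:
        return "small"
    return "negligible"


def classify_mcid(score_difference: float) -> str:
    """Clinical-importance band of a 0-100 score difference (sign ignored).

    < 5 trivial, 5-10 minimal, 10-20 moderate, > 20 very much; the 10 and 20
    boundaries go to the higher class.
    """
    m = abs(score_difference)
    if np.isnan(m):
        return "undefined"
    if m > 20:
        return "very_much"
    if m >= 10:
        return "moderate"
    if m >= 5:
        return "minimal"
    return "trivial"


def stars(p: float) -> str:
    """Significance star coding at 0.05 / 0.01 / 0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------- screens

def _correlation_screen(
    predictors: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float,
    method: str,
) -> ScreenResult:
    corr = kendall_tau_b if method == "kendall_tau_b" else pearson_r
    common = predictors.index.intersection(scores.index)
    if len(common) < 10:
        raise ValueError(
            f"screen requires >= 10 subjects with both data types, got {len(common)}"
        )
    X = predictors.loc[common]
    Y = scores.loc[common]
    p_mat = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    e_mat = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    hits: list[StatResult] = []
    for pcol in X.columns:
        xv = X[pcol].to_numpy(dtype=float)
        for scol in Y.columns:
            est, p = corr(xv, Y[scol].to_numpy(dtype=float))
            p_mat.loc[pcol, scol] = p
            e_mat.loc[pcol, scol] = est
            if not np.isnan(p) and p < alpha:
                hits.append(
                    StatResult(str(pcol), str(scol), method, est, p,
                               int((~(np.isnan(xv) | Y[scol].isna())).sum()),
                               significant=True)
                )
    return ScreenResult(p_mat, e_mat, alpha, method, hits)


def lesion_hrqol_screen(
    overlaps: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.001,
    measure: str = "overlap_ml",
) -> ScreenResult:
    """Kendall tau-b screen of region overlap against every HRQoL scale.

    ``overlaps`` is the tidy overlap table; each (lesion type, region) pair
    becomes one predictor column using ``measure`` (``overlap_ml`` by
    default, ``overlap_fraction`` as the alternative — Kendall depends only
    on ranks, so for a fixed region both give identical results).  Cells
    with a constant predictor (e.g. a region no lesion ever touches) are
    undefined and excluded from the significant list.
    """
    if measure not in ("overlap_ml", "overlap_fraction"):
        raise ValueError(f"unknown overlap measure {measure!r}")
    wide = overlaps.pivot_table(
        index="subject",
        columns=["lesion_type", "atlas", "region_name"],
        values=measure,
    )
    wide.columns = [f"{t}:{a}:{r}" for t, a, r in wide.columns]
    return _correlation_screen(wide, scores, alpha, "kendall_tau_b")


def rsfc_hrqol_screen(
    wnc: pd.DataFrame, scores: pd.DataFrame, alpha: float = 0.01
) -> ScreenResult:
    """Pearson screen of per-node within-network connectivity vs the scales.

    ``wnc`` is a subject x node table of within-network connectivity values.
    """
    return _correlation_screen(wnc, scores, alpha, "pearson")


def volume_hrqol_correlations(
    totals: pd.DataFrame, scores: pd.DataFrame
) -> list[StatResult]:
    """Kendall tau-b of each lesion type's total volume against each scale."""
    wide = totals.pivot_table(index="subject", columns="lesion_type", values="total_ml")
    common = wide.index.intersection(scores.index)
    if len(common) < 10:
        raise ValueError(f"requires >= 10 subjects, got {len(common)}")
    out: list[StatResult] = []
    for t in wide.columns:
        x = wide.loc[common, t].to_numpy(dtype=float)
        for s in scores.columns:
            y = scores.loc[common, s].to_numpy(dtype=float)
            tau, p = kendall_tau_b(x, y)
            und = np.isnan(p)
            out.append(
                StatResult(f"total_volume:{t}", str(s), "kendall_tau_b", tau,
                           p if not und else float("nan"),
                           int((~(np.isnan(x) | np.isnan(y))).sum()),
                           significant=bool(not und and p < 0.05), undefined=und)
            )
    return out


def laterality_comparison(scores: pd.DataFrame, side: pd.Series) -> pd.DataFrame:
    """Left-vs-right comparison of every scale.

    Returns one row per scale with group medians and means, the Mann-Whitney
    U and p, Cohen's d (left minus right) with its magnitude class, the
    clinical-importance class of the mean difference, and star coding.
    """
    side = side.reindex(scores.index)
    left = scores[side == "left"]
    right = scores[side == "right"]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("laterality comparison requires subjects on both sides")
    rows = []
    for s in scores.columns:
        a = left[s].dropna().to_numpy()
        b = right[s].dropna().to_numpy()
        U, p = mann_whitney_u(a, b)
        d = cohens_d(a, b)
        delta = float(a.mean() - b.mean())
        rows.append(
            {
                "scale": s,
                "n_left": len(a),
                "n_right": len(b),
                "median_left": float(np.median(a)),
                "median_right": float(np.median(b)),
                "mean_difference": delta,
                "U": U,
                "p_value": p,
                "cohens_d": d,
                "d_class": classify_d(d),
                "mcid_class": classify_mcid(delta),
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("scale")
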