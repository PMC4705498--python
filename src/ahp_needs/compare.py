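"""Between-group comparison: rank correlation, t-tests, boxplot summaries.

The pipeline contrasts expert subgroups (clinical vs technical) in three
ways: a tie-corrected Spearman rank correlation between the subgroups'
median weight profiles, per-item two-sample t-tests on the individual
weights (Welch's unequal-variance variant by default — the groups differ
in size and no variance homogeneity is assumed; Student's pooled test is
available), and boxplot five-number summaries with the 1.5 x IQR fence
rule for outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthesis import PanelResult, subgroup_median_weights

__all__ = [
    "spearman",
    "welch_t",
    "boxplot_stats",
    "BoxplotStats",
    "ComparisonResult",
    "compare_groups",
]


class DegenerateDataError(ValueError):
    """Input has no variation where the statistic requires some."""


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Ranks use the average-rank convention for ties; rho is the Pearson
    correlation of the rank vectors.  The p-value comes from the
    t-approximation t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of
    freedom, or (``exact=True``, n <= 10 only) from exact enumeration of
    all pairings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("rank correlation undefined for a constant vector")
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        res = stats.permutation_test(
            (x, y),
            lambda a, b: np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1],
            permutation_type="pairings",
            n_resamples=math.factorial(n),
        )
        return rho, float(res.pvalue)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(x, y, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test: (t, df, two-sided p).

    Defaults to Welch's unequal-variance statistic with the
    Welch-Satterthwaite degrees of freedom; ``equal_var=True`` gives the
    pooled-variance Student test.  Raises when both samples are constant
    (zero pooled variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateDataError("both groups are constant; t-test undefined")
    nx, ny = x.size, y.size
    if equal_var:
        df = nx + ny - 2
    else:
        a, b = vx / nx, vy / ny
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(df), float(p)


@dataclass
class BoxplotStats:
    """Five-number boxplot summary with 1.5 x IQR outlier fences.

    Quartiles use linear interpolation between closest ranks; whiskers sit
    at the most extreme data points within 1.5 x IQR of the box edges, and
    everything beyond is listed individually as an outlier.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_stats(values) -> BoxplotStats:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=[float(o) for o in np.sort(outliers)],
    )


@dataclass
class ComparisonResult:
    """Subgroup contrast: per-item t-tests plus a Spearman summary.

    ``needs`` carries one row per leaf with the two subgroup medians and
    the GW/LW t-test p-values; ``categories`` the same for CW.  ``rho``
    and ``rho_p`` correlate the two subgroups' median GW profiles.
    """

    group_a: str
    group_b: str
    needs: pd.DataFrame
    categories: pd.DataFrame
    rho: float
    rho_p: float


def compare_groups(
    panel: PanelResult,
    group_a: str = "technical",
    group_b: str = "clinical",
    equal_var: bool = False,
) -> ComparisonResult:
    """Contrast two respondent groups need-by-need and category-by-category.

    T-tests run on the individual respondents' weights (GW and leaf LW per
    need, CW per category); the Spearman correlation runs on the subgroup
    median GW profiles across all leaves.
    """
    h = panel.hierarchy
    med_a = subgroup_median_weights(panel, group_a)
    med_b = subgroup_median_weights(panel, group_b)
    gw_a, gw_b = panel.gw_table(group_a), panel.gw_table(group_b)
    lw_a, lw_b = panel.leaf_lw_table(group_a), panel.leaf_lw_table(group_b)

    def _p(xa, xb):
        try:
            return welch_t(xa, xb, equal_var=equal_var)[2]
        except DegenerateDataError:
            return float("nan")

    need_rows = []
    for leaf in h.leaves():
        need_rows.append(
            {
                "need": leaf.id,
                "label": h.node(leaf.id).label,
                f"median_{group_a}_gw": med_a["gw"][leaf.id],
                f"median_{group_b}_gw": med_b["gw"][leaf.id],
                f"median_{group_a}_lw": med_a["leaf_lw"][leaf.id],
                f"median_{group_b}_lw": med_b["leaf_lw"][leaf.id],
                "gw_ttest_p": _p(gw_a.loc[leaf.id], gw_b.loc[leaf.id]),
                "lw_ttest_p": _p(lw_a.loc[leaf.id], lw_b.loc[leaf.id]),
            }
        )
    cw_a, cw_b = panel.cw_table(group_a), panel.cw_table(group_b)
    cat_rows = []
    for cat in h.categories():
        cat_rows.append(
            {
                "category": cat.id,
                "label": cat.label,
                f"median_{group_a}_cw": med_a["cw"][cat.id],
                f"median_{group_b}_cw": med_b["cw"][cat.id],
                "ttest_p": _p(cw_a.loc[cat.id], cw_b.loc[cat.id]),
            }
        )
    needs = pd.DataFrame(need_rows)
    rho, rho_p = spearman(
        needs[f"median_{group_a}_gw"], needs[f"median_{group_b}_gw"]
    )
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        needs=needs,
        categories=pd.DataFrame(cat_rows),
        rho=rho,
        rho_p=rho_p,
    )
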