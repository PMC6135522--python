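"""Group-comparison statistics for network parameters.

Covers the non-parametric tests applied to per-group parameter values:
the Mann-Whitney U test for two-group comparisons, the Scheirer-Ray-Hare
rank-based two-way analysis (the Kruskal-Wallis extension to two crossed
factors), and the all-pairs parameter correlation map with a
significance mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "mann_whitney",
    "SRHResult",
    "scheirer_ray_hare",
    "correlation_map",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float     # U of the first sample
    p_value: float         # two-sided
    method: str            # "exact" or "asymptotic"


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties. The p-value is
    exact (full enumeration) when n_a + n_b <= 12 and the pooled data
    hold no ties; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return MannWhitneyResult(len(a) * len(b) / 2.0, 1.0, "degenerate")
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class SRHResult:
    """H statistics referred to chi-square with the effect's df."""

    h: dict                # effect -> H
    df: dict               # effect -> degrees of freedom
    p: dict                # effect -> p-value
    ss: dict               # effect -> sum of squares of ranks (+ 'within', 'total')
    ms_total: float        # total mean square of the ranks


def scheirer_ray_hare(values, factor_a, factor_b) -> SRHResult:
    """Scheirer-Ray-Hare rank-based two-way analysis.

    All observations are ranked jointly (midranks for ties); two-way
    sums of squares are computed on the ranks, and each effect's
    H = SS_effect / MS_total is referred to a chi-square distribution
    with the effect's degrees of freedom. MS_total = SS_total/(N-1)
    equals N(N+1)/12 without ties and is tie-corrected otherwise.
    Requires a complete crossed layout (every cell non-empty).
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": factor_a, "b": factor_b}
    )
    if df.isna().any().any():
        raise ValueError("values and factors must be complete (no NaN)")
    levels_a = df["a"].unique()
    levels_b = df["b"].unique()
    cells = df.groupby(["a", "b"], sort=False)["y"].count()
    if len(cells) != len(levels_a) * len(levels_b) or (cells < 1).any():
        raise ValueError("empty cells: the two-factor layout must be complete")

    df["r"] = sps.rankdata(df["y"])
    n = len(df)
    grand = df["r"].sum()
    cf = grand**2 / n  # correction factor

    def ss_groups(by) -> float:
        g = df.groupby(by, sort=False)["r"]
        return float((g.sum() ** 2 / g.count()).sum() - cf)

    ss_a = ss_groups("a")
    ss_b = ss_groups("b")
    ss_cells = ss_groups(["a", "b"])
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float((df["r"] ** 2).sum() - cf)
    ss_within = ss_total - ss_cells
    ms_total = ss_total / (n - 1)

    dfs = {
        "a": len(levels_a) - 1,
        "b": len(levels_b) - 1,
        "interaction": (len(levels_a) - 1) * (len(levels_b) - 1),
    }
    hs = {
        "a": ss_a / ms_total,
        "b": ss_b / ms_total,
        "interaction": ss_ab / ms_total,
    }
    ps = {
        k: float(sps.chi2.sf(hs[k], dfs[k])) if dfs[k] > 0 else np.nan
        for k in hs
    }
    ss = {"a": ss_a, "b": ss_b, "interaction": ss_ab,
          "within": ss_within, "total": ss_total}
    return SRHResult(h=hs, df=dfs, p=ps, ss=ss, ms_total=ms_total)


def correlation_map(
    table: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations between per-fly parameters.

    Returns (r, significant) DataFrames over the numeric columns of
    ``table``; ``significant`` masks p < ``alpha``. Zero-variance
    columns yield NaN coefficients (flagged not significant).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    num = table.select_dtypes("number")
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    sig = np.zeros((k, k), dtype=bool)
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    for i, j in itertools.product(range(k), repeat=2):
        x, y = num[cols[i]].to_numpy(), num[cols[j]].to_numpy()
        if len(x) < 3:
            raise ValueError("need at least 3 paired observations")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        if i == j:
            r[i, j] = 1.0
            sig[i, j] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fn(x, y)
        r[i, j] = res.statistic
        sig[i, j] = res.pvalue < alpha
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(sig, index=cols, columns=cols),
    )
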