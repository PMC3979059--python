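"""Group-comparison statistics for morphometric measurements.

Continuous morphometric outcomes are compared by one-way fixed-effects
ANOVA followed by Tukey's HSD post-hoc test (Tukey-Kramer for unequal
group sizes, adjusted p from the studentized-range distribution).
Ordinal outcomes such as clinical scores use the two-sided Mann-Whitney
U test, exact for small samples and tie-corrected normal otherwise.
All tests are two-sided; the conventional significance level is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsResult",
    "PairwiseComparison",
    "anova_tukey",
    "mann_whitney",
    "summarise",
]


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float
    p_adjusted: float
    significant: bool


@dataclass
class StatsResult:
    test: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _extract_groups(
    table: pd.DataFrame, measurement: str | None
) -> tuple[list[str], list[np.ndarray]]:
    df = table
    if measurement is not None:
        df = df[df["measurement"] == measurement]
    labels = list(dict.fromkeys(df["group"]))
    values = [np.asarray(df.loc[df["group"] == g, "value"], dtype=float) for g in labels]
    return labels, values


def anova_tukey(
    table: pd.DataFrame,
    measurement: str | None = None,
    alpha: float = 0.05,
    pairwise: bool = True,
) -> StatsResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``table`` needs columns ``group`` and ``value`` (and ``measurement``
    if a measurement filter is given).  Requires >= 2 groups with n >= 2
    each.  The F statistic and Tukey q are computed from the classical
    sums of squares; adjusted p-values come from the studentized-range
    distribution with the pooled within-group degrees of freedom
    (Tukey-Kramer standard error for unequal n).  ``pairwise=False``
    skips the post-hoc comparisons (useful in large simulation loops
    where only the omnibus F matters).
    """
    labels, groups = _extract_groups(table, measurement)
    k = len(groups)
    if k < 2:
        raise ValueError(f"ANOVA needs >= 2 groups, got {k}")
    ns = np.array([len(g) for g in groups])
    if (ns < 2).any():
        small = [l for l, n in zip(labels, ns) if n < 2]
        raise ValueError(f"each group needs n >= 2 for ANOVA, too small: {small}")
    means = np.array([g.mean() for g in groups])
    N = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between, df_within = k - 1, N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else np.inf
        p = 1.0 if ms_between == 0 else 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))

    comparisons: list[PairwiseComparison] = []
    if not pairwise:
        return StatsResult(
            test="one-way ANOVA", statistic=float(f_stat), p_value=p, alpha=alpha
        )
    for (ia, a), (ib, b) in combinations(enumerate(labels), 2):
        diff = means[ib] - means[ia]
        se = np.sqrt(ms_within / 2.0 * (1.0 / ns[ia] + 1.0 / ns[ib]))
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        comparisons.append(
            PairwiseComparison(a, b, float(diff), p_adj, bool(p_adj < alpha))
        )
    return StatsResult(
        test="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat),
        p_value=p,
        alpha=alpha,
        pairwise=comparisons,
    )


#: largest permutation count for which the exact branch enumerates
_MW_EXACT_MAX_PERMUTATIONS = 200_000


def mann_whitney(group_a, group_b, alpha: float = 0.05) -> StatsResult:
    """Two-sided Mann-Whitney U test.

    Small samples (nA * nB <= 400 and a tractable number of group
    assignments) use the exact permutation null distribution of U, which
    handles ties correctly; larger samples fall back to the tie-corrected
    normal approximation with continuity correction.  The permutation
    distribution of U is symmetric about nA*nB/2, so the exact two-sided
    p-value P(|U - mu| >= |u - mu|) coincides with the usual doubled-tail
    convention on tie-free data.
    """
    import math

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    small = na * nb <= 400 and math.comb(na + nb, na) <= _MW_EXACT_MAX_PERMUTATIONS
    if small:
        from itertools import combinations as icombs

        offset = na * (na + 1) / 2.0
        d_obs = abs(u_obs - mu)
        count = total = 0
        for idx in icombs(range(na + nb), na):
            u = sum(ranks[i] for i in idx) - offset
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return StatsResult(
        test=f"Mann-Whitney U ({method})",
        statistic=u_obs,
        p_value=float(min(p, 1.0)),
        alpha=alpha,
    )


def summarise(table: pd.DataFrame) -> pd.DataFrame:
    """Per (measurement, group): n, mean, sample SD (n-1), SEM.

    Singleton groups report SD and SEM as missing.
    """
    keys = [c for c in ("measurement", "group") if c in table.columns]
    if not keys:
        raise ValueError("table needs a 'group' column")

    def _agg(vals: pd.Series) -> pd.Series:
        v = vals.to_numpy(dtype=float)
        n = v.size
        sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
        return pd.Series(
            {
                "n": n,
                "mean": float(v.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )

    out = table.groupby(keys, sort=False)["value"].apply(_agg).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()
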