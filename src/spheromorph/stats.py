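"""Hypothesis tests for size-stratified shape measures.

Two tests drive the shape analysis: a Levene-family test for equality of
circularity *variances* between small and large spheroids (irregular growth
shows up as extra shape spread in the large stratum, not necessarily as a
location shift), and the Mann-Whitney rank test for a *location* difference
in sphericity between small and large tumours.

The Levene variant used by default is the "quadratic" one: each observation
is replaced by its squared deviation from the group mean and the one-way
ANOVA F statistic of those transformed values is referred to the
F(k-1, N-k) distribution.  The classical absolute-deviation and the
median-centred (Brown-Forsythe) variants are available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

LeveneVariant = Literal["quadratic", "abs-mean", "abs-median"]


@dataclass
class VarianceTestResult:
    statistic: float          # W, the ANOVA F on transformed deviations
    df1: int
    df2: int
    p_value: float
    group_sizes: tuple[int, ...]
    group_variances: tuple[float, ...]
    variant: str = "quadratic"


@dataclass
class RankTestResult:
    u: float                  # U of the first sample
    p_value: float            # two-sided unless noted
    method: str               # "exact" | "normal-approx"
    group_sizes: tuple[int, int]
    tie_correction_applied: bool
    medians: tuple[float, float]
    alternative: str = "two-sided"


@dataclass
class SizeStratification:
    split_variable: str
    threshold: float          # the sample median
    small_ids: list
    large_ids: list


# ---------------------------------------------------------------------------
# Levene-family variance test


def _levene_transform(x: np.ndarray, variant: LeveneVariant) -> np.ndarray:
    if variant == "quadratic":
        return (x - x.mean()) ** 2
    if variant == "abs-mean":
        return np.abs(x - x.mean())
    if variant == "abs-median":
        return np.abs(x - np.median(x))
    raise ValueError(f"unknown Levene variant {variant!r}")


def levene_quadratic(
    groups: Sequence[Sequence[float]],
    variant: LeveneVariant = "quadratic",
) -> VarianceTestResult:
    """Levene test for equality of variances across two or more groups.

    With the default quadratic transform, z_ij = (x_ij - mean_i)^2 and the
    statistic W is the one-way ANOVA F of the z_ij, with p from
    F(k-1, N-k).  If the transformed values show no between-group spread
    W = 0 and p = 1; if all within-group spread of the z_ij vanishes while
    the between-group spread does not, W is infinite and p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} < 2 observations")

    k = len(gs)
    n_total = sum(g.size for g in gs)
    df1, df2 = k - 1, n_total - k
    z = [_levene_transform(g, variant) for g in gs]
    grand = np.concatenate(z).mean()
    ss_between = sum(g.size * (zi.mean() - grand) ** 2
                     for g, zi in zip(gs, z))
    ss_within = sum(float(np.sum((zi - zi.mean()) ** 2)) for zi in z)

    if ss_between <= 0:
        w, p = 0.0, 1.0
    elif ss_within == 0:
        w, p = math.inf, 0.0
    else:
        w = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(w, df1, df2))
    return VarianceTestResult(
        statistic=float(w), df1=df1, df2=df2, p_value=p,
        group_sizes=tuple(g.size for g in gs),
        group_variances=tuple(float(np.var(g, ddof=1)) for g in gs),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution of U as counts over u = 0..n1*n2 (no ties).

    Classic recursion: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u),
    run as an iterative convolution; the total is C(n1+n2, n1).
    """
    # DP over the n1+n2 ranks: ways[j][u] = subsets of size j with U = u
    ways = [np.zeros(n1 * n2 + 1, dtype=object) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for rank in range(1, n1 + n2 + 1):
        for j in range(min(rank, n1), 0, -1):
            # choosing this rank as the j-th smallest of sample 1
            # contributes (rank - j) to U
            u_add = rank - j
            prev = ways[j - 1]
            cur = ways[j]
            if u_add == 0:
                cur += prev
            else:
                cur[u_add:] += prev[:-u_add]
    return tuple(int(c) for c in ways[n1])


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = np.array(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    ui = int(round(u))
    lower = counts[: ui + 1].sum() / total
    upper = counts[ui:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    method: Literal["auto", "exact", "normal"] = "auto",
    alternative: str = "two-sided",
) -> RankTestResult:
    """Mann-Whitney U test for a location difference between two samples.

    U is computed from midrank sums of the first sample.  With
    ``method="auto"`` the exact null distribution is enumerated when
    n1 + n2 <= 20 and the data carry no ties; otherwise (and always in the
    presence of ties) the normal approximation with continuity and tie
    correction is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    use_exact = (
        method == "exact"
        or (method == "auto" and n1 + n2 <= 20)
    ) and not has_ties
    if method == "exact" and has_ties:
        use_exact = False  # exact null with midranks is not attempted

    if use_exact:
        if alternative != "two-sided":
            counts = np.array(_u_counts(n1, n2), dtype=float)
            total = counts.sum()
            ui = int(round(u1))
            if alternative == "greater":
                p = float(counts[ui:].sum() / total)
            else:
                p = float(counts[: ui + 1].sum() / total)
        else:
            p = _exact_two_sided_p(u1, n1, n2)
        meth = "exact"
        tie_flag = False
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            diff = u1 - mu
            cc = 0.5 * np.sign(diff)
            z = (diff - cc) / math.sqrt(var)
            if alternative == "two-sided":
                p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
            elif alternative == "greater":
                p = float(sps.norm.sf((u1 - mu - 0.5) / math.sqrt(var)))
            else:
                p = float(sps.norm.cdf((u1 - mu + 0.5) / math.sqrt(var)))
        meth = "normal-approx"
        tie_flag = has_ties
    return RankTestResult(
        u=u1, p_value=p, method=meth, group_sizes=(n1, n2),
        tie_correction_applied=tie_flag,
        medians=(float(np.median(x)), float(np.median(y))),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# stratification and composite analyses


def stratify_by_median(
    table, variable: str, id_column: str | None = None
) -> SizeStratification:
    """Split a measurement table at the sample median of one column.

    Rows with value <= median go to "small", the rest to "large"
    (median-valued items are assigned to "small"; the rule is arbitrary but
    deterministic).  Raises if either group would be empty.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to stratify")
    values = pd.to_numeric(df[variable])
    threshold = float(values.median())
    small = values <= threshold
    ids = df[id_column] if id_column else df.index.to_series()
    small_ids = ids[small].tolist()
    large_ids = ids[~small].tolist()
    if not small_ids or not large_ids:
        raise ValueError(
            f"stratification by {variable!r} left an empty group "
            f"(constant variable?)"
        )
    return SizeStratification(
        split_variable=variable, threshold=threshold,
        small_ids=small_ids, large_ids=large_ids,
    )


def circularity_variance_test(
    measures,
    variant: LeveneVariant = "quadratic",
) -> tuple[VarianceTestResult, SizeStratification]:
    """Compare circularity variance of small vs large spheroids.

    Stratifies a morphometry table at the median area, then applies the
    Levene test to the circularity values of the two strata.  Requires
    >= 4 objects with valid circularity.
    """
    import pandas as pd

    df = pd.DataFrame(measures).dropna(subset=["area_um2", "circularity"])
    if len(df) < 4:
        raise ValueError("need >= 4 objects with valid circularity")
    id_col = "object_id" if "object_id" in df else None
    strat = stratify_by_median(df, "area_um2", id_column=id_col)
    small = df["area_um2"] <= strat.threshold
    result = levene_quadratic(
        [df.loc[small, "circularity"], df.loc[~small, "circularity"]],
        variant=variant,
    )
    return result, strat
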