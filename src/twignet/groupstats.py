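"""Supporting inference: K-S normality, one-/two-way ANOVA, Duncan's test.

One-way ANOVA uses the explicit between/within sum-of-squares decomposition
(so that degenerate all-constant inputs yield F = 0 rather than NaN); it is
cross-checked against scipy in the test suite. The two-way ANOVA runs on a
fully crossed N × P sub-grid through a type-II OLS decomposition. Duncan's
multiple range test assigns letter displays from studentized-range critical
values at the protection level 1 − (1 − α)^(p−1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ks_normality",
    "anova_oneway",
    "anova_twoway",
    "duncan_groups",
    "OnewayResult",
    "TwowayResult",
    "group_summary",
]


def ks_normality(values: Sequence[float], lilliefors: bool = False) -> tuple[float, float]:
    """One-sample K-S test against a normal with the sample mean and sd.

    With estimated parameters the asymptotic K-S p-value is conservative;
    pass ``lilliefors=True`` for the Lilliefors-corrected p-value.
    Raises on constant samples (sd = 0) and samples with n < 5.
    """
    x = np.asarray(values, float)
    if x.size < 5:
        raise ValueError("K-S normality check requires n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined (sd = 0)")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


@dataclass(frozen=True)
class OnewayResult:
    F: float
    p: float
    df_between: int
    df_within: int
    mse: float
    group_n: Mapping[str, int]
    group_mean: Mapping[str, float]
    group_sd: Mapping[str, float]


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> OnewayResult:
    """Classical one-way fixed-effects ANOVA from the SS decomposition."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA requires at least 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    mse = ss_within / df_w
    if ss_between == 0:
        f = 0.0
        p = 1.0
    elif ss_within == 0:
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    return OnewayResult(
        F=float(f),
        p=float(p),
        df_between=df_b,
        df_within=df_w,
        mse=float(mse),
        group_n={k: int(a.size) for k, a in arrays.items()},
        group_mean={k: float(a.mean()) for k, a in arrays.items()},
        group_sd={k: float(a.std(ddof=1)) for k, a in arrays.items()},
    )


@dataclass(frozen=True)
class TwowayResult:
    F_N: float
    F_P: float
    F_interaction: float
    p_N: float
    p_P: float
    p_interaction: float
    df: Mapping[str, int]


def anova_twoway(
    table: pd.DataFrame,
    value: str,
    n_col: str = "n_rate",
    p_col: str = "p_rate",
) -> TwowayResult:
    """Two-way fixed-effects ANOVA (type-II SS) on a complete N × P grid.

    `table` must contain every combination of the N and P rates present,
    each with at least two replicates; an incomplete grid raises with the
    missing cells listed.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n_vals = sorted(table[n_col].unique())
    p_vals = sorted(table[p_col].unique())
    counts = table.groupby([n_col, p_col]).size()
    def _py(v):
        return v.item() if hasattr(v, "item") else v

    missing = [
        (_py(n), _py(p)) for n in n_vals for p in p_vals if (n, p) not in counts.index
    ]
    if missing:
        raise ValueError(f"incomplete N x P grid; missing cells: {missing}")
    if (counts < 2).any():
        thin = sorted(counts[counts < 2].index.tolist())
        raise ValueError(f"cells with fewer than 2 replicates: {thin}")

    df = table[[n_col, p_col, value]].rename(columns={value: "_y"})
    model = smf.ols(f"_y ~ C({n_col}) * C({p_col})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    n_term, p_term = f"C({n_col})", f"C({p_col})"
    i_term = f"{n_term}:{p_term}"
    return TwowayResult(
        F_N=float(aov.loc[n_term, "F"]),
        F_P=float(aov.loc[p_term, "F"]),
        F_interaction=float(aov.loc[i_term, "F"]),
        p_N=float(aov.loc[n_term, "PR(>F)"]),
        p_P=float(aov.loc[p_term, "PR(>F)"]),
        p_interaction=float(aov.loc[i_term, "PR(>F)"]),
        df={
            "N": int(aov.loc[n_term, "df"]),
            "P": int(aov.loc[p_term, "df"]),
            "interaction": int(aov.loc[i_term, "df"]),
            "residual": int(aov.loc["Residual", "df"]),
        },
    )


@lru_cache(maxsize=1024)
def _duncan_q(n_means: int, df_error: int, alpha: float) -> tuple[float, ...]:
    """Studentized-range quantiles at Duncan's protection level for spans
    p = 2..n_means (cached: the ppf is expensive and reused across traits)."""
    ps = np.arange(2, n_means + 1)
    protection = 1.0 - (1.0 - alpha) ** (ps - 1)
    return tuple(stats.studentized_range.ppf(1.0 - protection, ps, df_error))


def _duncan_ranges(n_means: int, df_error: int, mse: float, n_h: float, alpha: float) -> np.ndarray:
    """Critical range R_p for spans p = 2..n_means (index p-2)."""
    q = np.array(_duncan_q(n_means, df_error, alpha))
    return q * np.sqrt(mse / n_h)


def duncan_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's multiple range test letter display.

    Means are sorted descending; a span of p consecutive means is declared
    homogeneous when its extreme difference is below the critical range
    R_p = q(1−(1−α)^(p−1); p, df_error) · sqrt(MSE / n_h), with n_h the
    harmonic mean group size, and spans inside a homogeneous span are not
    tested further. Groups sharing a letter do not differ at level α.
    """
    if len(groups) < 2:
        raise ValueError("Duncan's test requires at least 2 groups")
    aov = anova_oneway(groups)
    labels = sorted(groups, key=lambda k: -aov.group_mean[k])
    means = np.array([aov.group_mean[k] for k in labels])
    k = len(labels)
    sizes = np.array([aov.group_n[lab] for lab in labels], float)
    n_h = k / (1.0 / sizes).sum()
    if aov.mse == 0:
        ranges = np.zeros(k - 1)
    else:
        ranges = _duncan_ranges(k, aov.df_within, aov.mse, n_h, alpha)
    # ranges must be monotone non-decreasing in span size
    ranges = np.maximum.accumulate(ranges)

    homogeneous: list[tuple[int, int]] = []
    visited: set[tuple[int, int]] = set()

    def _test(i: int, j: int) -> None:
        if i >= j or (i, j) in visited:
            return
        visited.add((i, j))
        if means[i] - means[j] < ranges[j - i - 1] or means[i] - means[j] == 0:
            homogeneous.append((i, j))
            return
        _test(i, j - 1)
        _test(i + 1, j)

    _test(0, k - 1)
    # keep maximal spans only; cover singletons not inside any span
    maximal = [
        (i, j)
        for (i, j) in set(homogeneous)
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    for idx in range(k):
        if not any(a <= idx <= b for a, b in maximal):
            maximal.append((idx, idx))
    maximal.sort()

    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (a, b) in zip(alphabet, maximal):
        for idx in range(a, b + 1):
            letters[labels[idx]] += letter
    return letters


def group_summary(
    plot_table: pd.DataFrame,
    trait: str,
    by: str = "level",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group n/mean/sd with Duncan letters for one trait."""
    groups = {str(k): g[trait].to_numpy(float) for k, g in plot_table.groupby(by, sort=False)}
    aov = anova_oneway(groups)
    letters = duncan_groups(groups, alpha=alpha)
    rows = [
        {
            by: k,
            "n": aov.group_n[k],
            "mean": aov.group_mean[k],
            "sd": aov.group_sd[k],
            "duncan": letters[k],
        }
        for k in groups
    ]
    out = pd.DataFrame(rows)
    out.attrs["F"] = aov.F
    out.attrs["p"] = aov.p
    return out
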