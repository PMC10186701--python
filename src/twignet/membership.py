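"""Fuzzy membership-function comprehensive growth scoring.

Each trait's treatment-level means are min–max rescaled to [0, 1]:

    U(x) = (x − x_min) / (x_max − x_min)              (positive orientation)
    U(x) = 1 − (x − x_min) / (x_max − x_min)          (inverse orientation)

with the minimum and maximum taken across treatment levels. Traits whose
larger values indicate poorer growth (by default: traits negatively
Spearman-correlated with twig mass across the pooled plot table) use the
inverse form. The comprehensive growth score of a level is the unweighted
mean of its U values over all traits, and a dose series is scored by the
mean over its member levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import SERIES_LEVELS
from .traits import TRAIT_ORDER

__all__ = [
    "membership_value",
    "default_directions",
    "membership_matrix",
    "rank_series",
    "level_trait_means",
    "MembershipMatrix",
]


def membership_value(x: float, xmin: float, xmax: float, orientation: str = "positive") -> float:
    """Min–max membership of x in [xmin, xmax]; 0.5 when the range collapses."""
    if orientation not in ("positive", "inverse"):
        raise ValueError(f"orientation must be 'positive' or 'inverse', got {orientation!r}")
    if xmax < xmin:
        raise ValueError("xmax must be >= xmin")
    if not xmin <= x <= xmax:
        raise ValueError(f"x={x} outside [{xmin}, {xmax}]")
    if xmax == xmin:
        return 0.5
    u = (x - xmin) / (xmax - xmin)
    return 1.0 - u if orientation == "inverse" else u


def level_trait_means(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level trait means (rows: levels; keeps the series tag)."""
    keep = [c for c in ("series",) if c in plot_table.columns]
    traits = [t for t in TRAIT_ORDER if t in plot_table.columns]
    means = plot_table.groupby("level", sort=False)[traits].mean()
    if keep:
        means.insert(0, "series", plot_table.groupby("level", sort=False)["series"].first())
    return means


def default_directions(plot_table: pd.DataFrame, anchor: str = "TM") -> dict[str, str]:
    """Orientation map: inverse for traits negatively rank-correlated with
    the anchor trait (twig mass) across the pooled plot table."""
    traits = [t for t in TRAIT_ORDER if t in plot_table.columns]
    anchor_vals = plot_table[anchor].to_numpy(float)
    out = {}
    for t in traits:
        rho = stats.spearmanr(plot_table[t].to_numpy(float), anchor_vals).statistic
        out[t] = "inverse" if np.isfinite(rho) and rho < 0 else "positive"
    return out


@dataclass(frozen=True)
class MembershipMatrix:
    """U values per (treatment level × trait) with derived scores."""

    U: pd.DataFrame                 # levels × traits, values in [0, 1]
    xmin: pd.Series
    xmax: pd.Series
    directions: Mapping[str, str]
    scores: pd.Series               # per-level comprehensive score
    series_scores: pd.Series        # per-series mean score


def membership_matrix(
    level_means: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
    series_levels: Mapping[str, Sequence[str]] | None = None,
) -> MembershipMatrix:
    """Membership values and comprehensive scores from level trait means.

    `level_means` has one row per treatment level (>= 2) and the 17 trait
    columns (a missing trait raises). `directions` maps trait → orientation;
    omitted traits default to positive. Series scores average the levels in
    `series_levels` (default: the four dose series, sharing N20P4 between
    the combined series; CK enters no series).
    """
    traits = [t for t in TRAIT_ORDER if t in level_means.columns]
    missing = sorted(set(TRAIT_ORDER) - set(traits))
    if missing:
        raise ValueError(f"level means are missing traits: {missing}")
    if len(level_means) < 2:
        raise ValueError("membership scoring requires at least 2 treatment levels")
    directions = dict(directions or {})
    x = level_means[traits].astype(float)
    xmin, xmax = x.min(axis=0), x.max(axis=0)
    span = (xmax - xmin).replace(0.0, np.nan)
    u = (x - xmin) / span
    for t in traits:
        if directions.get(t, "positive") == "inverse":
            u[t] = 1.0 - u[t]
    u = u.fillna(0.5)  # constant traits contribute neutrally
    scores = u.mean(axis=1)

    series_levels = SERIES_LEVELS if series_levels is None else series_levels
    ser = {}
    for name, levels in series_levels.items():
        present = [lv for lv in levels if lv in scores.index]
        if present:
            ser[name] = float(scores.loc[present].mean())
    return MembershipMatrix(
        U=u,
        xmin=xmin,
        xmax=xmax,
        directions={t: directions.get(t, "positive") for t in traits},
        scores=scores,
        series_scores=pd.Series(ser, dtype=float),
    )


def rank_series(matrix: MembershipMatrix, tie_tol: float = 1e-9) -> list[tuple[str, float, bool]]:
    """Series ordered by mean comprehensive score, descending.

    Returns (series, score, tied) triples; `tied` marks a score within
    `tie_tol` of an adjacent series' score.
    """
    s = matrix.series_scores.sort_values(ascending=False, kind="mergesort")
    names, vals = list(s.index), s.to_numpy()
    tied = [False] * len(names)
    for i in range(len(names) - 1):
        if abs(vals[i] - vals[i + 1]) <= tie_tol:
            tied[i] = tied[i + 1] = True
    return [(n, float(v), t) for n, v, t in zip(names, vals, tied)]
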