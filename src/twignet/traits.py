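"""Derivation of the 17 twig traits and nested plot aggregation.

Seven quantities are measured on every current-year twig: stem length (L),
basal diameter (BD), leaf number (LN), total blade mass (TBM), total petiole
mass (TPM), stem mass (SM), and total leaf area (TLA). The remaining ten are
arithmetic combinations:

    TM  = TBM + TPM + SM        twig mass
    TLM = TBM + TPM             total leaf mass
    SPM = TPM / LN              single petiole mass
    SBM = TBM / LN              single blade mass
    SLM = SPM + SBM             single leaf mass
    LA  = TLA / LN              single leaf area
    SLA = TLA / TBM             specific leaf area (blade-mass basis)
    LI  = LN / SM               leafing intensity
    LAR = TLA / TM              leaf area ratio
    LAMR = TLA / SM             leaf area-to-stem mass ratio

SLA is computed on blade-only mass, the conventional leaf-economics
definition. Ratio traits are derived per twig and then averaged up the
hierarchy (twig → tree → plot), never recomputed from averaged numerators
and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .generator import ID_COLUMNS, RAW_MEASUREMENTS

__all__ = [
    "TraitInfo",
    "TRAIT_ORDER",
    "trait_catalog",
    "derive_traits",
    "derive_table",
    "aggregate_plots",
    "TraitValidationError",
]


class TraitValidationError(ValueError):
    """A twig record violates a measurement constraint; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class TraitInfo:
    category: str  # stem | leaf | ratio
    units: str


#: The 17 traits in catalog order: 4 stem, 10 leaf, 3 ratio.
_CATALOG: Mapping[str, TraitInfo] = {
    "L": TraitInfo("stem", "cm"),
    "BD": TraitInfo("stem", "cm"),
    "SM": TraitInfo("stem", "g"),
    "TM": TraitInfo("stem", "g"),
    "LA": TraitInfo("leaf", "cm2"),
    "LN": TraitInfo("leaf", "count"),
    "TBM": TraitInfo("leaf", "g"),
    "TPM": TraitInfo("leaf", "g"),
    "TLA": TraitInfo("leaf", "cm2"),
    "TLM": TraitInfo("leaf", "g"),
    "SPM": TraitInfo("leaf", "g"),
    "SBM": TraitInfo("leaf", "g"),
    "SLM": TraitInfo("leaf", "g"),
    "SLA": TraitInfo("leaf", "cm2 g-1"),
    "LI": TraitInfo("ratio", "n g-1"),
    "LAR": TraitInfo("ratio", "cm2 g-1"),
    "LAMR": TraitInfo("ratio", "cm2 g-1"),
}

TRAIT_ORDER: tuple[str, ...] = tuple(_CATALOG)


def trait_catalog() -> Mapping[str, TraitInfo]:
    """Mapping of trait name → (category, units) for all 17 traits."""
    return dict(_CATALOG)


def _validate_record(record: Mapping) -> None:
    for m in RAW_MEASUREMENTS:
        if m not in record:
            raise TraitValidationError(m, "missing measurement")
        v = record[m]
        if not np.isfinite(v) or v <= 0:
            raise TraitValidationError(m, f"must be finite and > 0, got {v!r}")
    ln = record["LN"]
    if int(ln) != ln or ln < 1:
        raise TraitValidationError("LN", f"must be an integer >= 1, got {ln!r}")


def derive_traits(record: Mapping) -> dict[str, float]:
    """Compute the 17 traits of a single twig record.

    Raises :class:`TraitValidationError` naming the offending field when a
    measurement is non-positive, missing, or LN is not a positive integer.
    """
    _validate_record(record)
    L, BD, LN = float(record["L"]), float(record["BD"]), float(record["LN"])
    TBM, TPM = float(record["TBM"]), float(record["TPM"])
    SM, TLA = float(record["SM"]), float(record["TLA"])
    TM = TBM + TPM + SM
    TLM = TBM + TPM
    SPM = TPM / LN
    SBM = TBM / LN
    out = {
        "L": L,
        "BD": BD,
        "SM": SM,
        "TM": TM,
        "LA": TLA / LN,
        "LN": LN,
        "TBM": TBM,
        "TPM": TPM,
        "TLA": TLA,
        "TLM": TLM,
        "SPM": SPM,
        "SBM": SBM,
        "SLM": SPM + SBM,
        "SLA": TLA / TBM,
        "LI": LN / SM,
        "LAR": TLA / TM,
        "LAMR": TLA / SM,
    }
    return out


def derive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trait derivation over a twig table.

    Returns the identifier columns plus the 17 trait columns in catalog
    order. Every row must satisfy the twig-record constraints.
    """
    for m in RAW_MEASUREMENTS:
        if m not in table.columns:
            raise TraitValidationError(m, "missing column")
        col = table[m].to_numpy(float)
        if not np.all(np.isfinite(col) & (col > 0)):
            raise TraitValidationError(m, "non-positive or non-finite value present")
    ln = table["LN"].to_numpy(float)
    if not np.all((ln >= 1) & (ln == np.rint(ln))):
        raise TraitValidationError("LN", "must be integer >= 1")

    ids = [c for c in ID_COLUMNS if c in table.columns]
    out = table[ids].copy()
    L, BD = table["L"].to_numpy(float), table["BD"].to_numpy(float)
    TBM, TPM = table["TBM"].to_numpy(float), table["TPM"].to_numpy(float)
    SM, TLA = table["SM"].to_numpy(float), table["TLA"].to_numpy(float)
    TM = TBM + TPM + SM
    out["L"], out["BD"], out["SM"], out["TM"] = L, BD, SM, TM
    out["LA"] = TLA / ln
    out["LN"] = ln
    out["TBM"], out["TPM"], out["TLA"] = TBM, TPM, TLA
    out["TLM"] = TBM + TPM
    out["SPM"] = TPM / ln
    out["SBM"] = TBM / ln
    out["SLM"] = (TPM + TBM) / ln
    out["SLA"] = TLA / TBM
    out["LI"] = ln / SM
    out["LAR"] = TLA / TM
    out["LAMR"] = TLA / SM
    return out[ids + list(TRAIT_ORDER)]


def aggregate_plots(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate twig-level traits to plot means via nested averaging.

    Traits are derived per twig, averaged within each tree, and tree means
    are averaged within each plot, so unbalanced twig counts do not weight
    trees unequally. Because ratio traits do not commute with averaging, plot
    values of e.g. LAR are means of twig ratios, not ratios of plot means.
    Returns one row per plot with series/level identity preserved.
    """
    derived = derive_table(table) if "TM" not in table.columns else table
    if derived.empty:
        raise ValueError("cannot aggregate an empty twig table")
    id_keep = [c for c in ("series", "level", "n_rate", "p_rate") if c in derived.columns]
    tree_means = (
        derived.groupby(id_keep + ["plot", "tree"], sort=False, as_index=False)[list(TRAIT_ORDER)]
        .mean()
    )
    plot_means = (
        tree_means.groupby(id_keep + ["plot"], sort=False, as_index=False)[list(TRAIT_ORDER)]
        .mean()
    )
    return plot_means
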