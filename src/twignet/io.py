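"""Reading/writing twig tables and the structured run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign
from .generator import GeneratorParams, ID_COLUMNS, RAW_MEASUREMENTS

__all__ = [
    "read_twig_table",
    "write_twig_table",
    "ReadResult",
    "load_config_file",
    "save_config_file",
]

_COLUMNS = list(ID_COLUMNS) + list(RAW_MEASUREMENTS)


@dataclass
class ReadResult:
    """A validated twig table plus the rejected input rows.

    `rejected` holds (1-based data row number, reason) pairs.
    """

    table: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_twig_table(path: str | Path) -> ReadResult:
    """Read and validate a twig-measurement CSV.

    A missing column raises naming it. Rows with non-numeric, non-positive,
    or non-integer-LN measurements are rejected individually with their row
    numbers; valid rows are kept.
    """
    raw = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"twig table is missing required columns: {missing}")
    raw = raw[_COLUMNS]

    rejected: list[tuple[int, str]] = []
    ok = np.ones(len(raw), bool)
    for m in RAW_MEASUREMENTS:
        vals = pd.to_numeric(raw[m], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(float)) | (vals.to_numpy(float) <= 0)
        if m == "LN":
            v = vals.to_numpy(float)
            bad |= ~np.isfinite(v) | (v < 1) | (v != np.rint(v))
        for i in np.nonzero(bad & ok)[0]:
            rejected.append((int(i) + 1, f"invalid {m}: {raw[m].iloc[i]!r}"))
        ok &= ~bad
        raw[m] = vals
    table = raw.loc[ok].reset_index(drop=True)
    table["LN"] = table["LN"].astype(int)
    rejected.sort()
    return ReadResult(table=table, rejected=rejected)


def write_twig_table(table: pd.DataFrame, path: str | Path) -> None:
    table[_COLUMNS].to_csv(path, index=False)


def load_config_file(path: str | Path) -> dict:
    """Load a YAML config; `design` and `params` sections are materialized."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "design" in cfg:
        cfg["design"] = ExperimentDesign.from_dict(cfg["design"])
    if "params" in cfg:
        cfg["params"] = GeneratorParams.from_dict(cfg["params"])
    return cfg


def save_config_file(cfg: Mapping, path: str | Path) -> None:
    out = dict(cfg)
    if isinstance(out.get("design"), ExperimentDesign):
        out["design"] = out["design"].to_dict()
    if isinstance(out.get("params"), GeneratorParams):
        out["params"] = out["params"].to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
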