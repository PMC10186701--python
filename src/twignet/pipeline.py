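"""End-to-end analysis pipeline and its run configuration.

Stages: simulate (optional) → derive → effects → stats → network →
membership. Every artifact directory carries run metadata with the seed and
a hash of the configuration; a fixed configuration and seed reproduce the
bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .design import ExperimentDesign, wild_apple_design
from .effects import effect_table
from .generator import GeneratorParams, simulate_experiment
from .groupstats import anova_twoway, group_summary
from .io import read_twig_table, write_twig_table
from .membership import default_directions, level_trait_means, membership_matrix, rank_series
from .network import (
    build_ptn,
    key_traits,
    node_centralities,
    spearman_matrix,
    subset_levels,
    topology_report,
)
from .traits import TRAIT_ORDER, aggregate_plots, trait_catalog

__all__ = ["RunConfig", "run_pipeline", "config_hash", "ALL_STAGES"]

ALL_STAGES = ("simulate", "derive", "effects", "stats", "network", "membership")

#: The two complete N × P sub-grids of the 12-level design that admit a
#: crossed two-way ANOVA with interaction.
TWOWAY_GRIDS = {
    "N0-20_x_P": ("CK", "P2", "P4", "P8", "N20", "N20P2", "N20P4", "N20P8"),
    "N_x_P0-4": ("CK", "N10", "N20", "N40", "P4", "N10P4", "N20P4", "N40P4"),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path = "twignet_out"
    input_path: str | Path | None = None  # None → simulate
    seed: int = 0
    alpha: float = 0.05
    bootstrap_B: int = 10_000
    ci_method: str = "studentized"
    stages: tuple[str, ...] = ALL_STAGES
    design: ExperimentDesign = field(default_factory=wild_apple_design)
    params: GeneratorParams = field(default_factory=GeneratorParams)
    directions: dict | None = None  # trait → positive|inverse; None → data-driven

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "input_path": None if self.input_path is None else str(self.input_path),
            "seed": self.seed,
            "alpha": self.alpha,
            "bootstrap_B": self.bootstrap_B,
            "ci_method": self.ci_method,
            "stages": list(self.stages),
            "design": self.design.to_dict(),
            "params": self.params.to_dict(),
            "directions": self.directions,
        }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns artifact name → path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    meta = {
        "package": "twignet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }

    stage = "simulate"
    try:
        if config.input_path is not None:
            result = read_twig_table(config.input_path)
            twigs = result.table
            meta["rejected_rows"] = result.rejected
        else:
            twigs = simulate_experiment(config.design, config.params, seed=config.seed)
            if "simulate" in config.stages:
                path = out / "twig_table.csv"
                write_twig_table(twigs, path)
                artifacts["twig_table"] = path
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "derive"
    try:
        plots = aggregate_plots(twigs)
        if "derive" in config.stages:
            path = out / "plot_traits.csv"
            plots.to_csv(path, index=False)
            artifacts["plot_traits"] = path
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    if "effects" in config.stages:
        stage = "effects"
        try:
            eff = effect_table(
                plots, B=config.bootstrap_B, seed=config.seed,
                ci_method=config.ci_method, alpha=config.alpha,
            )
            path = out / "effects.csv"
            eff.to_csv(path, index=False)
            artifacts["effects"] = path
            meta["n_effect_tests"] = int(len(eff))
            meta["n_significant_effects"] = int(eff["significant"].sum())
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    if "stats" in config.stages:
        stage = "stats"
        try:
            frames = []
            for trait in TRAIT_ORDER:
                summ = group_summary(plots, trait, by="level", alpha=config.alpha)
                summ.insert(0, "trait", trait)
                summ["F"] = summ.attrs["F"]
                summ["p"] = summ.attrs["p"]
                frames.append(summ)
            path = out / "group_stats.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            artifacts["group_stats"] = path

            twoway = {}
            for grid_name, levels in TWOWAY_GRIDS.items():
                sub = plots[plots["level"].isin(levels)]
                twoway[grid_name] = {
                    trait: vars(anova_twoway(sub, trait)) for trait in ("L", "BD", "SM", "TM")
                }
            path = out / "anova_twoway.json"
            _write_json(path, twoway)
            artifacts["anova_twoway"] = path
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    if "network" in config.stages:
        stage = "network"
        try:
            cats = {t: info.category for t, info in trait_catalog().items()}
            reports = {}
            for subset in ("N", "P", "N20Px", "NxP4", "all"):
                levels = subset_levels(subset)
                sub = plots if levels is None else plots[plots["level"].isin(levels)]
                rho, p = spearman_matrix(sub)
                net = build_ptn(rho, p, alpha=config.alpha, subset=subset, categories=cats)
                cent = node_centralities(net)
                ranked, keys = key_traits(cent)
                rep = topology_report(net).to_dict()
                rep["key_traits"] = keys
                rep["ranked_traits"] = ranked
                reports[subset] = rep
                nx.write_graphml(net.graph, out / f"ptn_{subset}.graphml")
                net.edge_list().to_csv(out / f"ptn_{subset}_edges.csv", index=False)
                cent.to_csv(out / f"ptn_{subset}_nodes.csv", index=False)
                artifacts[f"ptn_{subset}"] = out / f"ptn_{subset}.graphml"
            path = out / "topology.json"
            _write_json(path, reports)
            artifacts["topology"] = path
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    if "membership" in config.stages:
        stage = "membership"
        try:
            means = level_trait_means(plots)
            directions = config.directions or default_directions(plots)
            mm = membership_matrix(means, directions)
            u = mm.U.copy()
            u.insert(0, "score", mm.scores)
            path = out / "membership.csv"
            u.to_csv(path)
            artifacts["membership"] = path
            ranking = rank_series(mm)
            path = out / "membership_scores.json"
            _write_json(
                path,
                {
                    "directions": dict(mm.directions),
                    "level_scores": {k: float(v) for k, v in mm.scores.items()},
                    "series_scores": {k: float(v) for k, v in mm.series_scores.items()},
                    "ranking": [{"series": s, "score": v, "tied": t} for s, v, t in ranking],
                },
            )
            artifacts["membership_scores"] = path
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    meta_path = out / "run_metadata.json"
    _write_json(meta_path, meta)
    artifacts["run_metadata"] = meta_path
    return artifacts
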