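"""Synthetic twig-measurement generator.

Simulates the hierarchical field experiment that the downstream analysis
assumes: treatment level → replicate plot → sapling (tree) → current-year
twig. Each plot carries a latent growth factor G driven by the N and P doses
through a saturating (Monod) gain with a quadratic high-dose inhibition term
and a multiplicative N×P interaction; the seven raw twig measurements are
allometric power functions of G with multiplicative lognormal noise at the
plot, tree, and twig levels. Only raw measurements are simulated — every
derived trait is computed downstream, so trait identities hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import ExperimentDesign, wild_apple_design

__all__ = [
    "DoseResponse",
    "TraitLoading",
    "GeneratorParams",
    "latent_growth",
    "expected_measurements",
    "simulate_experiment",
]

#: Raw measurement columns of a twig table, in canonical order.
RAW_MEASUREMENTS = ("L", "BD", "LN", "TBM", "TPM", "SM", "TLA")

#: Identifier columns of a twig table.
ID_COLUMNS = ("series", "level", "n_rate", "p_rate", "plot", "tree", "twig")


@dataclass(frozen=True)
class DoseResponse:
    """Saturating dose response with high-dose inhibition.

    gain(d) = max_gain * d / (half_saturation + d) - inhibition * d**2
    """

    half_saturation: float
    max_gain: float
    inhibition: float = 0.0

    def __post_init__(self) -> None:
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be > 0")
        if self.inhibition < 0:
            raise ValueError("inhibition must be >= 0")

    def gain(self, dose: float) -> float:
        dose = float(dose)
        return self.max_gain * dose / (self.half_saturation + dose) - self.inhibition * dose**2


@dataclass(frozen=True)
class TraitLoading:
    """Allometric link of one raw measurement to the latent growth factor:
    measurement = scale * G ** exponent (before noise)."""

    scale: float
    exponent: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("trait loading scale must be strictly positive")


def _default_loadings() -> Mapping[str, TraitLoading]:
    # Exponents chosen so that each derived trait is monotone in G and the
    # three ratio traits (and SLA) decline as growth increases, the direction
    # reported for fertilized wild-apple twigs.
    return {
        "L": TraitLoading(15.0, 0.8),    # stem length, cm
        "BD": TraitLoading(0.30, 0.4),   # basal diameter, cm
        "LN": TraitLoading(8.0, 0.5),    # leaf number (rounded to int >= 1)
        "TBM": TraitLoading(1.20, 1.05), # total blade mass, g
        "TPM": TraitLoading(0.15, 1.0),  # total petiole mass, g
        "SM": TraitLoading(1.00, 1.2),   # stem mass, g
        "TLA": TraitLoading(80.0, 0.85), # total leaf area, cm^2
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic experiment.

    Defaults encode the qualitative dose-response structure of the field
    study: promotion by N at all three rates with mild saturation/inhibition,
    a weaker P response, and an antagonistic N×P interaction strong enough
    that N-only plots outgrow the combined treatments. Noise standard
    deviations are lognormal sigmas of mean-one multiplicative factors at the
    plot, tree, and twig level.
    """

    baseline_growth: float = 1.0
    n_response: DoseResponse = field(default_factory=lambda: DoseResponse(2.0, 0.40, 5e-5))
    p_response: DoseResponse = field(default_factory=lambda: DoseResponse(40.0, 0.90, 0.0))
    interaction_coefficient: float = -7.0
    trait_loadings: Mapping[str, TraitLoading] = field(default_factory=_default_loadings)
    noise_sd: tuple[float, float, float] = (0.05, 0.05, 0.10)  # plot, tree, twig

    def __post_init__(self) -> None:
        if self.baseline_growth <= 0:
            raise ValueError("baseline_growth must be strictly positive")
        missing = set(RAW_MEASUREMENTS) - set(self.trait_loadings)
        if missing:
            raise ValueError(f"trait_loadings missing measurements: {sorted(missing)}")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd components must be >= 0")

    def with_noise(self, plot: float, tree: float, twig: float) -> "GeneratorParams":
        return replace(self, noise_sd=(plot, tree, twig))

    @classmethod
    def null(cls, noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "GeneratorParams":
        """Parameters with no treatment effects (flat dose response)."""
        return cls(
            n_response=DoseResponse(1.0, 0.0, 0.0),
            p_response=DoseResponse(1.0, 0.0, 0.0),
            interaction_coefficient=0.0,
            noise_sd=noise_sd,
        )

    def to_dict(self) -> dict:
        return {
            "baseline_growth": self.baseline_growth,
            "n_response": vars(self.n_response).copy(),
            "p_response": vars(self.p_response).copy(),
            "interaction_coefficient": self.interaction_coefficient,
            "trait_loadings": {k: vars(v).copy() for k, v in self.trait_loadings.items()},
            "noise_sd": list(self.noise_sd),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        kwargs: dict = {}
        if "baseline_growth" in d:
            kwargs["baseline_growth"] = float(d["baseline_growth"])
        for key in ("n_response", "p_response"):
            if key in d:
                kwargs[key] = DoseResponse(**d[key])
        if "interaction_coefficient" in d:
            kwargs["interaction_coefficient"] = float(d["interaction_coefficient"])
        if "trait_loadings" in d:
            kwargs["trait_loadings"] = {k: TraitLoading(**v) for k, v in d["trait_loadings"].items()}
        if "noise_sd" in d:
            kwargs["noise_sd"] = tuple(float(x) for x in d["noise_sd"])
        return cls(**kwargs)


def latent_growth(params: GeneratorParams, n_rate: float, p_rate: float) -> float:
    """Expected latent growth factor of a plot at the given nutrient doses."""
    fn = params.n_response.gain(n_rate)
    fp = params.p_response.gain(p_rate)
    return (
        params.baseline_growth
        * (1.0 + fn)
        * (1.0 + fp)
        * (1.0 + params.interaction_coefficient * fn * fp)
    )


def expected_measurements(design: ExperimentDesign, params: GeneratorParams) -> pd.DataFrame:
    """Closed-form expected raw measurements per treatment level.

    For a mean-one lognormal factor v with sigma s, E[v**b] = exp(b(b-1)s²/2),
    so the expectation of scale * (G·v_plot·v_tree)**b * v_twig is
    scale * G**b * exp(b(b-1)(s_plot² + s_tree²)/2). Leaf number is reported
    for the continuous latent value, ignoring the integer rounding applied
    during simulation (bias well below a percent at the default leaf counts).
    """
    sp, st, _ = params.noise_sd
    rows = {}
    for lv in design.levels:
        g = latent_growth(params, lv.n_rate, lv.p_rate)
        row = {}
        for m in RAW_MEASUREMENTS:
            ld = params.trait_loadings[m]
            b = ld.exponent
            row[m] = ld.scale * g**b * np.exp(b * (b - 1) * (sp**2 + st**2) / 2.0)
        rows[lv.label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "level"
    return out[list(RAW_MEASUREMENTS)]


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_experiment(
    design: ExperimentDesign | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a twig-measurement table for the given design.

    Returns one row per twig with columns
    series, level, n_rate, p_rate, plot, tree, twig, L, BD, LN, TBM, TPM, SM, TLA
    (units cm, cm, count, g, g, g, cm²). Plot identifiers are global
    (1..n_plots); trees and twigs are numbered within their parent. The same
    (design, params, seed) always yields an identical table.
    """
    design = wild_apple_design() if design is None else design
    params = GeneratorParams() if params is None else params
    rng = np.random.default_rng(seed)
    sp, st, sw = params.noise_sd
    lo, hi = design.twigs_per_tree
    n_plots, n_trees = design.plots_per_level, design.trees_per_plot

    frames: list[pd.DataFrame] = []
    plot_offset = 0
    for lv in design.levels:
        g_level = latent_growth(params, lv.n_rate, lv.p_rate)
        g_plot = g_level * _mean_one_lognormal(rng, sp, n_plots)
        g_tree = g_plot[:, None] * _mean_one_lognormal(rng, st, (n_plots, n_trees))
        twigs_per_tree = rng.integers(lo, hi + 1, size=(n_plots, n_trees))
        counts = twigs_per_tree.ravel()
        g_twig = np.repeat(g_tree.ravel(), counts)
        n_rows = g_twig.size

        cols: dict[str, np.ndarray] = {
            "plot": np.repeat(
                plot_offset + 1 + np.repeat(np.arange(n_plots), n_trees), counts
            ),
            "tree": np.repeat(np.tile(np.arange(1, n_trees + 1), n_plots), counts),
            "twig": np.concatenate([np.arange(1, c + 1) for c in counts]),
        }
        for m in RAW_MEASUREMENTS:
            ld = params.trait_loadings[m]
            val = ld.scale * g_twig**ld.exponent * _mean_one_lognormal(rng, sw, n_rows)
            if m == "LN":
                val = np.maximum(1, np.rint(val)).astype(int)
            cols[m] = val
        frame = pd.DataFrame(cols)
        frame.insert(0, "series", lv.series)
        frame.insert(1, "level", lv.label)
        frame.insert(2, "n_rate", lv.n_rate)
        frame.insert(3, "p_rate", lv.p_rate)
        frames.append(frame)
        plot_offset += n_plots
    table = pd.concat(frames, ignore_index=True)
    return table[list(ID_COLUMNS) + list(RAW_MEASUREMENTS)]
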