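"""Factorial nutrient-addition experimental design.

The reference design is a four-year N/P fertilization trial on wild apple
(*Malus sieversii*) saplings: three N-only rates (10, 20, 40 g m⁻² yr⁻¹),
three P-only rates (2, 4, 8 g m⁻² yr⁻¹), two combined series that share the
N20P4 level (fixed N20 with variable P, and variable N with fixed P4), and a
single water-only control (CK) — 12 unique treatment levels, five replicate
plots each, four saplings per plot, 1–3 current-year twigs per sapling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TreatmentLevel",
    "ExperimentDesign",
    "wild_apple_design",
    "SERIES_LEVELS",
]

#: Treatment levels belonging to each dose series. N20P4 is shared between
#: the two combined series and listed under both.
SERIES_LEVELS: Mapping[str, tuple[str, ...]] = {
    "N": ("N10", "N20", "N40"),
    "P": ("P2", "P4", "P8"),
    "N20Px": ("N20P2", "N20P4", "N20P8"),
    "NxP4": ("N10P4", "N20P4", "N40P4"),
}


@dataclass(frozen=True)
class TreatmentLevel:
    """One fertilization level: label, N and P rates (g m⁻² yr⁻¹), series tag."""

    label: str
    n_rate: float
    p_rate: float
    series: str

    def __post_init__(self) -> None:
        if self.n_rate < 0 or self.p_rate < 0:
            raise ValueError(f"negative nutrient rate in level {self.label!r}")
        if self.series not in ("CK", "N", "P", "N20Px", "NxP4"):
            raise ValueError(f"unknown series tag {self.series!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """A replicated factorial layout of treatment levels.

    Invariants enforced at construction: unique level labels, exactly one
    unfertilized control (CK), and at least one twig per tree.
    """

    levels: tuple[TreatmentLevel, ...]
    plots_per_level: int = 5
    trees_per_plot: int = 4
    twigs_per_tree: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate level labels: {dup}")
        controls = [lv for lv in self.levels if lv.n_rate == 0 and lv.p_rate == 0]
        if len(controls) != 1:
            raise ValueError(
                f"design must contain exactly one unfertilized control, found {len(controls)}"
            )
        if self.plots_per_level < 1 or self.trees_per_plot < 1:
            raise ValueError("plots_per_level and trees_per_plot must be >= 1")
        lo, hi = self.twigs_per_tree
        if lo < 1 or hi < lo:
            raise ValueError("twigs_per_tree must be an inclusive range with lower bound >= 1")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_plots(self) -> int:
        return self.n_levels * self.plots_per_level

    @property
    def control(self) -> TreatmentLevel:
        return next(lv for lv in self.levels if lv.n_rate == 0 and lv.p_rate == 0)

    def level(self, label: str) -> TreatmentLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"no treatment level {label!r} in design")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    def to_dict(self) -> dict:
        return {
            "levels": [
                {"label": lv.label, "n_rate": lv.n_rate, "p_rate": lv.p_rate, "series": lv.series}
                for lv in self.levels
            ],
            "plots_per_level": self.plots_per_level,
            "trees_per_plot": self.trees_per_plot,
            "twigs_per_tree": list(self.twigs_per_tree),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        return cls(
            levels=tuple(TreatmentLevel(**lv) for lv in d["levels"]),
            plots_per_level=int(d.get("plots_per_level", 5)),
            trees_per_plot=int(d.get("trees_per_plot", 4)),
            twigs_per_tree=tuple(d.get("twigs_per_tree", (1, 3))),  # type: ignore[arg-type]
        )


def wild_apple_design() -> ExperimentDesign:
    """The 12-level wild-apple sapling fertilization design (60 plots).

    CK plus N10/N20/N40, P2/P4/P8, N20P2/N20P4/N20P8 and N10P4/N40P4;
    N20P4 belongs to both combined series but appears once, tagged N20Px.
    """
    levels = [TreatmentLevel("CK", 0, 0, "CK")]
    levels += [TreatmentLevel(f"N{d}", d, 0, "N") for d in (10, 20, 40)]
    levels += [TreatmentLevel(f"P{d}", 0, d, "P") for d in (2, 4, 8)]
    levels += [TreatmentLevel(f"N20P{d}", 20, d, "N20Px") for d in (2, 4, 8)]
    levels += [TreatmentLevel(f"N{d}P4", d, 4, "NxP4") for d in (10, 40)]
    return ExperimentDesign(levels=tuple(levels))
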