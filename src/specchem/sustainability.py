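"""Quantitative sustainability calculators: carbon footprint, blueness, whiteness.

* Carbon footprint (kg CO2 eq per sample): sum over instruments of
  power (kW) x analysis time (h) x grid emission factor (kg CO2/kWh).
* BAGI blueness: ten practicality criteria scored 1 (worst) to 10 (best);
  the composite is the geometric mean, reported here on a 10-100 scale
  (ten equal scores s map to 10*s).  The original tool's exact rounding is
  not reproduced.
* RGB12 whiteness: twelve algorithm scores on 0-100 in three groups — red
  (validation), green (environmental), blue (economic/practical) — each
  color is the mean of its four scores and whiteness the mean of the three
  colors; optional weights default to uniform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gmean

from .errors import SpecchemError

__all__ = [
    "InstrumentUsage",
    "BagiInput",
    "Rgb12Input",
    "carbon_footprint",
    "bagi_score",
    "rgb12_whiteness",
]

BAGI_CRITERIA = (
    "analysis_type",
    "number_of_analytes",
    "instrumentation",
    "sample_throughput",
    "sample_preparation",
    "samples_per_hour",
    "reagents",
    "preconcentration",
    "automation_degree",
    "sample_amount",
)


@dataclass(frozen=True)
class InstrumentUsage:
    """One instrument's contribution: power (kW), time (h), emission factor
    (kg CO2 per kWh)."""

    power_kw: float
    hours: float
    emission_factor: float

    def __post_init__(self) -> None:
        if self.power_kw < 0 or self.hours < 0 or self.emission_factor < 0:
            raise SpecchemError("instrument usage fields must be >= 0")


@dataclass(frozen=True)
class BagiInput:
    """Exactly ten practicality criterion scores, each on 1-10."""

    criteria: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.criteria) != 10:
            raise SpecchemError(f"BAGI needs exactly 10 criteria, got {len(self.criteria)}")
        for name, s in zip(BAGI_CRITERIA, self.criteria):
            if not 1 <= s <= 10:
                raise SpecchemError(f"BAGI criterion {name!r} = {s} outside [1, 10]")


@dataclass(frozen=True)
class Rgb12Input:
    """Four red (validation), green (environmental) and blue (practical)
    algorithm scores, each on 0-100."""

    red: tuple[float, float, float, float]
    green: tuple[float, float, float, float]
    blue: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for color in ("red", "green", "blue"):
            scores = getattr(self, color)
            if len(scores) != 4:
                raise SpecchemError(f"{color} group needs exactly 4 scores")
            for s in scores:
                if not 0 <= s <= 100:
                    raise SpecchemError(f"{color} score {s} outside [0, 100]")


def carbon_footprint(usages: list[InstrumentUsage]) -> float:
    """Total kg CO2 eq per sample, summed over instruments."""
    if not usages:
        raise SpecchemError("need at least one instrument usage")
    return float(sum(u.power_kw * u.hours * u.emission_factor for u in usages))


def bagi_score(inp: BagiInput) -> float:
    """10 x geometric mean of the ten criteria (range 10-100)."""
    return float(10.0 * gmean(np.asarray(inp.criteria, dtype=float)))


def rgb12_whiteness(
    inp: Rgb12Input,
    weights: tuple[float, float, float] | None = None,
) -> dict:
    """Per-color means and the aggregate whiteness (0-100)."""
    colors = {
        "red": float(np.mean(inp.red)),
        "green": float(np.mean(inp.green)),
        "blue": float(np.mean(inp.blue)),
    }
    w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() == 0:
        raise SpecchemError("weights must be 3 non-negative values with a positive sum")
    vals = np.array([colors["red"], colors["green"], colors["blue"]])
    colors["whiteness"] = float((vals * w).sum() / w.sum())
    return colors
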