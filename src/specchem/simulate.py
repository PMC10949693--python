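"""Synthetic two-component Beer-Lambert UV-vis spectra.

The generator emulates the statistical structure of strongly overlapping
two-drug absorbance data: each pure component is a sum of Gaussian bands
(absorptivity per ug/mL), mixtures mix linearly in concentration, and the
detector adds homoscedastic Gaussian absorbance noise plus an optional
constant per-sample baseline offset.

The default scenario places the two components' dominant bands at 218 and
228 nm (strong overlap below 250 nm) and gives one component an additional
resolved band near 285 nm, with amplitudes chosen so the 10-30 ug/mL
calibration mixtures peak between 0.2 and 1.5 AU.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSpec, MixtureDesign
from .errors import SpecchemError
from .spectra import SpectralMatrix, WavelengthGrid

__all__ = [
    "GaussianBand",
    "PureComponentModel",
    "NoiseModel",
    "Scenario",
    "ConfinedSignalScenario",
    "pure_spectrum",
    "simulate_mixtures",
    "simulate_confined",
    "confined_signal_scenario",
    "default_scenario",
]


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), Gaussian sigma (nm), peak absorptivity
    (AU per ug/mL)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise SpecchemError(f"band width must be positive, got {self.width_nm}")
        if self.amplitude < 0:
            raise SpecchemError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class PureComponentModel:
    """Per-analyte unit-concentration absorptivity profile as a band sum."""

    analyte: str
    bands: tuple[GaussianBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise SpecchemError(f"{self.analyte}: need at least one band")


@dataclass(frozen=True)
class NoiseModel:
    """Additive homoscedastic Gaussian absorbance noise plus baseline offsets.

    ``baseline_sigma > 0`` draws a constant offset per sample from
    N(baseline_offset, baseline_sigma^2); otherwise every sample gets the
    fixed ``baseline_offset``.
    """

    sigma_abs: float = 0.002
    baseline_offset: float = 0.0
    baseline_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.baseline_sigma < 0:
            raise SpecchemError("noise standard deviations must be >= 0")


def pure_spectrum(model: PureComponentModel, grid: WavelengthGrid) -> np.ndarray:
    """Unit-concentration spectrum (AU per ug/mL) on the grid."""
    wl = grid.wavelengths()
    out = np.zeros_like(wl)
    for band in model.bands:
        out += band.amplitude * np.exp(-((wl - band.center_nm) ** 2) / (2.0 * band.width_nm**2))
    return out


def simulate_mixtures(
    design: MixtureDesign,
    pures: tuple[PureComponentModel, PureComponentModel],
    grid: WavelengthGrid,
    noise: NoiseModel,
) -> SpectralMatrix:
    """Beer-Lambert mixing: row_i = sum_k c_ik * pure_k + baseline_i + eps."""
    names = [p.analyte for p in pures]
    missing = [n for n in names if n not in design.concentrations.columns]
    if missing:
        raise SpecchemError(f"design lacks analytes {missing} required by the pure models")
    C = design.concentrations[names].to_numpy(dtype=float)
    if (C < 0).any():
        raise SpecchemError("negative concentrations are not physical")
    S = np.stack([pure_spectrum(p, grid) for p in pures])
    A = C @ S
    rng = np.random.default_rng(noise.seed)
    if noise.baseline_sigma > 0:
        baselines = rng.normal(noise.baseline_offset, noise.baseline_sigma, size=len(C))
    else:
        baselines = np.full(len(C), noise.baseline_offset)
    A = A + baselines[:, None]
    if noise.sigma_abs > 0:
        A = A + rng.normal(0.0, noise.sigma_abs, size=A.shape)
    return SpectralMatrix(grid, A, list(design.concentrations.index))


@dataclass(frozen=True)
class ConfinedSignalScenario:
    """A wavelength-selection stress setting: analyte signal confined to one
    region, the rest of the spectrum dominated by matrix absorption.

    Both analyte band sets live inside ``region_nm``; outside it, several
    independent matrix absorbers (excipient-like components whose per-sample
    amounts vary but carry no analyte information) tile the spectrum.  Their
    number exceeds the latent-variable budget of the selection fitness, so
    including out-of-region wavelengths measurably degrades cross-validated
    prediction — which is what gives variable selection a real gradient.
    Pure i.i.d. detector noise outside the region would not: a latent-variable
    regression is nearly flat in such channels.
    """

    pures: tuple[PureComponentModel, PureComponentModel]
    interferents: tuple[PureComponentModel, ...]
    grid: WavelengthGrid
    noise_sigma: float
    region_nm: tuple[float, float]
    interferent_conc_range: tuple[float, float] = (5.0, 25.0)


def confined_signal_scenario() -> ConfinedSignalScenario:
    """Default confined-signal setting: analyte bands inside 240-300 nm,
    six matrix absorbers covering 210-240 and 300-400 nm."""
    pures = (
        PureComponentModel("LCZ", (GaussianBand(259.0, 8.0, 0.027),)),
        PureComponentModel("MLK", (GaussianBand(277.0, 8.0, 0.024),)),
    )
    interferents = tuple(
        PureComponentModel(f"matrix_{i + 1}", (GaussianBand(c, w, a),))
        for i, (c, w, a) in enumerate(
            [
                (216.0, 9.0, 0.020),
                (231.0, 8.0, 0.018),
                (312.0, 10.0, 0.020),
                (338.0, 12.0, 0.020),
                (365.0, 12.0, 0.018),
                (392.0, 10.0, 0.020),
            ]
        )
    )
    return ConfinedSignalScenario(
        pures=pures,
        interferents=interferents,
        grid=WavelengthGrid(200.0, 400.0, 1.0),
        noise_sigma=0.002,
        region_nm=(240.0, 300.0),
    )


def simulate_confined(
    design: MixtureDesign, scenario: ConfinedSignalScenario, seed: int
) -> SpectralMatrix:
    """Mixture spectra for the confined-signal setting.

    Analytes mix per the design; each matrix absorber gets an independent
    uniform per-sample amount drawn from ``seed``; detector noise is added
    on top.
    """
    base = simulate_mixtures(
        design, scenario.pures, scenario.grid, NoiseModel(scenario.noise_sigma, seed=seed)
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F]))
    lo, hi = scenario.interferent_conc_range
    A = base.absorbance
    for p in scenario.interferents:
        amounts = rng.uniform(lo, hi, size=base.n_samples)
        A = A + amounts[:, None] * pure_spectrum(p, scenario.grid)
    return SpectralMatrix(scenario.grid, A, list(base.sample_ids))


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setting: design spec, pure profiles, grid, noise."""

    design_spec: DesignSpec
    pures: tuple[PureComponentModel, PureComponentModel]
    grid: WavelengthGrid
    noise: NoiseModel
    trim_lo_nm: float = 210.0
    trim_hi_nm: float = 400.0


def default_scenario(seed: int = 0) -> Scenario:
    """Deterministic default setting for the two-drug quantification problem.

    Acquisition grid 200-400 nm at 1 nm (modeling range 210-400 nm, 191
    points), calibration levels spanning 10-30 ug/mL for both analytes, and
    additive noise of 0.002 AU.  Band constants are fixed here, not fitted to
    any measured spectrum.
    """
    lcz = PureComponentModel(
        "LCZ",
        (GaussianBand(228.0, 13.0, 0.027),),
    )
    mlk = PureComponentModel(
        "MLK",
        (GaussianBand(218.0, 12.0, 0.024), GaussianBand(285.0, 14.0, 0.015)),
    )
    return Scenario(
        design_spec=DesignSpec(),
        pures=(lcz, mlk),
        grid=WavelengthGrid(200.0, 400.0, 1.0),
        noise=NoiseModel(sigma_abs=0.002, seed=seed),
    )
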