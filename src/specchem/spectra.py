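"""Spectral data containers and pre-modeling transforms.

A :class:`SpectralMatrix` holds a block of absorbance spectra (rows are
samples, columns are wavelengths) bound to a uniform :class:`WavelengthGrid`.
The transforms here are the ones applied before multivariate calibration:
wavelength-range trimming, column mean-centering (with the removed means kept
for later application to prediction samples), and unweighted moving-window
smoothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GridError, SpecchemError

__all__ = [
    "WavelengthGrid",
    "SpectralMatrix",
    "PreprocessState",
    "trim",
    "mean_center",
    "apply_centering",
    "undo_centering",
    "moving_window_smooth",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Closed-interval uniform wavelength axis, inclusive at both ends.

    ``210-400 nm at 1 nm`` therefore has 191 points.
    """

    start_nm: float
    end_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise GridError(f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})")
        if not self.step_nm > 0:
            raise GridError(f"step_nm must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise GridError(
                f"(end_nm - start_nm) = {self.end_nm - self.start_nm} is not an "
                f"integer multiple of step_nm = {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.start_nm + self.step_nm * np.arange(self.n_points), dtype=float)

    def index_of(self, nm: float) -> int:
        """Index of a wavelength on the grid; raises if off-grid."""
        pos = (nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= self.n_points or abs(pos - idx) > 1e-9:
            below = self.start_nm + self.step_nm * np.floor(pos)
            above = below + self.step_nm
            raise GridError(
                f"{nm} nm is not on the grid [{self.start_nm}, {self.end_nm}] "
                f"step {self.step_nm}; nearest grid points are {below} and {above} nm"
            )
        return idx


@dataclass
class SpectralMatrix:
    """Sample x wavelength absorbance block (AU) on a uniform grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise SpecchemError("absorbance must be a 2-D array (samples x wavelengths)")
        if self.absorbance.shape[1] != self.grid.n_points:
            raise SpecchemError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.grid.n_points} points"
            )
        if self.absorbance.shape[0] != len(self.sample_ids):
            raise SpecchemError("sample_ids length must match the number of rows")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpecchemError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]}, "
                f"wavelength index {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()


@dataclass
class PreprocessState:
    """Frozen preprocessing derived from a calibration set.

    Stores the trim limits, the removed column means (one per retained
    wavelength, or ``None`` if no centering was applied), and the smoothing
    window width (or ``None``).
    """

    trim_lo_nm: float | None = None
    trim_hi_nm: float | None = None
    column_means: np.ndarray | None = None
    smoothing_window_nm: float | None = field(default=None)


def trim(spectra: SpectralMatrix, lo: float, hi: float) -> SpectralMatrix:
    """Restrict to wavelengths with ``lo <= lambda <= hi`` (both on-grid)."""
    if lo >= hi:
        raise GridError(f"trim requires lo < hi, got {lo} >= {hi}")
    i = spectra.grid.index_of(lo)
    j = spectra.grid.index_of(hi)
    new_grid = WavelengthGrid(lo, hi, spectra.grid.step_nm)
    return SpectralMatrix(new_grid, spectra.absorbance[:, i : j + 1].copy(), list(spectra.sample_ids))


def mean_center(spectra: SpectralMatrix) -> tuple[SpectralMatrix, PreprocessState]:
    """Remove per-wavelength column means; the means are kept in the state."""
    if spectra.n_samples < 2:
        raise SpecchemError(
            "mean-centering needs at least 2 samples (a single-sample mean "
            "cannot be reused for prediction)"
        )
    means = spectra.absorbance.mean(axis=0)
    centered = replace(spectra, absorbance=spectra.absorbance - means)
    state = PreprocessState(
        trim_lo_nm=spectra.grid.start_nm,
        trim_hi_nm=spectra.grid.end_nm,
        column_means=means,
    )
    return centered, state


def apply_centering(state: PreprocessState, spectra: SpectralMatrix) -> SpectralMatrix:
    """Subtract calibration-set column means from new spectra."""
    if state.column_means is None:
        return spectra
    if len(state.column_means) != spectra.grid.n_points:
        raise SpecchemError(
            f"stored means cover {len(state.column_means)} wavelengths but the "
            f"spectra have {spectra.grid.n_points}"
        )
    return replace(spectra, absorbance=spectra.absorbance - state.column_means)


def undo_centering(state: PreprocessState, spectra: SpectralMatrix) -> SpectralMatrix:
    if state.column_means is None:
        return spectra
    return replace(spectra, absorbance=spectra.absorbance + state.column_means)


def moving_window_smooth(spectra: SpectralMatrix, window_nm: float) -> SpectralMatrix:
    """Unweighted boxcar smoothing with edge truncation.

    Each point becomes the mean of the window centered on it; near the edges
    the window shrinks to the available points rather than padding.
    """
    step = spectra.grid.step_nm
    w = window_nm / step
    w_int = int(round(w))
    if abs(w - w_int) > 1e-9 or w_int < 1:
        raise GridError(f"window ({window_nm} nm) must be a positive multiple of the grid step ({step} nm)")
    if w_int % 2 == 0:
        raise GridError(
            f"window must span an odd number of grid points; {window_nm} nm is "
            f"{w_int} points — use {(w_int - 1) * step} or {(w_int + 1) * step} nm"
        )
    if w_int == 1:
        return replace(spectra, absorbance=spectra.absorbance.copy())
    kernel = np.ones(w_int)
    n = spectra.grid.n_points
    counts = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = np.stack(
        [np.convolve(row, kernel, mode="same") / counts for row in spectra.absorbance]
    )
    return replace(spectra, absorbance=smoothed)
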