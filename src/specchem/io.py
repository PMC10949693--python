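"""CSV I/O for spectra and concentration tables.

Spectra use a wavelength-first wide layout: header
``wavelength_nm,<sample_id_1>,...`` with one row per wavelength.
Concentration tables: header ``sample_id,<analyte>_ug_per_ml,...`` with one
row per sample.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .spectra import SpectralMatrix, WavelengthGrid

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
]

_CONC_SUFFIX = "_ug_per_ml"


def read_spectra(path: str | Path) -> SpectralMatrix:
    """Read a wide-format spectra CSV into a :class:`SpectralMatrix`.

    The first column must be a strictly increasing, uniformly spaced
    wavelength axis; remaining columns are per-sample absorbances.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a wavelength column plus at least one sample column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        df[col] = coerced
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if len(wl) < 2:
        raise FormatError(f"{path}: need at least two wavelength rows")
    diffs = np.diff(wl)
    step = diffs[0]
    if step <= 0:
        raise FormatError(f"{path}: wavelength column must be strictly increasing (row 3)")
    bad = np.where(np.abs(diffs - step) > 1e-6 * max(1.0, abs(step)))[0]
    if bad.size:
        # +3: 1 for the header line, 1 for 1-based rows, 1 for the diff offset
        raise FormatError(
            f"{path}: non-uniform wavelength spacing at row {bad[0] + 3} "
            f"(step {diffs[bad[0]]} vs expected {step})"
        )
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectralMatrix(grid, absorbance, [str(c) for c in df.columns[1:]])


def write_spectra(spectra: SpectralMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        spectra.absorbance.T,
        columns=spectra.sample_ids,
    )
    df.insert(0, "wavelength_nm", spectra.wavelengths())
    df.to_csv(path, index=False)


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a concentration table; returns a sample x analyte DataFrame (ug/mL)."""
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    df.columns = [c.removesuffix(_CONC_SUFFIX) for c in df.columns]
    return df.astype(float)


def write_concentrations(conc: pd.DataFrame, path: str | Path) -> None:
    out = conc.copy()
    out.columns = [f"{c}{_CONC_SUFFIX}" for c in out.columns]
    out.index.name = "sample_id"
    out.to_csv(path)
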