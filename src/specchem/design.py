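"""Structured calibration and validation mixture designs.

Two designs are provided for a two-analyte system:

* a 25-run five-level cyclic multilevel calibration design (Brereton-style),
  in which each analyte visits five coded levels (-2..+2) five times each and
  the two coded columns are orthogonal; the second analyte's code sequence is
  the first's shifted by one run (cyclically), and
* a stratified Latin hypercube validation design that splits each analyte's
  concentration range into ``n_strata`` equal-width strata and draws exactly
  one sample per stratum, with independent stratum permutations per analyte.

A prime stratum count (e.g. 13) is recommended for the Latin hypercube: it
avoids periodic resonances with the five calibration levels, though this is
not enforced.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = [
    "DesignSpec",
    "LHSSpec",
    "MixtureDesign",
    "brereton_design",
    "lhs_design",
    "coverage_diagnostics",
    "CANONICAL_CODES_5",
]

# Canonical realization of the five-level two-factor cyclic design: the coded
# sequence of the first analyte; the second analyte's code at run i is the
# first's at run i+1 (cyclic).  Levels -2..+2, each occurring 5 times.
CANONICAL_CODES_5: tuple[int, ...] = (
    0, 0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
    0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)


def _cyclic_shift(seq: tuple[int, ...]) -> tuple[int, ...]:
    return seq[1:] + seq[:1]


def _check_canonical() -> None:
    a = np.array(CANONICAL_CODES_5)
    b = np.array(_cyclic_shift(CANONICAL_CODES_5))
    counts = {lvl: int(np.sum(a == lvl)) for lvl in (-2, -1, 0, 1, 2)}
    if any(c != 5 for c in counts.values()):
        raise DesignError(f"canonical sequence is unbalanced: {counts}")
    if int(a.sum()) != 0 or int(b.sum()) != 0 or int(a @ b) != 0:
        raise DesignError("canonical coded columns are not centered/orthogonal")


_check_canonical()


@dataclass(frozen=True)
class DesignSpec:
    """Specification of the cyclic multilevel calibration design."""

    analyte_names: tuple[str, str] = ("LCZ", "MLK")
    low: tuple[float, float] = (10.0, 10.0)
    high: tuple[float, float] = (30.0, 30.0)
    n_levels: int = 5

    def __post_init__(self) -> None:
        if len(self.analyte_names) != 2:
            raise DesignError("only two-analyte designs are supported")
        for lo, hi, name in zip(self.low, self.high, self.analyte_names):
            if not lo < hi:
                raise DesignError(f"degenerate range for {name}: low {lo} >= high {hi}")
        if self.n_levels < 3 or self.n_levels % 2 == 0:
            raise DesignError(f"n_levels must be odd and >= 3, got {self.n_levels}")

    @property
    def n_runs(self) -> int:
        return self.n_levels**2


@dataclass(frozen=True)
class LHSSpec:
    """Specification of the stratified Latin hypercube validation design."""

    n_strata: int = 13
    analyte_names: tuple[str, str] = ("LCZ", "MLK")
    low: tuple[float, float] = (10.0, 10.0)
    high: tuple[float, float] = (30.0, 30.0)
    seed: int = 0
    round_to: int | None = None

    def __post_init__(self) -> None:
        if self.n_strata < 1:
            raise DesignError(f"n_strata must be >= 1, got {self.n_strata}")
        for lo, hi, name in zip(self.low, self.high, self.analyte_names):
            if not (hi - lo) / self.n_strata > 0:
                raise DesignError(f"degenerate range for {name}: low {lo} >= high {hi}")


@dataclass
class MixtureDesign:
    """A set of mixtures: concentrations (ug/mL) plus optional coded levels."""

    role: str  # "calibration" | "validation"
    concentrations: pd.DataFrame
    coded: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.concentrations)

    @property
    def analyte_names(self) -> list[str]:
        return list(self.concentrations.columns)


def brereton_design(spec: DesignSpec) -> MixtureDesign:
    """Generate the canonical 25-run five-level two-analyte calibration design.

    Codes map to concentrations by ``c = center + code * step`` with
    ``center = (low + high)/2`` and ``step = (high - low)/(n_levels - 1)``.
    """
    if spec.n_levels != 5:
        raise DesignError(
            f"unsupported design: only the 5-level two-factor cyclic design is "
            f"implemented (requested {spec.n_levels} levels)"
        )
    codes = np.column_stack(
        [CANONICAL_CODES_5, _cyclic_shift(CANONICAL_CODES_5)]
    ).astype(float)
    conc = np.empty_like(codes)
    for j, (lo, hi) in enumerate(zip(spec.low, spec.high)):
        center = (lo + hi) / 2.0
        step = (hi - lo) / (spec.n_levels - 1)
        conc[:, j] = center + codes[:, j] * step
    ids = [f"cal_{i + 1:02d}" for i in range(spec.n_runs)]
    conc_df = pd.DataFrame(conc, index=ids, columns=list(spec.analyte_names))
    conc_df.index.name = "sample_id"
    coded_df = pd.DataFrame(codes.astype(int), index=ids, columns=list(spec.analyte_names))
    coded_df.index.name = "sample_id"
    return MixtureDesign("calibration", conc_df, coded_df, {"spec": spec})


def lhs_design(spec: LHSSpec) -> MixtureDesign:
    """Stratified Latin hypercube sample: one mixture per equal-width stratum.

    Stratum permutations are drawn independently per analyte and positions
    within each stratum are uniform.  Optional decimal rounding is a lossy
    post-step: collapsed duplicates are recorded as warnings in the metadata,
    and the pre-rounding values are kept there for occupancy diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strata
    cols = {}
    for name, lo, hi in zip(spec.analyte_names, spec.low, spec.high):
        width = (hi - lo) / n
        strata = rng.permutation(n)
        cols[name] = lo + (strata + rng.random(n)) * width
    ids = [f"val_{i + 1:02d}" for i in range(n)]
    exact = pd.DataFrame(cols, index=ids)
    exact.index.name = "sample_id"
    meta: dict = {"spec": spec, "unrounded": exact.copy(), "warnings": []}
    out = exact
    if spec.round_to is not None:
        out = exact.round(spec.round_to)
        for name in spec.analyte_names:
            if out[name].duplicated().any():
                meta["warnings"].append(
                    f"rounding to {spec.round_to} decimals collapsed samples to "
                    f"equal {name} values; one-per-stratum occupancy is no longer strict"
                )
    return MixtureDesign("validation", out, None, meta)


def coverage_diagnostics(design: MixtureDesign) -> dict:
    """Concentration-space coverage summary.

    Reports the correlation of the two coded calibration columns (NaN-flagged
    when degenerate), per-analyte stratum occupancy for Latin hypercube
    validation designs (computed pre-rounding), and the minimum pairwise
    Euclidean distance between mixtures.
    """
    if design.n_samples == 0:
        raise DesignError("empty design")
    diag: dict = {"n_samples": design.n_samples}
    if design.coded is not None and design.coded.shape[1] == 2:
        a, b = (design.coded.iloc[:, j].to_numpy(dtype=float) for j in (0, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = float(np.corrcoef(a, b)[0, 1])
        diag["coded_correlation"] = corr
        diag["degenerate_coding"] = bool(math.isnan(corr))
    spec = design.metadata.get("spec")
    if design.role == "validation" and isinstance(spec, LHSSpec):
        values = design.metadata.get("unrounded", design.concentrations)
        occupancy = {}
        for name, lo, hi in zip(spec.analyte_names, spec.low, spec.high):
            edges = np.linspace(lo, hi, spec.n_strata + 1)
            hist, _ = np.histogram(values[name].to_numpy(), bins=edges)
            occupancy[name] = hist.tolist()
        diag["stratum_occupancy"] = occupancy
    if design.n_samples >= 2:
        pts = design.concentrations.to_numpy(dtype=float)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        diag["min_pairwise_distance"] = float(d[np.triu_indices(len(pts), k=1)].min())
    else:
        diag["min_pairwise_distance"] = None
        diag["degenerate_distance"] = True
    return diag
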