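"""Figures of merit for calibration and external validation.

Implements the full validation-statistic suite for one model/analyte pair:
RSS, SSX, R^2, PRESS, Q^2, the RMSE family (RMSEC / RMSECV / RMSEP), bias,
SEC, RRMSEP, BCMSEP, LOD/LOQ from the prediction-vs-measured regression,
percent recovery with %RSD, and the one-way ANOVA used to compare models.

Conventions follow the printed equations of the source workflow rather than
textbook defaults where they differ; in particular RRMSEP% carries a 1/n
prefactor (not 1/sqrt(n)) by default:

    RRMSEP% = (1/n) * sqrt(sum (y_i - yhat_i)^2) / y_bar * 100

The conventional form sqrt(RSS/n)/y_bar*100 is available via ``form``.
SEC uses an n-1 denominator after bias correction, the RMSE family uses n,
and LOD/LOQ are 3.3 sigma/S and 10 sigma/S with sigma the residual standard
error (n-2) of the ordinary least-squares line of measured (y) on predicted
(x) concentrations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecchemError

__all__ = [
    "PairedOutcomes",
    "RegressionLine",
    "MeritReport",
    "core_stats",
    "q2_press",
    "precision_stats",
    "regression_line",
    "lod_loq",
    "recovery_rsd",
    "anova_oneway",
    "merit_report",
]


@dataclass
class PairedOutcomes:
    """Reference vs predicted concentrations for one analyte in one context."""

    y_observed: np.ndarray
    y_predicted: np.ndarray
    context: str = "calibration"  # calibration | cross_validation | prediction

    def __post_init__(self) -> None:
        self.y_observed = np.asarray(self.y_observed, dtype=float)
        self.y_predicted = np.asarray(self.y_predicted, dtype=float)
        if self.y_observed.shape != self.y_predicted.shape or self.y_observed.ndim != 1:
            raise SpecchemError("y_observed and y_predicted must be equal-length 1-D arrays")
        if self.y_observed.size < 1:
            raise SpecchemError("need at least one sample")
        if not (np.all(np.isfinite(self.y_observed)) and np.all(np.isfinite(self.y_predicted))):
            raise SpecchemError("non-finite concentration values")

    @property
    def n(self) -> int:
        return self.y_observed.size


@dataclass
class RegressionLine:
    """OLS line of measured (y-axis) on predicted (x-axis) concentrations."""

    slope: float
    intercept: float
    sigma: float  # residual standard error, n-2 denominator

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SpecchemError("sigma must be >= 0")


def core_stats(p: PairedOutcomes) -> dict:
    """RSS, SSX, R^2 (= 1 - RSS/SSX), RMSE (= sqrt(RSS/n)) and bias."""
    resid = p.y_observed - p.y_predicted
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / p.n)
    bias = float(resid.mean())
    out = {"rss": rss, "rmse": rmse, "bias": bias, "ssx": math.nan, "r2": math.nan, "r2_defined": False}
    if p.n >= 2:
        dev = p.y_observed - p.y_observed.mean()
        ssx = float(dev @ dev)
        out["ssx"] = ssx
        if ssx > 0:
            out["r2"] = 1.0 - rss / ssx
            out["r2_defined"] = True
    return out


def q2_press(p: PairedOutcomes, ssx: float) -> dict:
    """PRESS from cross-validated predictions and Q^2 = 1 - PRESS/SSX."""
    resid = p.y_observed - p.y_predicted
    press = float(resid @ resid)
    out = {"press": press, "q2": math.nan, "q2_defined": False}
    if ssx > 0:
        out["q2"] = 1.0 - press / ssx
        out["q2_defined"] = True
    return out


def precision_stats(p: PairedOutcomes, form: str = "paper") -> dict:
    """SEC, RRMSEP%% and BCMSEP per the printed equations.

    ``form="paper"`` keeps the 1/n prefactor inside RRMSEP%;
    ``form="conventional"`` uses RMSE/y_bar*100.
    """
    if p.n < 2:
        raise SpecchemError("precision statistics need n >= 2")
    resid = p.y_observed - p.y_predicted
    bias = float(resid.mean())
    sec = math.sqrt(float(((resid - bias) ** 2).sum()) / (p.n - 1))
    rss = float(resid @ resid)
    bcmsep = rss / p.n - bias**2
    y_bar = float(p.y_observed.mean())
    if y_bar == 0:
        rrmsep = math.nan
        defined = False
    else:
        defined = True
        if form == "paper":
            rrmsep = (math.sqrt(rss) / p.n) / y_bar * 100.0
        elif form == "conventional":
            rrmsep = math.sqrt(rss / p.n) / y_bar * 100.0
        else:
            raise SpecchemError(f"unknown RRMSEP form {form!r}")
    return {"sec": sec, "rrmsep_pct": rrmsep, "rrmsep_defined": defined, "bcmsep": bcmsep}


def regression_line(p: PairedOutcomes) -> RegressionLine:
    """Fit measured (y) on predicted (x) by OLS; sigma is the residual
    standard error with an n-2 denominator."""
    if p.n < 3:
        raise SpecchemError("regression line needs n >= 3 for a residual standard error")
    res = stats.linregress(p.y_predicted, p.y_observed)
    fitted = res.intercept + res.slope * p.y_predicted
    sigma = math.sqrt(float(((p.y_observed - fitted) ** 2).sum()) / (p.n - 2))
    return RegressionLine(float(res.slope), float(res.intercept), sigma)


def lod_loq(line: RegressionLine) -> tuple[float, float]:
    """LOD = 3.3 sigma/S and LOQ = 10 sigma/S."""
    if line.slope == 0:
        raise SpecchemError("zero slope: LOD/LOQ undefined")
    return 3.3 * line.sigma / line.slope, 10.0 * line.sigma / line.slope


def recovery_rsd(
    found: Sequence[float],
    nominal: Sequence[float],
    replicate_groups: Sequence | None = None,
) -> pd.DataFrame:
    """Percent recovery and per-group %RSD.

    ``replicate_groups`` labels replicates of the same level; per group the
    mean recovery and %RSD (= 100*SD/mean, SD with n-1) are reported.  With
    no grouping, all samples form one group.
    """
    found = np.asarray(found, dtype=float)
    nominal = np.asarray(nominal, dtype=float)
    if found.shape != nominal.shape:
        raise SpecchemError("found and nominal must have equal lengths")
    if np.any(nominal <= 0):
        raise SpecchemError("nominal concentrations must be > 0")
    rec = 100.0 * found / nominal
    groups = np.asarray(replicate_groups if replicate_groups is not None else np.zeros(len(rec)))
    rows = []
    for g in pd.unique(groups):
        r = rec[groups == g]
        mean = float(r.mean())
        sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": int(r.size),
                "mean_recovery_pct": mean,
                "sd_recovery_pct": sd,
                "rsd_pct": 100.0 * sd / mean if mean != 0 else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class AnovaResult:
    f: float
    p: float
    f_critical: float
    df_between: int
    df_within: int
    degenerate: bool = False


def anova_oneway(groups: Iterable[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across models' recovery lists, with the critical F."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise SpecchemError("ANOVA needs >= 2 groups with >= 2 values each")
    dfb = len(arrays) - 1
    dfw = sum(a.size for a in arrays) - len(arrays)
    f_crit = float(stats.f.ppf(1 - alpha, dfb, dfw))
    within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [a.mean() for a in arrays]
    if within == 0 and len(set(np.round(means, 12))) > 1:
        return AnovaResult(math.inf, 0.0, f_crit, dfb, dfw, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # all groups identical constants
        f, p = 0.0, 1.0
    return AnovaResult(float(f), float(p), f_crit, dfb, dfw)


@dataclass
class MeritReport:
    """All figures of merit for one model/analyte pair."""

    model: str
    analyte: str
    rss: float
    ssx: float
    r2: float
    rmsec: float
    press: float
    q2: float
    rmsecv: float
    rmsep: float
    bias: float
    sec: float
    rrmsep_pct: float
    bcmsep: float
    lod: float
    loq: float
    mean_recovery_pct: float
    sd_recovery_pct: float
    rsd_pct: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def merit_report(
    model: str,
    analyte: str,
    calibration: PairedOutcomes,
    cross_validation: PairedOutcomes,
    prediction: PairedOutcomes,
    rrmsep_form: str = "paper",
) -> MeritReport:
    """Aggregate the full merit suite from the three prediction contexts.

    R^2/RMSEC and SSX come from the calibration pairs, Q^2/RMSECV from the
    cross-validated pairs, and RMSEP/bias/SEC/RRMSEP/BCMSEP/LOD/LOQ plus the
    recovery summary from the external prediction pairs.
    """
    cal = core_stats(calibration)
    cvs = core_stats(cross_validation)
    q2 = q2_press(cross_validation, cal["ssx"])
    pred = core_stats(prediction)
    prec = precision_stats(prediction, form=rrmsep_form)
    line = regression_line(prediction)
    lod, loq = lod_loq(line)
    rec = recovery_rsd(prediction.y_predicted, prediction.y_observed)
    flags = []
    if not cal["r2_defined"]:
        flags.append("r2 undefined (zero calibration variance)")
    if not q2["q2_defined"]:
        flags.append("q2 undefined (zero calibration variance)")
    if not prec["rrmsep_defined"]:
        flags.append("rrmsep undefined (zero mean reference concentration)")
    return MeritReport(
        model=model,
        analyte=analyte,
        rss=cal["rss"],
        ssx=cal["ssx"],
        r2=cal["r2"],
        rmsec=cal["rmse"],
        press=q2["press"],
        q2=q2["q2"],
        rmsecv=cvs["rmse"],
        rmsep=pred["rmse"],
        bias=pred["bias"],
        sec=prec["sec"],
        rrmsep_pct=prec["rrmsep_pct"],
        bcmsep=prec["bcmsep"],
        lod=lod,
        loq=loq,
        mean_recovery_pct=float(rec["mean_recovery_pct"].iloc[0]),
        sd_recovery_pct=float(rec["sd_recovery_pct"].iloc[0]),
        rsd_pct=float(rec["rsd_pct"].iloc[0]),
        flags=flags,
    )
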