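"""End-to-end desk-scale workflow: design -> simulate -> fit -> validate.

Runs the complete two-drug quantification study on synthetic spectra: build
the 25-run calibration design and the Latin hypercube validation design,
simulate Beer-Lambert mixture spectra, trim to the working range, fit CLS
(auto smoothing window), PCR, PLS and GA-PLS, predict the validation set,
and assemble figures of merit, a triplicate precision block, a one-way
ANOVA across models, and the sustainability calculators into one report.

Every stochastic stage draws its seed from a single master seed through
``numpy.random.SeedSequence`` spawning, so a fixed configuration yields a
byte-identical report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import LHSSpec, MixtureDesign, brereton_design, lhs_design
from .errors import SpecchemError
from .ga import GAConfig, fit_ga_pls
from .merits import (
    MeritReport,
    PairedOutcomes,
    anova_oneway,
    merit_report,
    recovery_rsd,
)
from .models import (
    CalibrationModel,
    CVConfig,
    cross_val_predict,
    fit_cls,
    fit_pcr,
    fit_pls,
    predict,
    select_latent,
)
from .simulate import Scenario, default_scenario, simulate_mixtures
from .spectra import SpectralMatrix, trim
from .sustainability import (
    BagiInput,
    InstrumentUsage,
    Rgb12Input,
    bagi_score,
    carbon_footprint,
    rgb12_whiteness,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "standard_addition", "fit_all_models"]

_PRECISION_LEVELS = (15.0, 20.0, 25.0)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    scenario: Scenario = field(default_factory=default_scenario)
    n_strata: int = 13
    max_lv: int = 10
    cv: CVConfig = field(default_factory=CVConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    include_ga: bool = True
    precision_levels: tuple[float, ...] = _PRECISION_LEVELS
    n_replicates: int = 3
    instrument_usages: tuple[InstrumentUsage, ...] = (InstrumentUsage(0.1, 0.5, 0.4),)
    bagi: BagiInput | None = BagiInput((10, 10, 9, 9, 10, 8, 10, 10, 7, 9))
    rgb12: Rgb12Input | None = Rgb12Input(
        red=(95, 99, 85, 98), green=(95, 92, 90, 95), blue=(90, 95, 92, 85)
    )
    seed: int = 0


@dataclass
class RunReport:
    """Everything one pipeline run computed, JSON-serializable."""

    merits: dict[str, dict[str, MeritReport]]  # model -> analyte -> report
    lv_scans: dict[str, dict]
    ga_summary: dict[str, dict]
    anova: dict[str, dict]
    precision: dict[str, dict]
    sustainability: dict
    provenance: dict

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "merits": {
                    m: {a: r.to_dict() for a, r in per.items()} for m, per in self.merits.items()
                },
                "lv_scans": self.lv_scans,
                "ga_summary": self.ga_summary,
                "anova": self.anova,
                "precision": self.precision,
                "sustainability": self.sustainability,
                "provenance": self.provenance,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def fit_all_models(
    A: SpectralMatrix,
    C: pd.DataFrame,
    cfg: RunConfig,
) -> dict[str, CalibrationModel]:
    """Fit CLS (auto window), PCR, PLS (CV-selected LVs) and optionally GA-PLS."""
    models: dict[str, CalibrationModel] = {}
    models["CLS"] = fit_cls(A, C, intercept=True, window_nm="auto", cv=cfg.cv)
    pcr_scan = select_latent(A, C, max_lv=cfg.max_lv, cv=cfg.cv, method="pcr")
    models["PCR"] = fit_pcr(A, C, pcr_scan.chosen)
    pls_scan = select_latent(A, C, max_lv=cfg.max_lv, cv=cfg.cv, method="pls")
    models["PLS"] = fit_pls(A, C, pls_scan.chosen)
    models["PCR"].extras["lv_scan"] = pcr_scan
    models["PLS"].extras["lv_scan"] = pls_scan
    if cfg.include_ga:
        models["GA-PLS"] = fit_ga_pls(A, C, cfg.ga, cv=cfg.cv)
    return models


def _refitter(model: CalibrationModel, cfg: RunConfig):
    """A closure refitting the model at its frozen hyperparameters, for CV."""
    if model.method == "CLS":
        w = model.preprocess.smoothing_window_nm

        return lambda A, C: fit_cls(A, C, intercept=True, window_nm=w)
    if model.method == "PCR":
        return lambda A, C: fit_pcr(A, C, model.n_latent)
    if model.method == "PLS":
        return lambda A, C: fit_pls(A, C, model.n_latent)
    masks = model.masks

    return lambda A, C: fit_ga_pls(A, C, cfg.ga, cv=cfg.cv, masks=masks)


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full workflow; optionally write JSON/CSV/plot artifacts."""
    sc = cfg.scenario
    names = list(sc.design_spec.analyte_names)
    seeds = _stage_seeds(cfg.seed, ["simulate_cal", "simulate_val", "ga", "precision"])

    stage = "design"
    try:
        cal = brereton_design(sc.design_spec)
        val = lhs_design(
            LHSSpec(
                n_strata=cfg.n_strata,
                analyte_names=sc.design_spec.analyte_names,
                low=sc.design_spec.low,
                high=sc.design_spec.high,
                seed=seeds["simulate_val"],
            )
        )

        stage = "simulate"
        noise_cal = dataclasses.replace(sc.noise, seed=seeds["simulate_cal"])
        noise_val = dataclasses.replace(sc.noise, seed=seeds["simulate_val"])
        A_cal = trim(simulate_mixtures(cal, sc.pures, sc.grid, noise_cal), sc.trim_lo_nm, sc.trim_hi_nm)
        A_val = trim(simulate_mixtures(val, sc.pures, sc.grid, noise_val), sc.trim_lo_nm, sc.trim_hi_nm)
        C_cal, C_val = cal.concentrations, val.concentrations

        stage = "fit"
        ga_cfg = dataclasses.replace(cfg.ga, seed=seeds["ga"])
        run_cfg = dataclasses.replace(cfg, ga=ga_cfg)
        models = fit_all_models(A_cal, C_cal, run_cfg)

        stage = "validate"
        merits: dict[str, dict[str, MeritReport]] = {}
        recoveries: dict[str, dict[str, np.ndarray]] = {a: {} for a in names}
        for mname, model in models.items():
            cal_pred = predict(model, A_cal)
            cv_pred = cross_val_predict(A_cal, C_cal, cfg.cv, _refitter(model, run_cfg))
            val_pred = predict(model, A_val)
            merits[mname] = {}
            for a in names:
                merits[mname][a] = merit_report(
                    mname,
                    a,
                    PairedOutcomes(C_cal[a].to_numpy(), cal_pred[a].to_numpy(), "calibration"),
                    PairedOutcomes(C_cal[a].to_numpy(), cv_pred[a].to_numpy(), "cross_validation"),
                    PairedOutcomes(C_val[a].to_numpy(), val_pred[a].to_numpy(), "prediction"),
                )
                recoveries[a][mname] = 100.0 * val_pred[a].to_numpy() / C_val[a].to_numpy()

        stage = "precision"
        precision = _precision_block(models, run_cfg, seeds["precision"])

        stage = "anova"
        anova = {}
        for a in names:
            res = anova_oneway(list(recoveries[a].values()))
            anova[a] = {
                "f": res.f,
                "p": res.p,
                "f_critical": res.f_critical,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "models": list(recoveries[a].keys()),
            }

        stage = "sustainability"
        sustainability: dict = {
            "carbon_footprint_kg_co2_eq": carbon_footprint(list(cfg.instrument_usages))
        }
        if cfg.bagi is not None:
            sustainability["bagi"] = bagi_score(cfg.bagi)
        if cfg.rgb12 is not None:
            sustainability["rgb12"] = rgb12_whiteness(cfg.rgb12)

        lv_scans = {
            m: {
                "chosen": models[m].n_latent,
                "rmsecv": models[m].extras["lv_scan"].rmsecv.to_dict(),
            }
            for m in ("PCR", "PLS")
        }
        ga_summary = {}
        if cfg.include_ga:
            for a, res in models["GA-PLS"].extras.get("ga_results", {}).items():
                ga_summary[a] = {
                    "generations_run": res.generations_run,
                    "reduction_fraction": res.reduction_fraction,
                    "n_selected": int(res.selected_mask.sum()),
                    "final_rmsecv": float(res.fitness_trace["best"].iloc[-1]),
                }

        provenance = {
            "specchem_version": __version__,
            "master_seed": cfg.seed,
            "stage_seeds": seeds,
            "config_hash": hashlib.sha256(
                json.dumps(_jsonable(_config_fingerprint(cfg)), sort_keys=True).encode()
            ).hexdigest(),
            "models": list(models.keys()),
        }
        report = RunReport(merits, lv_scans, ga_summary, anova, precision, sustainability, provenance)
    except Exception as exc:
        raise SpecchemError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        _write_artifacts(report, models, Path(outdir))
    return report


def _config_fingerprint(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def _precision_block(models: dict, cfg: RunConfig, seed: int) -> dict:
    """Triplicate predictions at fixed levels; %RSD per model/level/analyte."""
    sc = cfg.scenario
    names = list(sc.design_spec.analyte_names)
    rows = []
    ids = []
    for level in cfg.precision_levels:
        for r in range(cfg.n_replicates):
            rows.append([level] * len(names))
            ids.append(f"p{level:g}_{r + 1}")
    conc = pd.DataFrame(rows, index=ids, columns=names)
    design = MixtureDesign("validation", conc)
    noise = dataclasses.replace(sc.noise, seed=seed)
    A = trim(simulate_mixtures(design, sc.pures, sc.grid, noise), sc.trim_lo_nm, sc.trim_hi_nm)
    out: dict[str, dict] = {}
    levels = conc.iloc[:, 0].to_numpy()
    for mname, model in models.items():
        pred = predict(model, A)
        out[mname] = {}
        for a in names:
            table = recovery_rsd(pred[a].to_numpy(), conc[a].to_numpy(), levels)
            out[mname][a] = {
                f"{lvl:g}": {
                    "mean_recovery_pct": float(row["mean_recovery_pct"]),
                    "rsd_pct": float(row["rsd_pct"]),
                }
                for lvl, row in table.iterrows()
            }
    return out


def standard_addition(
    model: CalibrationModel,
    base_spectra: SpectralMatrix,
    spiked_spectra: SpectralMatrix,
    added: pd.DataFrame,
) -> pd.DataFrame:
    """Recovery of spiked additions: 100 * (found_total - found_base) / added.

    ``base_spectra`` holds replicate measurements of the unspiked sample
    (their mean prediction is the base level); ``added`` gives the spiked
    amount per spiked sample and analyte (all > 0).
    """
    if (added.to_numpy() <= 0).any():
        raise SpecchemError("spiked additions must be > 0")
    if len(added) != spiked_spectra.n_samples:
        raise SpecchemError("added table must align with the spiked spectra")
    base = predict(model, base_spectra).mean(axis=0)
    total = predict(model, spiked_spectra)
    analytes = [a for a in added.columns if a in total.columns]
    rec = pd.DataFrame(index=total.index, columns=analytes, dtype=float)
    for a in analytes:
        rec[a] = 100.0 * (total[a].to_numpy() - float(base[a])) / added[a].to_numpy()
    flagged = [a for a in analytes if (total[a].to_numpy() < float(base[a])).all()]
    rec.attrs["negative_recovery_flagged"] = flagged
    return rec


def _write_artifacts(report: RunReport, models: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    rows = [r.to_dict() for per in report.merits.values() for r in per.values()]
    pd.DataFrame(rows).to_csv(outdir / "merits.csv", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for m in ("PCR", "PLS"):
            scan = models[m].extras["lv_scan"]
            for col in scan.rmsecv.columns:
                ax.plot(scan.rmsecv.index, scan.rmsecv[col], marker="o", label=f"{m} {col}")
        ax.set_xlabel("latent variables")
        ax.set_ylabel("RMSECV (ug/mL)")
        ax.set_yscale("log")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "lv_scan.png", dpi=120)
        plt.close(fig)
        if "GA-PLS" in models:
            fig, ax = plt.subplots(figsize=(6, 4))
            for a, res in models["GA-PLS"].extras.get("ga_results", {}).items():
                ax.plot(res.fitness_trace.index, res.fitness_trace["best"], label=f"{a} best")
                ax.plot(res.fitness_trace.index, res.fitness_trace["median"], "--", label=f"{a} median")
            ax.set_xlabel("generation")
            ax.set_ylabel("RMSECV (ug/mL)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / "ga_trace.png", dpi=120)
            plt.close(fig)
    except Exception:  # plotting must never sink a finished run
        pass
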