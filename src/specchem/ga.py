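"""Genetic-algorithm wavelength selection feeding a refined PLS model.

Chromosomes switch contiguous, non-overlapping windows of wavelengths on or
off (window width in variables, default 2; a trailing remainder forms a
narrower window).  Fitness is the cross-validated RMSECV of a PLS model on
the active wavelengths — lower is better — estimated by random-subset CV
with fresh splits every generation and averaged over the configured number
of iterations.  Selection is fitness-proportionate over ranks, crossover is
single- or two-point on the window-gene string, mutation flips genes
independently, and one elite chromosome (with its evaluated fitness) is
carried over each generation, which makes the best-fitness trace
non-increasing by construction.

Default parameters are the optimized values of the source workflow
(population 40, up to 65 generations, mutation rate 0.005, 15% of windows
active at initialization, 80% convergence threshold, double crossover, at
most 3 latent variables, 5 random CV subsets, 2 CV iterations per
generation).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ModelError, SpecchemError
from .models import CalibrationModel, CVConfig, _latent_paths, fit_pls, select_latent
from .spectra import PreprocessState, SpectralMatrix

__all__ = ["GAConfig", "GAResult", "run_ga", "fit_ga_pls"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    max_generations: int = 65
    mutation_rate: float = 0.005
    init_fraction: float = 0.15
    window_width: int = 2
    convergence_fraction: float = 0.80
    crossover: str = "double"  # single | double
    max_latent: int = 3
    cv_subsets: int = 5
    cv_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise SpecchemError("population_size must be >= 4")
        if not 0 <= self.mutation_rate < 1:
            raise SpecchemError("mutation_rate must be in [0, 1)")
        if not 0 < self.init_fraction <= 1:
            raise SpecchemError("init_fraction must be in (0, 1]")
        if self.window_width < 1:
            raise SpecchemError("window_width must be >= 1")
        if not 0 < self.convergence_fraction <= 1:
            raise SpecchemError("convergence_fraction must be in (0, 1]")
        if self.crossover not in ("single", "double"):
            raise SpecchemError(f"unknown crossover type {self.crossover!r}")


@dataclass
class GAResult:
    selected_mask: np.ndarray  # boolean per wavelength
    fitness_trace: pd.DataFrame  # columns: best, median (ug/mL RMSECV)
    generations_run: int
    reduction_fraction: float
    config: GAConfig
    analyte: str | None = None
    extras: dict = field(default_factory=dict)


def _windows(n_wl: int, width: int) -> list[slice]:
    return [slice(i, min(i + width, n_wl)) for i in range(0, n_wl, width)]


def _expand(chrom: np.ndarray, windows: list[slice], n_wl: int) -> np.ndarray:
    mask = np.zeros(n_wl, dtype=bool)
    for on, sl in zip(chrom, windows):
        if on:
            mask[sl] = True
    return mask


def _repair(chrom: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not chrom.any():
        chrom = chrom.copy()
        chrom[rng.integers(len(chrom))] = True
    return chrom


def _generation_splits(
    n: int, cfg: GAConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random-subset CV splits drawn once per generation and shared by every
    chromosome, so fitness comparisons within a generation are paired and the
    split-assignment noise cancels."""
    splits = []
    for _ in range(cfg.cv_iterations):
        perm = rng.permutation(n)
        for part in np.array_split(perm, cfg.cv_subsets):
            splits.append((np.setdiff1d(np.arange(n), part), np.sort(part)))
    return splits


def _fitness(
    X: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    cfg: GAConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean RMSECV (over analyte columns) of PLS on the masked wavelengths,
    using the best LV count <= max_latent under the generation's CV splits."""
    Xm = X[:, mask]
    n = len(Xm)
    max_lv = min(cfg.max_latent, n - int(np.ceil(n / cfg.cv_subsets)) - 1, Xm.shape[1])
    max_lv = max(max_lv, 1)
    sq = np.zeros((max_lv, Y.shape[1]))
    cnt = 0
    for train, part in splits:
        x_mean = Xm[train].mean(axis=0)
        y_mean = Y[train].mean(axis=0)
        try:
            path = _latent_paths(Xm[train] - x_mean, Y[train] - y_mean, max_lv, "pls", pad=True)
        except ModelError:
            return np.inf
        Xt = Xm[part] - x_mean
        for k in range(max_lv):
            resid = Xt @ path[k] + y_mean - Y[part]
            sq[k] += (resid**2).sum(axis=0)
        cnt += len(part)
    rmsecv = np.sqrt(sq / cnt)  # (max_lv, n_analytes)
    return float(rmsecv.min(axis=0).mean())


def _crossover(a: np.ndarray, b: np.ndarray, kind: str, rng: np.random.Generator):
    n = len(a)
    if n < 2:
        return a.copy(), b.copy()
    if kind == "single":
        cut = rng.integers(1, n)
        return (
            np.concatenate([a[:cut], b[cut:]]),
            np.concatenate([b[:cut], a[cut:]]),
        )
    i, j = np.sort(rng.choice(np.arange(1, n), size=2, replace=False)) if n > 2 else (1, 1)
    c1, c2 = a.copy(), b.copy()
    c1[i:j], c2[i:j] = b[i:j], a[i:j]
    return c1, c2


def run_ga(
    A: SpectralMatrix,
    C: pd.DataFrame,
    cfg: GAConfig,
    analyte: str | None = None,
) -> GAResult:
    """Evolve a wavelength-window selection minimizing PLS RMSECV.

    ``analyte`` restricts the fitness to one concentration column (the
    default when C has a single column); with several columns and no analyte
    given, the fitness is the mean RMSECV across analytes (joint mode).
    Fixed seed implies a bit-reproducible selection.
    """
    if A.n_samples != len(C):
        raise ModelError("spectra and concentrations must be row-aligned")
    if analyte is not None:
        if analyte not in C.columns:
            raise SpecchemError(f"unknown analyte {analyte!r}")
        Y = C[[analyte]].to_numpy(dtype=float)
    else:
        Y = C.to_numpy(dtype=float)
        if Y.shape[1] == 1:
            analyte = str(C.columns[0])
    X = A.absorbance
    n_wl = X.shape[1]
    windows = _windows(n_wl, cfg.window_width)
    n_genes = len(windows)
    rng = np.random.default_rng(cfg.seed)

    pop = [_repair(rng.random(n_genes) < cfg.init_fraction, rng) for _ in range(cfg.population_size)]

    trace = []
    generations_run = 0
    best_so_far = np.inf
    best_chrom = pop[0]
    for gen in range(cfg.max_generations):
        generations_run = gen + 1
        # every chromosome (elite included) is scored on the same fresh
        # splits, so within-generation comparisons are paired and fair
        splits = _generation_splits(A.n_samples, cfg, rng)
        fitness = np.array([_fitness(X, Y, _expand(c, windows, n_wl), cfg, splits) for c in pop])
        order = np.argsort(fitness, kind="stable")
        best_idx = order[0]
        if fitness[best_idx] < best_so_far:
            best_so_far = float(fitness[best_idx])
            best_chrom = pop[best_idx].copy()
        trace.append(
            {"generation": gen + 1, "best": best_so_far, "median": float(np.median(fitness))}
        )
        same_as_best = sum(np.array_equal(c, pop[best_idx]) for c in pop)
        if same_as_best >= cfg.convergence_fraction * cfg.population_size:
            break
        if gen == cfg.max_generations - 1:
            break
        # rank-proportionate selection: rank r (0 = best) gets weight pop - r
        weights = np.empty(cfg.population_size)
        weights[order] = np.arange(cfg.population_size, 0, -1)
        probs = weights / weights.sum()
        children = [pop[best_idx].copy()]  # one-chromosome elitism
        while len(children) < cfg.population_size:
            i, j = rng.choice(cfg.population_size, size=2, p=probs)
            c1, c2 = _crossover(pop[i], pop[j], cfg.crossover, rng)
            for c in (c1, c2):
                if len(children) >= cfg.population_size:
                    break
                if cfg.mutation_rate > 0:
                    flip = rng.random(n_genes) < cfg.mutation_rate
                    c = np.where(flip, ~c, c)
                children.append(_repair(c, rng))
        pop = children

    mask = _expand(best_chrom, windows, n_wl)
    return GAResult(
        selected_mask=mask,
        fitness_trace=pd.DataFrame(trace).set_index("generation"),
        generations_run=generations_run,
        reduction_fraction=1.0 - mask.sum() / n_wl,
        config=cfg,
        analyte=analyte,
        extras={"n_windows": n_genes},
    )


def fit_ga_pls(
    A: SpectralMatrix,
    C: pd.DataFrame,
    cfg: GAConfig | dict[str, GAConfig],
    cv: CVConfig | None = None,
    masks: dict[str, np.ndarray] | None = None,
) -> CalibrationModel:
    """GA-selected-wavelength PLS: one GA run and one PLS1 fit per analyte.

    ``cfg`` may be a single config or a per-analyte mapping. ``masks``
    bypasses the GA with precomputed per-analyte wavelength masks (used for
    degenerate/diagnostic cases).  The returned model retains the union of
    the per-analyte masks; each analyte's coefficients are zero outside its
    own mask, and the LV count is re-selected on the masked spectra.
    """
    analytes = list(C.columns)
    cfgs = cfg if isinstance(cfg, dict) else {a: cfg for a in analytes}
    wl = A.wavelengths()
    per_mask: dict[str, np.ndarray] = {}
    ga_results: dict[str, GAResult] = {}
    for a in analytes:
        if masks is not None and a in masks:
            per_mask[a] = np.asarray(masks[a], dtype=bool)
        else:
            res = run_ga(A, C, cfgs[a], analyte=a)
            ga_results[a] = res
            per_mask[a] = res.selected_mask
    union = np.logical_or.reduce([per_mask[a] for a in analytes])
    coef = np.zeros((int(union.sum()), len(analytes)))
    intercepts = np.zeros(len(analytes))
    chosen: dict[str, int] = {}
    scans = {}
    for j, a in enumerate(analytes):
        sub = _masked_matrix(A, per_mask[a])
        scan = select_latent(sub, C[[a]], max_lv=cfgs[a].max_latent, cv=cv or CVConfig())
        chosen[a] = scan.chosen[a]
        scans[a] = scan
        model_a = fit_pls(sub, C[[a]], chosen[a])
        # place the analyte's coefficients at its mask positions within the union
        pos = np.searchsorted(wl[union], wl[per_mask[a]])
        coef[pos, j] = model_a.coefficients[:, 0]
        intercepts[j] = model_a.intercepts[0]
    return CalibrationModel(
        method="GA-PLS",
        analyte_names=analytes,
        wavelengths_nm=wl[union],
        coefficients=coef,
        intercepts=intercepts,
        n_latent=chosen,
        preprocess=PreprocessState(trim_lo_nm=A.grid.start_nm, trim_hi_nm=A.grid.end_nm),
        masks=per_mask,
        extras={"ga_results": ga_results, "lv_scans": scans},
    )


def _masked_matrix(A: SpectralMatrix, mask: np.ndarray) -> SpectralMatrix:
    """Non-contiguous wavelength subset packaged for the fitting routines.

    The fitting code only consumes ``absorbance`` and ``wavelengths()``; the
    carrier grid keeps the original step so LV limits stay correct.
    """
    sub = A.absorbance[:, mask]
    wl = A.wavelengths()[mask]
    return SpectralMatrix(_RaggedGrid(wl, A.grid.step_nm), sub, list(A.sample_ids))


class _RaggedGrid:
    """Duck-typed grid over an explicit (possibly non-uniform) wavelength set."""

    def __init__(self, wl: np.ndarray, step_nm: float) -> None:
        self._wl = np.asarray(wl, dtype=float)
        self.step_nm = step_nm
        self.start_nm = float(wl[0]) if len(wl) else np.nan
        self.end_nm = float(wl[-1]) if len(wl) else np.nan

    @property
    def n_points(self) -> int:
        return len(self._wl)

    def wavelengths(self) -> np.ndarray:
        return self._wl

    def index_of(self, nm: float) -> int:
        hits = np.where(np.abs(self._wl - nm) <= 1e-9)[0]
        if not hits.size:
            from .errors import GridError

            raise GridError(f"{nm} nm is not among the retained wavelengths")
        return int(hits[0])
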