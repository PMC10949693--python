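"""Multivariate calibration models: CLS with intercept, PCR, and PLS.

All three models reduce, after fitting, to the same affine prediction rule
``c_hat = A_retained @ coefficients + intercepts`` so that a single
:func:`predict` serves every method (training-set centering is folded into
the intercepts; CLS optionally boxcar-smooths spectra first).

PLS is implemented per analyte (PLS1) by default — each concentration column
gets its own sequence of covariance-maximizing latent variables — with a
joint PLS2 variant behind a flag.  Latent-variable counts are chosen by
cross-validated RMSECV with a one-standard-error parsimony rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, ModelError
from .spectra import PreprocessState, SpectralMatrix

__all__ = [
    "CalibrationModel",
    "CVConfig",
    "LVScan",
    "cv_folds",
    "fit_cls",
    "fit_pcr",
    "fit_pls",
    "select_latent",
    "predict",
    "cross_val_predict",
]

_CLS_WINDOW_SCAN_NM = tuple(range(5, 31, 2))  # odd widths, 5-29 nm


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme for model selection and Q^2 estimation."""

    scheme: str = "venetian_blinds"  # venetian_blinds | leave_one_out | random_subsets
    n_splits: int = 5
    n_iterations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("venetian_blinds", "leave_one_out", "random_subsets"):
            raise ModelError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme != "leave_one_out" and self.n_splits < 2:
            raise ModelError("split-based CV needs n_splits >= 2")


@dataclass
class LVScan:
    """RMSECV as a function of latent-variable count, with the chosen counts."""

    lv_grid: np.ndarray
    rmsecv: pd.DataFrame  # index: LV count, columns: analytes (ug/mL)
    se: pd.DataFrame  # standard error of the per-fold RMSEs
    chosen: dict[str, int]


@dataclass
class CalibrationModel:
    """A fitted affine calibration predictor on a retained wavelength set."""

    method: str  # CLS | PCR | PLS | GA-PLS
    analyte_names: list[str]
    wavelengths_nm: np.ndarray  # retained wavelengths, ascending
    coefficients: np.ndarray  # (n_retained, n_analytes), ug/mL per AU
    intercepts: np.ndarray  # (n_analytes,), ug/mL
    n_latent: dict[str, int] | None = None
    preprocess: PreprocessState = field(default_factory=PreprocessState)
    masks: dict[str, np.ndarray] | None = None  # per-analyte wavelength masks (GA-PLS)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coefficients.shape != (len(self.wavelengths_nm), len(self.analyte_names)):
            raise ModelError("coefficient rows must align 1:1 with retained wavelengths")


def cv_folds(n: int, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs for the requested scheme.

    ``random_subsets`` repeats the split ``n_iterations`` times with fresh
    seeded permutations; the other schemes are deterministic.
    """
    idx = np.arange(n)
    if cv.scheme == "leave_one_out":
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    if cv.n_splits > n:
        raise ModelError(f"cannot split {n} samples into {cv.n_splits} subsets")
    if cv.scheme == "venetian_blinds":
        return [(idx[idx % cv.n_splits != k], idx[idx % cv.n_splits == k]) for k in range(cv.n_splits)]
    rng = np.random.default_rng(cv.seed)
    folds = []
    for _ in range(max(1, cv.n_iterations)):
        perm = rng.permutation(n)
        for part in np.array_split(perm, cv.n_splits):
            folds.append((np.setdiff1d(idx, part), np.sort(part)))
    return folds


def _check_aligned(A: SpectralMatrix, C: pd.DataFrame) -> np.ndarray:
    if A.n_samples != len(C):
        raise ModelError(f"spectra have {A.n_samples} samples but concentrations {len(C)}")
    return C.to_numpy(dtype=float)


def _boxcar(X: np.ndarray, w_int: int) -> np.ndarray:
    """Row-wise truncated-edge boxcar mean over ``w_int`` points."""
    if w_int <= 1:
        return X
    kernel = np.ones(w_int)
    counts = np.convolve(np.ones(X.shape[1]), kernel, mode="same")
    return np.stack([np.convolve(row, kernel, mode="same") / counts for row in X])


# ---------------------------------------------------------------------------
# CLS


def _cls_operator(A: np.ndarray, C: np.ndarray, intercept: bool, analytes: list[str]):
    """Estimate pure profiles S from A = C S and build the prediction operator."""
    k = C.shape[1]
    C_aug = np.column_stack([C, np.ones(len(C))]) if intercept else C
    if np.linalg.matrix_rank(C_aug) < C_aug.shape[1]:
        corr = np.corrcoef(C, rowvar=False)
        pairs = [
            f"{analytes[i]}~{analytes[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ModelError(f"rank-deficient concentration design; collinear analytes: {pairs or 'constant column'}")
    S_aug, *_ = np.linalg.lstsq(C_aug, A, rcond=None)
    if np.any(np.linalg.norm(S_aug[:k], axis=1) < 1e-12):
        raise ModelError("degenerate (all-zero) estimated pure profile")
    # second-stage least squares: [c, b] = pinv(basis^T) a (linear in a).  With
    # the intercept on, the basis carries a ones row so a constant baseline on
    # a new spectrum is absorbed by b rather than biasing c; the stage-1
    # offset row only keeps background out of the S estimates.
    basis = np.vstack([S_aug[:k], np.ones(A.shape[1])]) if intercept else S_aug[:k]
    M = np.linalg.pinv(basis.T)  # (k[+1], n_wl)
    coefficients = M[:k].T  # (n_wl, k)
    return S_aug, coefficients


def fit_cls(
    A: SpectralMatrix,
    C: pd.DataFrame,
    intercept: bool = True,
    window_nm: float | str | None = None,
    cv: CVConfig | None = None,
) -> CalibrationModel:
    """Classical least squares on estimated pure profiles.

    The first stage estimates the pure-component absorptivity matrix S (plus
    an offset row when ``intercept``) from ``A = C S``; prediction solves the
    second-stage least squares of a new spectrum against S.  ``window_nm``
    applies boxcar smoothing first; ``"auto"`` scans odd widths of 5-29 nm by
    cross-validated RMSECV and keeps the minimizer (no smoothing if it wins).
    """
    Cn = _check_aligned(A, C)
    if A.n_samples < Cn.shape[1] + 1:
        raise ModelError("CLS needs at least n_analytes + 1 samples")
    step = A.grid.step_nm
    analytes = list(C.columns)

    if window_nm == "auto":
        cv = cv or CVConfig()
        best = (np.inf, None)
        for w in (None, *_CLS_WINDOW_SCAN_NM):
            rmsecv = _cls_rmsecv(A, Cn, intercept, w, cv, analytes)
            if rmsecv < best[0] - 1e-12:
                best = (rmsecv, w)
        window_nm = best[1]

    w_int = 0
    if window_nm is not None:
        w_int = int(round(window_nm / step))
        if w_int % 2 == 0 or abs(window_nm / step - w_int) > 1e-9:
            raise GridError(f"window {window_nm} nm must be an odd multiple of the step {step} nm")
    X = _boxcar(A.absorbance, w_int) if w_int > 1 else A.absorbance
    S_aug, coefficients = _cls_operator(X, Cn, intercept, analytes)
    return CalibrationModel(
        method="CLS",
        analyte_names=analytes,
        wavelengths_nm=A.wavelengths(),
        coefficients=coefficients,
        intercepts=np.zeros(len(analytes)),
        preprocess=PreprocessState(
            trim_lo_nm=A.grid.start_nm,
            trim_hi_nm=A.grid.end_nm,
            smoothing_window_nm=float(window_nm) if window_nm else None,
        ),
        extras={"pure_profiles": S_aug, "intercept_term": intercept},
    )


def _cls_rmsecv(
    A: SpectralMatrix,
    Cn: np.ndarray,
    intercept: bool,
    window_nm: float | None,
    cv: CVConfig,
    analytes: list[str],
) -> float:
    step = A.grid.step_nm
    w_int = int(round(window_nm / step)) if window_nm else 0
    X = _boxcar(A.absorbance, w_int) if w_int > 1 else A.absorbance
    sq = 0.0
    m = 0
    for train, test in cv_folds(len(Cn), cv):
        _, coef = _cls_operator(X[train], Cn[train], intercept, analytes)
        resid = X[test] @ coef - Cn[test]
        sq += float((resid**2).sum())
        m += resid.size
    return np.sqrt(sq / m)


# ---------------------------------------------------------------------------
# PCR / PLS cores (centered data)


def _pad_path(path: list[np.ndarray], max_lv: int) -> list[np.ndarray]:
    """Extend a truncated coefficient path by repeating its last element, so
    CV scans past the extractable rank see a flat error curve."""
    while len(path) < max_lv:
        path.append(path[-1].copy())
    return path


def _pcr_coef_path(Xc: np.ndarray, Yc: np.ndarray, max_lv: int, pad: bool = False) -> list[np.ndarray]:
    """Wavelength-space coefficient matrices for 1..max_lv principal components."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if max_lv > rank and not pad:
        raise ModelError(f"n_latent = {max_lv} exceeds the spectral rank {rank}")
    path = []
    B = np.zeros((Xc.shape[1], Yc.shape[1]))
    for j in range(min(max_lv, rank)):
        t = U[:, j] * s[j]
        gamma = (t @ Yc) / (t @ t)
        B = B + np.outer(Vt[j], gamma)
        path.append(B.copy())
    return _pad_path(path, max_lv) if pad else path


def _pls1_coef_path(Xc: np.ndarray, yc: np.ndarray, max_lv: int, pad: bool = False) -> list[np.ndarray]:
    """Coefficient vectors for 1..max_lv PLS1 latent variables (NIPALS-style).

    PLS1 extraction is closed-form per LV: weight = X'y (normalized), score
    t = Xw, loadings by regression on t, then deflation of X and y.
    """
    Xd = Xc.copy()
    yd = yc.copy()
    W, P, Q = [], [], []
    for a in range(max_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            if pad and a > 0:
                break
            raise ModelError(f"degenerate latent variable {a + 1}: no residual covariance")
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            if pad and a > 0:
                break
            raise ModelError(f"degenerate latent variable {a + 1}: zero score variance")
        p = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    path = []
    for k in range(1, len(W) + 1):
        R = np.linalg.solve(Pm[:, :k].T @ Wm[:, :k], qv[:k])
        path.append(Wm[:, :k] @ R)
    return _pad_path(path, max_lv) if pad else path


def _pls2_coef_path(
    Xc: np.ndarray,
    Yc: np.ndarray,
    max_lv: int,
    pad: bool = False,
    max_iter: int = 500,
    tol: float = 1e-12,
):
    """NIPALS PLS2: joint latent variables for a multi-column response."""
    Xd = Xc.copy()
    Yd = Yc.copy()
    W, P, Q = [], [], []
    for a in range(max_lv):
        if np.max(np.var(Yd, axis=0)) < 1e-24 and pad and a > 0:
            break
        u = Yd[:, int(np.argmax(np.var(Yd, axis=0)))]
        for it in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                if pad and a > 0:
                    w = None
                    break
                raise ModelError(f"degenerate latent variable {a + 1}")
            w = w / nw
            t = Xd @ w
            q = Yd.T @ t / float(t @ t)
            u_new = Yd @ q / float(q @ q)
            if np.linalg.norm(u_new - u) <= tol * max(1.0, np.linalg.norm(u)):
                u = u_new
                break
            u = u_new
        else:
            raise ModelError(f"PLS2 latent variable {a + 1} did not converge in {max_iter} iterations")
        if w is None:
            break
        tt = float(t @ t)
        p = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, Yd.T @ t / tt)
        W.append(w)
        P.append(p)
        Q.append(q)
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Qm = np.column_stack(Q)
    path = []
    for k in range(1, len(W) + 1):
        R = np.linalg.solve(Pm[:, :k].T @ Wm[:, :k], Qm[:, :k].T)
        path.append(Wm[:, :k] @ R)
    return _pad_path(path, max_lv) if pad else path


def _latent_paths(
    Xc: np.ndarray,
    Yc: np.ndarray,
    max_lv: int,
    method: str,
    variant: str = "pls1",
    pad: bool = False,
) -> list[np.ndarray]:
    """Coefficient paths B_1..B_max_lv mapping centered spectra to centered
    concentrations, for PCR or PLS (per-analyte PLS1 columns by default).

    ``pad`` repeats the last extractable coefficient matrix when the data
    rank is exhausted before max_lv (used by CV scans on near-exact data).
    """
    if method == "pcr":
        return _pcr_coef_path(Xc, Yc, max_lv, pad=pad)
    if method != "pls":
        raise ModelError(f"unknown latent-variable method {method!r}")
    if variant == "pls2":
        return _pls2_coef_path(Xc, Yc, max_lv, pad=pad)
    cols = [_pls1_coef_path(Xc, Yc[:, j], max_lv, pad=pad) for j in range(Yc.shape[1])]
    return [np.column_stack([cols[j][k] for j in range(Yc.shape[1])]) for k in range(max_lv)]


def _fit_latent(
    A: SpectralMatrix,
    C: pd.DataFrame,
    n_latent: int | dict[str, int],
    method: str,
    variant: str = "pls1",
) -> CalibrationModel:
    Cn = _check_aligned(A, C)
    analytes = list(C.columns)
    if isinstance(n_latent, int):
        n_latent = {a: n_latent for a in analytes}
    max_needed = max(n_latent.values())
    limit = min(A.n_samples - 1, A.grid.n_points)
    if max_needed < 1 or max_needed > limit:
        raise ModelError(f"n_latent must be in [1, {limit}], got {max_needed}")
    x_mean = A.absorbance.mean(axis=0)
    y_mean = Cn.mean(axis=0)
    Xc = A.absorbance - x_mean
    Yc = Cn - y_mean
    path = _latent_paths(Xc, Yc, max_needed, method, variant)
    B = np.column_stack([path[n_latent[a] - 1][:, j] for j, a in enumerate(analytes)])
    intercepts = y_mean - x_mean @ B
    return CalibrationModel(
        method=method.upper(),
        analyte_names=analytes,
        wavelengths_nm=A.wavelengths(),
        coefficients=B,
        intercepts=intercepts,
        n_latent=dict(n_latent),
        preprocess=PreprocessState(
            trim_lo_nm=A.grid.start_nm,
            trim_hi_nm=A.grid.end_nm,
            column_means=x_mean,
        ),
        extras={"variant": variant} if method == "pls" else {},
    )


def fit_pcr(A: SpectralMatrix, C: pd.DataFrame, n_latent: int | dict[str, int]) -> CalibrationModel:
    """Principal component regression: regress concentrations on the scores of
    the top principal components of the mean-centered spectra."""
    return _fit_latent(A, C, n_latent, "pcr")


def fit_pls(
    A: SpectralMatrix,
    C: pd.DataFrame,
    n_latent: int | dict[str, int],
    variant: str = "pls1",
) -> CalibrationModel:
    """Partial least squares with sequential covariance-maximizing LVs."""
    return _fit_latent(A, C, n_latent, "pls", variant)


def select_latent(
    A: SpectralMatrix,
    C: pd.DataFrame,
    max_lv: int = 10,
    cv: CVConfig | None = None,
    method: str = "pls",
) -> LVScan:
    """Scan 1..max_lv latent variables, score each by cross-validated RMSECV.

    The chosen count per analyte is the smallest whose RMSECV lies within one
    standard error of the global minimum (first-parsimonious rule).
    """
    cv = cv or CVConfig()
    Cn = _check_aligned(A, C)
    analytes = list(C.columns)
    folds = cv_folds(A.n_samples, cv)
    max_lv_eff = min(max_lv, min(len(tr) for tr, _ in folds) - 1, A.grid.n_points)
    n_lv = max_lv_eff
    sq = np.zeros((n_lv, len(analytes)))
    count = np.zeros((n_lv, len(analytes)))
    fold_rmse = np.full((len(folds), n_lv, len(analytes)), np.nan)
    for f, (train, test) in enumerate(folds):
        x_mean = A.absorbance[train].mean(axis=0)
        y_mean = Cn[train].mean(axis=0)
        path = _latent_paths(A.absorbance[train] - x_mean, Cn[train] - y_mean, n_lv, method, pad=True)
        Xt = A.absorbance[test] - x_mean
        for k in range(n_lv):
            resid = Xt @ path[k] + y_mean - Cn[test]
            sq[k] += (resid**2).sum(axis=0)
            count[k] += len(test)
            fold_rmse[f, k] = np.sqrt((resid**2).mean(axis=0))
    rmsecv = np.sqrt(sq / count)
    se = fold_rmse.std(axis=0, ddof=1) / np.sqrt(len(folds))
    lv_grid = np.arange(1, n_lv + 1)
    rmsecv_df = pd.DataFrame(rmsecv, index=lv_grid, columns=analytes)
    se_df = pd.DataFrame(se, index=lv_grid, columns=analytes)
    chosen = {}
    for j, a in enumerate(analytes):
        k_min = int(np.argmin(rmsecv[:, j]))
        threshold = rmsecv[k_min, j] + se[k_min, j]
        chosen[a] = int(lv_grid[np.argmax(rmsecv[:, j] <= threshold)])
    return LVScan(lv_grid, rmsecv_df, se_df, chosen)


def predict(model: CalibrationModel, A_new: SpectralMatrix) -> pd.DataFrame:
    """Apply a fitted model to new spectra; returns sample x analyte ug/mL.

    The new grid must contain every retained wavelength; extra wavelengths
    are ignored (so predicting untrimmed spectra matches pre-trimming them).
    """
    grid = A_new.grid
    try:
        idx = np.array([grid.index_of(w) for w in model.wavelengths_nm], dtype=int)
    except GridError:
        missing = [
            f"{w:g}" for w in model.wavelengths_nm
            if not _on_grid(grid, w)
        ]
        raise ModelError(
            f"prediction grid lacks {len(missing)} retained wavelengths: "
            f"{', '.join(missing[:8])}{'...' if len(missing) > 8 else ''} nm"
        ) from None
    X = A_new.absorbance[:, idx]
    w_nm = model.preprocess.smoothing_window_nm
    if w_nm:
        X = _boxcar(X, int(round(w_nm / grid.step_nm)))
    yhat = X @ model.coefficients + model.intercepts
    return pd.DataFrame(yhat, index=list(A_new.sample_ids), columns=model.analyte_names)


def _on_grid(grid, w: float) -> bool:
    try:
        grid.index_of(w)
        return True
    except GridError:
        return False


def cross_val_predict(
    A: SpectralMatrix,
    C: pd.DataFrame,
    cv: CVConfig,
    fit: "callable",
) -> pd.DataFrame:
    """Out-of-fold predictions for Q^2/RMSECV: refit with ``fit(A_sub, C_sub)``
    on each training split and predict the held-out samples.

    With ``random_subsets`` and several iterations, repeated predictions for a
    sample are averaged.
    """
    Cn = _check_aligned(A, C)
    acc = np.zeros_like(Cn)
    hits = np.zeros(len(Cn))
    for train, test in cv_folds(A.n_samples, cv):
        sub = SpectralMatrix(A.grid, A.absorbance[train], [A.sample_ids[i] for i in train])
        model = fit(sub, C.iloc[train])
        held = SpectralMatrix(A.grid, A.absorbance[test], [A.sample_ids[i] for i in test])
        acc[test] += predict(model, held).to_numpy()
        hits[test] += 1
    if np.any(hits == 0):
        raise ModelError("cross-validation left some samples never held out")
    return pd.DataFrame(acc / hits[:, None], index=list(C.index), columns=list(C.columns))
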