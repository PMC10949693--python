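"""Calibration models against exact linear-algebra and scikit-learn oracles."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from specchem.errors import ModelError
from specchem.models import (
    CVConfig,
    cross_val_predict,
    cv_folds,
    fit_cls,
    fit_pcr,
    fit_pls,
    predict,
    select_latent,
)
from specchem.simulate import NoiseModel, simulate_mixtures
from specchem.spectra import SpectralMatrix, WavelengthGrid, trim


def _rmsec(model, A, C):
    resid = predict(model, A).to_numpy() - C.to_numpy()
    return np.sqrt((resid**2).mean(axis=0))


class TestCls:
    def test_noiseless_predictions_exact(self, noiseless_cal, cal_conc):
        model = fit_cls(noiseless_cal, cal_conc, intercept=False)
        assert np.abs(predict(model, noiseless_cal).to_numpy() - cal_conc.to_numpy()).max() < 1e-8

    def test_intercept_absorbs_constant_offset(self, noiseless_cal, cal_conc):
        """Normal-equations oracle: a ones column in the prediction basis makes
        the fit invariant to adding a constant to every spectrum."""
        offset = dataclasses.replace(noiseless_cal, absorbance=noiseless_cal.absorbance + 0.05)
        with_b = fit_cls(noiseless_cal, cal_conc, intercept=True)
        without = fit_cls(noiseless_cal, cal_conc, intercept=False)
        err_with = np.abs(predict(with_b, offset).to_numpy() - cal_conc.to_numpy()).max()
        err_without = np.abs(predict(without, offset).to_numpy() - cal_conc.to_numpy()).max()
        assert err_with < 1e-6
        assert err_without > 0.1

    def test_scalar_sensitivity_recovered(self):
        grid = WavelengthGrid(250, 250.1, 0.1)
        c = np.array([[10.0], [20.0], [30.0]])
        A = SpectralMatrix(grid, 0.02 * np.repeat(c, 2, axis=1), ["a", "b", "c"])
        C = pd.DataFrame(c, index=["a", "b", "c"], columns=["x"])
        model = fit_cls(A, C, intercept=False)
        s = model.extras["pure_profiles"][0, 0]
        assert s == pytest.approx(0.02, rel=1e-10)

    def test_collinear_concentrations_rejected(self, noiseless_cal, cal_conc):
        C = cal_conc.copy()
        C["MLK"] = 2.0 * C["LCZ"]
        with pytest.raises(ModelError, match="collinear"):
            fit_cls(noiseless_cal, C)

    def test_auto_window_scan_returns_valid_width(self, noisy_cal, cal_conc):
        model = fit_cls(noisy_cal, cal_conc, intercept=True, window_nm="auto")
        w = model.preprocess.smoothing_window_nm
        assert w is None or (w in range(5, 31) and int(w) % 2 == 1)


class TestPcrPls:
    def test_rank_two_data_fit_exactly_with_two_lvs(self, noiseless_cal, cal_conc):
        for fitter in (fit_pcr, fit_pls):
            model = fitter(noiseless_cal, cal_conc, 2)
            assert _rmsec(model, noiseless_cal, cal_conc).max() < 1e-8

    def test_full_rank_limit_equals_multiple_regression(self, random_xy):
        sm, C = random_xy
        Xc = sm.absorbance - sm.absorbance.mean(axis=0)
        Yc = C.to_numpy() - C.to_numpy().mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        for fitter in (fit_pcr, fit_pls):
            model = fitter(sm, C, sm.grid.n_points)
            np.testing.assert_allclose(model.coefficients, B, atol=1e-8)

    def test_pls2_full_rank_matches_least_squares(self, random_xy):
        sm, C = random_xy
        Xc = sm.absorbance - sm.absorbance.mean(axis=0)
        Yc = C.to_numpy() - C.to_numpy().mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        model = fit_pls(sm, C, sm.grid.n_points, variant="pls2")
        np.testing.assert_allclose(model.coefficients, B, atol=1e-8)

    def test_training_fit_monotone_in_latent_count(self, random_xy):
        sm, C = random_xy
        for fitter in (fit_pcr, fit_pls):
            errs = [_rmsec(fitter(sm, C, k), sm, C).sum() for k in range(1, 7)]
            assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_pcr_one_lv_underfits_rank_two_data(self, noiseless_cal, cal_conc):
        lo = _rmsec(fit_pcr(noiseless_cal, cal_conc, 1), noiseless_cal, cal_conc)
        hi = _rmsec(fit_pcr(noiseless_cal, cal_conc, 2), noiseless_cal, cal_conc)
        assert (lo > hi + 1e-6).all()

    def test_excessive_latent_count_rejected(self, noiseless_cal, cal_conc):
        with pytest.raises(ModelError):
            fit_pcr(noiseless_cal, cal_conc, 30)

    def test_matches_sklearn_oracles(self, random_xy):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.cross_decomposition import PLSRegression
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression

        sm, C = random_xy
        k = 3
        mine = fit_pls(sm, C[["a"]], k)
        ref = PLSRegression(n_components=k, scale=False).fit(sm.absorbance, C[["a"]].to_numpy())
        np.testing.assert_allclose(mine.coefficients[:, 0], ref.coef_.ravel(), atol=1e-10)

        pcr = fit_pcr(sm, C, k)
        pca = PCA(n_components=k).fit(sm.absorbance)
        scores = pca.transform(sm.absorbance)
        lr = LinearRegression().fit(scores, C.to_numpy())
        ref_coef = pca.components_.T @ lr.coef_.T
        np.testing.assert_allclose(pcr.coefficients, ref_coef, atol=1e-10)

    def test_first_pls_lv_covariance_dominates_first_pc(self, random_xy):
        """PLS extracts the direction maximizing covariance with y, so its
        first score must carry at least the concentration covariance of the
        first principal component."""
        sm, C = random_xy
        y = C["a"].to_numpy()
        yc = y - y.mean()
        Xc = sm.absorbance - sm.absorbance.mean(axis=0)
        w_pls = Xc.T @ yc
        w_pls /= np.linalg.norm(w_pls)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        cov_pls = abs((Xc @ w_pls) @ yc)
        cov_pca = abs((Xc @ Vt[0]) @ yc)
        assert cov_pls >= cov_pca - 1e-12

    def test_sample_permutation_leaves_coefficients_unchanged(self, noisy_cal, cal_conc):
        rng = np.random.default_rng(5)
        perm = rng.permutation(noisy_cal.n_samples)
        shuffled = SpectralMatrix(
            noisy_cal.grid,
            noisy_cal.absorbance[perm],
            [noisy_cal.sample_ids[i] for i in perm],
        )
        C_perm = cal_conc.iloc[perm]
        for fitter in (
            lambda A, C: fit_cls(A, C, intercept=True),
            lambda A, C: fit_pcr(A, C, 2),
            lambda A, C: fit_pls(A, C, 2),
        ):
            a = fitter(noisy_cal, cal_conc)
            b = fitter(shuffled, C_perm)
            np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-10)


class TestSelectLatent:
    def test_zero_noise_rmsecv_vanishes_at_two_lvs(self, noiseless_cal, cal_conc):
        scan = select_latent(noiseless_cal, cal_conc, max_lv=5)
        assert scan.rmsecv.loc[2].max() < 1e-6

    def test_default_scenario_selects_two_lvs(self, noisy_cal, cal_conc):
        scan = select_latent(noisy_cal, cal_conc, max_lv=10, cv=CVConfig("venetian_blinds", 5))
        assert scan.chosen == {"LCZ": 2, "MLK": 2}

    def test_schemes_agree_when_minimum_is_well_separated(self, scenario, cal_design):
        agree = 0
        for seed in range(20):
            noise = NoiseModel(0.002, seed=1000 + seed)
            A = trim(
                simulate_mixtures(cal_design, scenario.pures, scenario.grid, noise), 210, 400
            )
            vb = select_latent(A, cal_design.concentrations, max_lv=6, cv=CVConfig("venetian_blinds", 5))
            loo = select_latent(A, cal_design.concentrations, max_lv=6, cv=CVConfig("leave_one_out"))
            agree += vb.chosen == loo.chosen
        assert agree >= 18

    def test_too_many_splits_rejected(self, noisy_cal, cal_conc):
        with pytest.raises(ModelError):
            select_latent(noisy_cal, cal_conc, cv=CVConfig("venetian_blinds", 26))


class TestPredict:
    def test_trim_commutes_with_prediction(self, scenario, cal_design, noisy_cal, cal_conc):
        model = fit_pls(noisy_cal, cal_conc, 2)
        untrimmed = simulate_mixtures(cal_design, scenario.pures, scenario.grid, scenario.noise)
        pre_trimmed = trim(untrimmed, 210, 400)
        np.testing.assert_allclose(
            predict(model, untrimmed).to_numpy(),
            predict(model, pre_trimmed).to_numpy(),
            atol=1e-12,
        )

    def test_missing_wavelengths_listed(self, noisy_cal, cal_conc):
        model = fit_pls(noisy_cal, cal_conc, 2)
        narrower = trim(noisy_cal, 250, 400)
        with pytest.raises(ModelError, match="retained wavelengths"):
            predict(model, narrower)

    def test_empty_sample_set_gives_empty_table(self, noisy_cal, cal_conc):
        model = fit_pls(noisy_cal, cal_conc, 2)
        empty = SpectralMatrix(noisy_cal.grid, np.empty((0, noisy_cal.grid.n_points)), [])
        out = predict(model, empty)
        assert out.shape == (0, 2)


def test_cross_val_predict_covers_every_sample(noisy_cal, cal_conc):
    cv = CVConfig("venetian_blinds", 5)
    pred = cross_val_predict(noisy_cal, cal_conc, cv, lambda A, C: fit_pls(A, C, 2))
    assert pred.shape == cal_conc.shape
    assert np.abs(pred.to_numpy() - cal_conc.to_numpy()).max() < 0.5


def test_venetian_blind_folds_partition_samples():
    folds = cv_folds(11, CVConfig("venetian_blinds", 4))
    held = np.concatenate([t for _, t in folds])
    assert sorted(held.tolist()) == list(range(11))
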