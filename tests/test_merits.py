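"""Figures of merit against straight-loop arithmetic oracles."""
import math

import numpy as np
import pytest
from scipy import stats

from specchem.errors import SpecchemError
from specchem.merits import (
    PairedOutcomes,
    RegressionLine,
    anova_oneway,
    core_stats,
    lod_loq,
    merit_report,
    precision_stats,
    q2_press,
    recovery_rsd,
    regression_line,
)


def _brute_force(y, yhat):
    """Independent loop re-implementation of every printed statistic."""
    n = len(y)
    rss = sum((a - b) ** 2 for a, b in zip(y, yhat))
    ybar = sum(y) / n
    ssx = sum((a - ybar) ** 2 for a in y)
    bias = sum(a - b for a, b in zip(y, yhat)) / n
    sec = math.sqrt(sum((a - b - bias) ** 2 for a, b in zip(y, yhat)) / (n - 1))
    return {
        "rss": rss,
        "ssx": ssx,
        "r2": 1 - rss / ssx if ssx > 0 else math.nan,
        "rmse": math.sqrt(rss / n),
        "bias": bias,
        "sec": sec,
        "rrmsep_pct": (math.sqrt(rss) / n) / ybar * 100,
        "bcmsep": rss / n - bias**2,
    }


class TestWorkedExamples:
    """The three-point hand calculations frozen as exact expectations."""

    y = np.array([10.0, 20.0, 30.0])
    yhat = np.array([11.0, 19.0, 31.0])

    def test_core_stats_hand_values(self):
        out = core_stats(PairedOutcomes(self.y, self.yhat))
        assert out["rss"] == pytest.approx(3.0)
        assert out["ssx"] == pytest.approx(200.0)
        assert out["r2"] == pytest.approx(0.985)
        assert out["rmse"] == pytest.approx(1.0)
        assert out["bias"] == pytest.approx(-1.0 / 3.0)

    def test_precision_stats_hand_values(self):
        out = precision_stats(PairedOutcomes(self.y, self.yhat))
        assert out["sec"] == pytest.approx(math.sqrt(24.0 / 18.0))  # 1.1547
        assert out["rrmsep_pct"] == pytest.approx(100.0 * math.sqrt(3.0) / 3.0 / 20.0)  # 2.8868
        assert out["bcmsep"] == pytest.approx(1.0 - 1.0 / 9.0)  # 0.8889

    def test_q2_hand_values(self):
        cv = PairedOutcomes(self.y, np.array([12.0, 18.0, 32.0]), "cross_validation")
        out = q2_press(cv, ssx=200.0)
        assert out["press"] == pytest.approx(12.0)
        assert out["q2"] == pytest.approx(0.94)

    def test_perfect_fit_degenerates_to_zeros_and_ones(self):
        p = PairedOutcomes(self.y, self.y)
        core = core_stats(p)
        prec = precision_stats(p)
        assert core["rss"] == 0 and core["r2"] == 1 and core["rmse"] == 0 and core["bias"] == 0
        assert prec["sec"] == 0 and prec["rrmsep_pct"] == 0 and prec["bcmsep"] == 0

    def test_q2_of_mean_model_is_zero(self):
        y = self.y
        cv = PairedOutcomes(y, np.full(3, y.mean()), "cross_validation")
        ssx = core_stats(PairedOutcomes(y, y))["ssx"]
        assert q2_press(cv, ssx)["q2"] == pytest.approx(0.0)


class TestBruteForceAgreement:
    def test_hundred_random_instances_match_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            y = rng.uniform(5, 50, size=n)
            yhat = y + rng.normal(0, 1, size=n)
            p = PairedOutcomes(y, yhat)
            got = {**core_stats(p), **precision_stats(p)}
            want = _brute_force(y.tolist(), yhat.tolist())
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-10), key

    def test_bcmsep_identity_and_positivity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.uniform(1, 10, size=12)
            yhat = y + rng.normal(0, 0.5, size=12)
            p = PairedOutcomes(y, yhat)
            core = core_stats(p)
            prec = precision_stats(p)
            assert prec["bcmsep"] == pytest.approx(core["rmse"] ** 2 - core["bias"] ** 2, abs=1e-12)
            assert prec["bcmsep"] >= -1e-12
            # SEC^2 = n/(n-1) * BCMSEP (exact algebra)
            assert prec["sec"] ** 2 == pytest.approx(12 / 11 * prec["bcmsep"], abs=1e-10)

    def test_constant_error_absorbed_by_bias(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        out = precision_stats(PairedOutcomes(y, y + 0.7))
        assert out["bcmsep"] == pytest.approx(0.0, abs=1e-12)
        assert out["sec"] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_and_permutation_invariances(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(5, 40, size=15)
        yhat = y + rng.normal(0, 1, size=15)
        base = core_stats(PairedOutcomes(y, yhat))
        perm = rng.permutation(15)
        shuffled = core_stats(PairedOutcomes(y[perm], yhat[perm]))
        assert shuffled["r2"] == pytest.approx(base["r2"], abs=1e-12)
        scaled = core_stats(PairedOutcomes(3 * y, 3 * yhat))
        assert scaled["rmse"] == pytest.approx(3 * base["rmse"], rel=1e-12)

    def test_conventional_rrmsep_form(self):
        y = np.array([10.0, 20.0, 30.0])
        yhat = np.array([11.0, 19.0, 31.0])
        out = precision_stats(PairedOutcomes(y, yhat), form="conventional")
        assert out["rrmsep_pct"] == pytest.approx(math.sqrt(1.0) / 20.0 * 100.0)


class TestDegenerateInputs:
    def test_constant_reference_flags_r2(self):
        out = core_stats(PairedOutcomes(np.array([5.0, 5, 5]), np.array([4.0, 5, 6])))
        assert not out["r2_defined"]
        assert math.isnan(out["r2"])

    def test_zero_mean_reference_flags_rrmsep(self):
        out = precision_stats(PairedOutcomes(np.array([-1.0, 1.0]), np.array([0.0, 0.0])))
        assert not out["rrmsep_defined"]


class TestLodLoq:
    def test_printed_formula_arithmetic(self):
        lod, loq = lod_loq(RegressionLine(slope=1.0, intercept=0.0, sigma=0.1))
        assert lod == pytest.approx(0.33)
        assert loq == pytest.approx(1.0)
        assert loq / lod == pytest.approx(10 / 3.3)

    def test_zero_sigma_gives_zero_lod(self):
        lod, _ = lod_loq(RegressionLine(1.0, 0.0, 0.0))
        assert lod == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(SpecchemError):
            lod_loq(RegressionLine(0.0, 0.0, 0.1))

    def test_regression_line_matches_hand_least_squares(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(10, 30, size=13)  # predicted
        y = x + rng.normal(0, 0.2, size=13)  # measured
        line = regression_line(PairedOutcomes(y, x, "prediction"))
        # hand normal equations
        sx, sy = x.sum(), y.sum()
        n = len(x)
        slope = (n * (x * y).sum() - sx * sy) / (n * (x**2).sum() - sx**2)
        intercept = (sy - slope * sx) / n
        resid = y - intercept - slope * x
        sigma = math.sqrt((resid**2).sum() / (n - 2))
        assert line.slope == pytest.approx(slope, rel=1e-10)
        assert line.intercept == pytest.approx(intercept, rel=1e-8)
        assert line.sigma == pytest.approx(sigma, rel=1e-10)


class TestRecoveryRsd:
    def test_single_recovery(self):
        table = recovery_rsd([19.8], [20.0])
        assert table["mean_recovery_pct"].iloc[0] == pytest.approx(99.0)

    def test_identical_replicates_have_zero_rsd(self):
        table = recovery_rsd([10.0, 10, 10], [10.0, 10, 10], [1, 1, 1])
        assert table["rsd_pct"].iloc[0] == 0.0

    def test_hand_sd_example(self):
        # recoveries 99, 100, 101 % -> mean 100, SD 1, %RSD 1
        table = recovery_rsd([9.9, 10.0, 10.1], [10.0, 10, 10], [1, 1, 1])
        assert table["mean_recovery_pct"].iloc[0] == pytest.approx(100.0)
        assert table["rsd_pct"].iloc[0] == pytest.approx(1.0)

    def test_zero_nominal_rejected(self):
        with pytest.raises(SpecchemError):
            recovery_rsd([1.0], [0.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([[1.0, 2, 3], [1.0, 2, 3]])
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_sum_of_squares_oracle(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4]]
        res = anova_oneway(groups)
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        f_hand = (ssb / 1) / (ssw / 4)
        assert res.f == pytest.approx(f_hand, rel=1e-12)
        assert res.f_critical == pytest.approx(stats.f.ppf(0.95, 1, 4))

    def test_zero_within_variance_flagged_infinite(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert math.isinf(res.f)
        assert res.degenerate

    def test_too_few_groups_rejected(self):
        with pytest.raises(SpecchemError):
            anova_oneway([[1.0, 2.0]])


class TestMeritReport:
    def test_fields_compose_from_individual_operations(self):
        rng = np.random.default_rng(9)
        y_cal = rng.uniform(10, 30, size=25)
        y_val = rng.uniform(10, 30, size=13)
        cal = PairedOutcomes(y_cal, y_cal + rng.normal(0, 0.1, 25), "calibration")
        cv = PairedOutcomes(y_cal, y_cal + rng.normal(0, 0.15, 25), "cross_validation")
        pred = PairedOutcomes(y_val, y_val + rng.normal(0, 0.1, 13), "prediction")
        rep = merit_report("PLS", "MLK", cal, cv, pred)
        assert rep.r2 == pytest.approx(core_stats(cal)["r2"])
        assert rep.q2 == pytest.approx(q2_press(cv, core_stats(cal)["ssx"])["q2"])
        assert rep.rmsep == pytest.approx(core_stats(pred)["rmse"])
        assert rep.sec == pytest.approx(precision_stats(pred)["sec"])
        lod, loq = lod_loq(regression_line(pred))
        assert rep.lod == pytest.approx(lod) and rep.loq == pytest.approx(loq)
        assert rep.to_dict()["model"] == "PLS"

    def test_all_perfect_inputs_give_unit_report(self):
        y = np.array([10.0, 15.0, 20.0, 25.0])
        p = lambda ctx: PairedOutcomes(y, y, ctx)
        rep = merit_report("CLS", "LCZ", p("calibration"), p("cross_validation"), p("prediction"))
        assert rep.r2 == 1 and rep.q2 == 1
        assert rep.rmsec == 0 and rep.rmsep == 0 and rep.lod == 0
        assert rep.mean_recovery_pct == pytest.approx(100.0)
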