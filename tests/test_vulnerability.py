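import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylemct.errors import ConvergenceError, ValidationError
from xylemct.synthetic import generate_plc_observations
from xylemct.vulnerability import (VulnerabilityCurve, bootstrap_thresholds,
                                   compare_curves, fit_curve, fit_logistic,
                                   fit_weibull, solve_weibull_parameters,
                                   threshold_psi, weibull_plc)


def _dense_points(scale, shape, n=40, lo=-8.0):
    psi = np.linspace(lo, -1e-3, n)
    return psi, weibull_plc(psi, scale, shape)


class TestFitWeibull:
    def test_noiseless_roundtrip(self):
        psi, plc = _dense_points(3.0, 4.0)
        fit = fit_weibull(psi, plc)
        assert fit.converged
        assert fit.scale_mpa == pytest.approx(3.0, rel=1e-6)
        assert fit.shape == pytest.approx(4.0, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_flat_plc_non_convergence(self):
        psi = np.linspace(-5.0, -0.5, 10)
        fit = fit_weibull(psi, np.zeros(10))
        assert not fit.converged
        assert np.isnan(fit.scale_mpa)
        with pytest.raises(ConvergenceError):
            threshold_psi(fit, 50.0)

    def test_identical_psi_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            fit_weibull([-2.0] * 6, [10.0, 20.0, 30.0, 40.0, 50.0, 60.0])

    def test_plc_out_of_range_rejected(self):
        psi = np.linspace(-5.0, -0.5, 4)
        with pytest.raises(ValidationError):
            fit_weibull(psi, [0.0, 50.0, 101.0, 90.0])
        with pytest.raises(ValidationError):
            fit_weibull(psi, [-5.0, 50.0, 80.0, 90.0])

    def test_positive_psi_rejected(self):
        with pytest.raises(ValidationError):
            fit_weibull([1.0, -2.0, -3.0, -4.0], [5.0, 30.0, 60.0, 90.0])

    def test_noisy_recovery_published_hydraulic_stem(self):
        # generating curve from psi50 = -2.81, psi88 = -3.72; n = 13,
        # sd = 5: mean fitted psi50 over 100 seeds within 0.1 MPa
        gen = solve_weibull_parameters(-2.81, 50.0, -3.72, 88.0)
        p50 = []
        for seed in range(100):
            df = generate_plc_observations(gen.scale_mpa, gen.shape, 13,
                                           (-5.0, 0.0), 5.0, seed=seed)
            fit = fit_weibull(df["psi_mpa"], df["plc_pct"])
            if fit.converged:
                p50.append(threshold_psi(fit, 50.0))
        assert len(p50) >= 95
        assert np.mean(p50) == pytest.approx(-2.81, abs=0.1)


class TestThresholdPsi:
    def test_closed_form_value(self):
        psi, plc = _dense_points(3.0, 4.0)
        fit = fit_weibull(psi, plc)
        assert threshold_psi(fit, 50.0) == pytest.approx(-2.7373, abs=1e-3)

    def test_limit_to_zero(self):
        psi, plc = _dense_points(3.0, 4.0)
        fit = fit_weibull(psi, plc)
        vals = [threshold_psi(fit, p) for p in (1.0, 1e-2, 1e-4, 1e-8)]
        assert all(v < 0 for v in vals)
        assert all(abs(b) < abs(a) for a, b in zip(vals, vals[1:]))
        assert abs(vals[-1]) < 1e-2

    def test_strictly_decreasing_in_p(self):
        psi, plc = _dense_points(2.5, 3.0)
        fit = fit_weibull(psi, plc)
        ps = np.linspace(1.0, 99.0, 50)
        vals = [threshold_psi(fit, p) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ordering_invariant_on_noisy_fits(self):
        for seed in range(25):
            df = generate_plc_observations(3.0, 2.0, 12, (-6.0, 0.0), 8.0,
                                           seed=seed)
            fit = fit_weibull(df["psi_mpa"], df["plc_pct"])
            if not fit.converged:
                continue
            assert (threshold_psi(fit, 12.0) > threshold_psi(fit, 50.0)
                    > threshold_psi(fit, 88.0))

    def test_p_out_of_range(self):
        psi, plc = _dense_points(3.0, 4.0)
        fit = fit_weibull(psi, plc)
        for bad in (0.0, 100.0, -3.0, 105.0):
            with pytest.raises(ValidationError):
                threshold_psi(fit, bad)


class TestSolveWeibullParameters:
    def test_roundtrip_against_threshold_psi(self):
        fit = solve_weibull_parameters(-1.5, 12.0, -3.2, 50.0)
        assert threshold_psi(fit, 12.0) == pytest.approx(-1.5, rel=1e-12)
        assert threshold_psi(fit, 50.0) == pytest.approx(-3.2, rel=1e-12)

    def test_published_hydraulic_stem_self_consistency(self):
        # solving from psi12 = -1.83, psi50 = -2.81 must put psi88 at the
        # published -3.72 within input rounding
        fit = solve_weibull_parameters(-1.83, 12.0, -2.81, 50.0)
        assert threshold_psi(fit, 88.0) == pytest.approx(-3.72, abs=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            solve_weibull_parameters(-2.0, 12.0, -2.0, 50.0)
        with pytest.raises(ValidationError):
            solve_weibull_parameters(-2.0, 50.0, -3.0, 50.0)


class TestBootstrapThresholds:
    def test_point_estimate_inside_ci(self):
        for seed in (0, 1, 2):
            df = generate_plc_observations(3.0, 3.0, 15, (-6.0, 0.0), 5.0,
                                           seed=seed)
            ts = bootstrap_thresholds(df["psi_mpa"], df["plc_pct"],
                                      n_boot=300, seed=seed)
            for name in ("psi12", "psi50", "psi88"):
                lo, hi = ts.ci[name]
                assert lo <= ts.value(name) <= hi

    def test_ci_collapses_without_noise(self):
        psi, plc = _dense_points(3.0, 4.0, n=20)
        ts = bootstrap_thresholds(psi, plc, n_boot=200, seed=0)
        lo, hi = ts.ci["psi50"]
        assert hi - lo < 1e-6

    def test_seed_reproducibility(self):
        df = generate_plc_observations(3.0, 3.0, 12, (-6.0, 0.0), 5.0, seed=4)
        a = bootstrap_thresholds(df["psi_mpa"], df["plc_pct"], n_boot=250, seed=7)
        b = bootstrap_thresholds(df["psi_mpa"], df["plc_pct"], n_boot=250, seed=7)
        assert a == b

    def test_n_boot_floor(self):
        df = generate_plc_observations(3.0, 3.0, 12, (-6.0, 0.0), 5.0, seed=4)
        with pytest.raises(ValidationError):
            bootstrap_thresholds(df["psi_mpa"], df["plc_pct"], n_boot=50, seed=0)

    def test_coverage_sanity(self):
        # scaled-down coverage check (the full 100-run version lives in
        # tests/test_acceptance.py): true psi50 inside the 95% CI most runs
        true50 = threshold_psi(
            fit_weibull(*_dense_points(3.0, 3.0)), 50.0)
        hits = 0
        for seed in range(30):
            df = generate_plc_observations(3.0, 3.0, 15, (-6.0, 0.0), 5.0,
                                           seed=100 + seed)
            ts = bootstrap_thresholds(df["psi_mpa"], df["plc_pct"],
                                      n_boot=250, seed=seed)
            lo, hi = ts.ci["psi50"]
            hits += lo <= true50 <= hi
        assert hits >= 24  # ~95% nominal, generous floor for 30 runs


class TestCompareCurves:
    def _curve(self, scale, shape, n, seed, organ, lo=-6.0, n_boot=250):
        df = generate_plc_observations(scale, shape, n, (lo, 0.0), 5.0,
                                       seed=seed)
        df = pd.DataFrame({"psi_mpa": df["psi_mpa"], "plc_pct": df["plc_pct"]})
        return fit_curve(df, organ, "microct", n_boot=n_boot, seed=seed)

    def test_identical_curves_not_significant(self):
        a = self._curve(3.0, 3.0, 15, seed=1, organ="a")
        res = compare_curves(a, a, "psi50")
        assert not res.significant

    def test_clearly_different_curves_significant(self):
        a = self._curve(1.2, 2.0, 15, seed=1, organ="vulnerable")
        b = self._curve(4.5, 4.0, 15, seed=2, organ="resistant")
        assert compare_curves(a, b, "psi50").significant

    def test_missing_cis_error(self):
        a = self._curve(3.0, 3.0, 15, seed=1, organ="a")
        bare = VulnerabilityCurve(organ="b", method="microct",
                                  points=a.points, fit=a.fit, thresholds=None)
        with pytest.raises(ValidationError):
            compare_curves(a, bare)

    def test_bad_threshold_name(self):
        a = self._curve(3.0, 3.0, 15, seed=1, organ="a")
        with pytest.raises(ValidationError):
            compare_curves(a, a, "psi99")


class TestFitLogistic:
    def test_recovers_midpoint(self):
        x50, s = 2.8, 3.0
        psi = np.linspace(-6.0, -0.01, 40)
        plc = 100.0 / (1.0 + np.exp(s * (x50 - np.abs(psi))))
        got_x50, got_s, rss = fit_logistic(psi, plc)
        assert got_x50 == pytest.approx(x50, rel=1e-6)
        assert got_s == pytest.approx(s, rel=1e-6)
        assert rss == pytest.approx(0.0, abs=1e-10)


@given(st.floats(min_value=0.5, max_value=6.0),
       st.floats(min_value=0.8, max_value=8.0))
@settings(max_examples=40, deadline=None)
def test_weibull_curve_monotone_nonincreasing_psi(scale, shape):
    psi = np.linspace(-9.0, 0.0, 60)
    plc = weibull_plc(psi, scale, shape)
    # PLC non-decreasing as psi decreases
    assert np.all(np.diff(plc) <= 1e-12)
    assert weibull_plc(0.0, scale, shape) == 0.0
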