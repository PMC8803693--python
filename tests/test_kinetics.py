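import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from clppkit.kinetics import (
    GompertzParams,
    InterpolatedCurve,
    KineticsOptions,
    classify_and_integrate,
    fit_curve,
    fit_gompertz,
    gompertz_value,
    heuristic_initializer,
    spline_interpolate,
    success_bookkeeping,
)

READ_TIMES = np.array([24.0, 48.0, 72.0, 96.0, 144.0])


def grid_curve(params, grid_points=100, horizon=96.0):
    grid = np.linspace(0.0, horizon, grid_points)
    return InterpolatedCurve(grid, np.clip(gompertz_value(params, grid), 0.0, None))


class TestGompertzClosedForm:
    @pytest.mark.parametrize(
        "A,mu,lam", [(1.0, 0.05, 10.0), (0.3, 0.01, 25.0), (2.5, 0.2, 3.0)]
    )
    def test_value_at_lag_is_A_exp_minus_e(self, A, mu, lam):
        p = GompertzParams(A, mu, lam)
        assert gompertz_value(p, lam) == pytest.approx(A * math.exp(-math.e), rel=1e-14)

    @pytest.mark.parametrize(
        "A,mu,lam", [(1.0, 0.05, 10.0), (0.3, 0.01, 25.0), (2.5, 0.2, 3.0)]
    )
    def test_inflection_value_is_A_over_e(self, A, mu, lam):
        p = GompertzParams(A, mu, lam)
        t_inf = lam + A / (mu * math.e)
        assert gompertz_value(p, t_inf) == pytest.approx(A / math.e, rel=1e-14)

    def test_example_evaluation(self, gompertz_oracle):
        p = GompertzParams(1.0, 0.05, 10.0)
        assert gompertz_value(p, 96.0) == pytest.approx(
            gompertz_oracle(1.0, 0.05, 10.0, 96.0), rel=1e-15
        )

    @given(
        A=st.floats(0.05, 3.0),
        mu_per_a=st.floats(0.005, 0.2),
        lam=st.floats(-20.0, 40.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_increasing_and_bounded_by_asymptote(self, A, mu_per_a, lam):
        p = GompertzParams(A, mu_per_a * A, lam)
        t = np.linspace(0.0, 500.0, 400)
        y = gompertz_value(p, t)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y <= A + 1e-12)
        assert gompertz_value(p, 1e6) == pytest.approx(A, rel=1e-6)


class TestSplineInterpolate:
    def test_reproduces_linear_data(self):
        ic = spline_interpolate(READ_TIMES, 0.01 * READ_TIMES)
        assert ic.od_hat == pytest.approx(0.01 * ic.grid_h, abs=1e-12)

    def test_grid_spans_96_despite_144h_read(self):
        ic = spline_interpolate(READ_TIMES, np.array([0.1, 0.5, 0.9, 1.0, 1.0]))
        assert ic.grid_h[-1] == 96.0
        assert len(ic.grid_h) == 100
        assert ic.od_hat[0] == 0.0  # anchor

    def test_144h_read_shapes_the_spline(self):
        with_tail = spline_interpolate(READ_TIMES, np.array([0.1, 0.5, 0.9, 1.0, 2.0]))
        without = spline_interpolate(READ_TIMES[:4], np.array([0.1, 0.5, 0.9, 1.0]))
        assert not np.allclose(with_tail.od_hat, without.od_hat)

    def test_all_zero_curve(self):
        ic = spline_interpolate(READ_TIMES, np.zeros(5))
        assert ic.is_zero

    def test_two_points_fall_back_to_linear(self):
        ic = spline_interpolate(np.array([24.0]), np.array([0.48]))
        assert ic.od_hat[0] == 0.0
        assert ic.od_hat == pytest.approx(np.interp(ic.grid_h, [0, 24], [0, 0.48]))

    def test_negative_excursions_clipped(self):
        # steep drop to zero can make a natural cubic spline undershoot
        ic = spline_interpolate(READ_TIMES, np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
        assert (ic.od_hat >= 0).all()


class TestHeuristicInitializer:
    def test_within_25_percent_on_noiseless_curve(self):
        truth = GompertzParams(1.2, 0.04, 12.0)
        p0 = heuristic_initializer(grid_curve(truth))
        assert p0.A == pytest.approx(truth.A, rel=0.25)
        assert p0.mu == pytest.approx(truth.mu, rel=0.25)
        assert p0.lam == pytest.approx(truth.lam, rel=0.25)

    def test_step_curve_amplitude(self):
        grid = np.linspace(0, 96, 100)
        od = np.where(grid > 40, 1.0, 0.0)
        p0 = heuristic_initializer(InterpolatedCurve(grid, od))
        assert p0.A == 1.0

    def test_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            heuristic_initializer(InterpolatedCurve(np.linspace(0, 96, 100), np.zeros(100)))


class TestFitGompertz:
    @pytest.mark.parametrize(
        "truth",
        [
            GompertzParams(1.2, 0.04, 12.0),
            GompertzParams(0.4, 0.01, 30.0),
            GompertzParams(2.0, 0.15, 5.0),
        ],
    )
    def test_noiseless_grid_recovery_below_1_percent(self, truth):
        cand = fit_gompertz(grid_curve(truth))
        assert cand.converged
        assert cand.params.A == pytest.approx(truth.A, rel=0.01)
        assert cand.params.mu == pytest.approx(truth.mu, rel=0.01)
        assert cand.params.lam == pytest.approx(truth.lam, rel=0.01)

    def test_median_amplitude_error_under_noise_below_5_percent(self):
        rng = np.random.default_rng(42)
        truth = GompertzParams(1.2, 0.04, 12.0)
        errs = []
        for _ in range(50):
            ic = grid_curve(truth)
            noisy = InterpolatedCurve(
                ic.grid_h, np.clip(ic.od_hat + rng.normal(0, 0.01, ic.od_hat.size), 0, None)
            )
            cand = fit_gompertz(noisy)
            errs.append(abs(cand.params.A / truth.A - 1.0))
        assert np.median(errs) < 0.05

    def test_slow_inprogress_growth_fits_negative_lag(self):
        truth = GompertzParams(1.0, 0.01, -10.0)
        od = gompertz_value(truth, READ_TIMES)
        fr = fit_curve(READ_TIMES, od)
        assert fr.outcome == "spline_fallback"
        assert fr.params.lam < 0


class TestClassifyAndIntegrate:
    def test_zero_curve_auc_exactly_zero(self):
        ic = InterpolatedCurve(np.linspace(0, 96, 100), np.zeros(100))
        fr = classify_and_integrate(ic, None)
        assert fr.outcome == "zero"
        assert fr.auc == 0.0

    def test_negative_lag_candidate_uses_spline_integral(self):
        ic = spline_interpolate(READ_TIMES, gompertz_value(GompertzParams(1.0, 0.01, -10.0), READ_TIMES))
        cand = fit_gompertz(ic)
        fr = classify_and_integrate(ic, cand)
        assert fr.outcome == "spline_fallback"
        assert fr.auc == pytest.approx(float(np.trapezoid(ic.od_hat, ic.grid_h)))

    def test_auc_matches_adaptive_quadrature_oracle(self, gompertz_oracle):
        rng = np.random.default_rng(1)
        for _ in range(25):
            A = rng.uniform(0.1, 2.0)
            truth = GompertzParams(A, A * rng.uniform(0.02, 0.1), rng.uniform(4, 30))
            fr = classify_and_integrate(grid_curve(truth), fit_gompertz(grid_curve(truth)))
            oracle, _ = quad(
                lambda t: gompertz_oracle(truth.A, truth.mu, truth.lam, t), 0, 96, limit=200
            )
            assert fr.outcome == "gompertz"
            assert fr.auc == pytest.approx(oracle, rel=0.005)


class TestSuccessBookkeeping:
    def make_fits(self, cells):
        rows = []
        for treatment, day, n_reactors, n_fail in cells:
            i = 0
            for reactor in range(n_reactors):
                for s in range(31):
                    rows.append(
                        dict(
                            sample_id=f"{treatment}-{reactor}", reactor_id=reactor + 1,
                            treatment=treatment, day=day, matrix="solid",
                            substrate=f"sub{s}", imputed=False,
                            outcome="spline_fallback" if i < n_fail else "gompertz",
                        )
                    )
                    i += 1
        return pd.DataFrame(rows)

    def test_all_successful_full_cell(self):
        out = success_bookkeeping(self.make_fits([("aerobic", 0, 3, 0)]))
        row = out.iloc[0]
        assert (row.n_success, row.n_total, row.percent) == (93, 93, 100.0)

    def test_percent_rounding(self):
        out = success_bookkeeping(self.make_fits([("aerobic", 0, 3, 24)]))
        row = out.iloc[0]
        assert (row.n_success, row.n_total, row.percent) == (69, 93, 74.2)

    def test_two_reactor_cell_denominator_62(self):
        out = success_bookkeeping(self.make_fits([("mixed", 763, 2, 0)]))
        assert out.iloc[0].n_total == 62

    def test_imputed_samples_excluded(self):
        fits = self.make_fits([("mixed", 763, 3, 0)])
        fits.loc[fits["reactor_id"] == 3, "imputed"] = True
        assert success_bookkeeping(fits).iloc[0].n_total == 62


def test_fit_target_cumulative_option_runs():
    truth = GompertzParams(1.2, 0.04, 12.0)
    opts = KineticsOptions(fit_target="cumulative")
    cand = fit_gompertz(grid_curve(truth), opts)
    assert cand.converged
    assert cand.params.A == pytest.approx(truth.A, rel=0.05)
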