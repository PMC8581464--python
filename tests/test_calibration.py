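"""Weighted calibration fits, RSE, inverse prediction, working range."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavorquant.calibration import (
    CalibrationFit,
    CalibrationPoint,
    WorkingRange,
    calibration_rse,
    determine_working_range,
    fit_calibration,
    inverse_predict,
    relative_response_factor,
)
from flavorquant.errors import (
    ArgumentError,
    BelowRangeSignal,
    EmptyRangeError,
    FitError,
    OverRangeSignal,
)


def points_on(f, xs, **kw):
    return [CalibrationPoint(x, f(x), **kw) for x in xs]


XS = [10 / 2**i for i in range(10)]


class TestRRF:
    def test_symmetry_and_arithmetic(self):
        assert relative_response_factor(1000, 1000, 2.0, 2.0) == 1.0
        assert relative_response_factor(500, 1000, 1.0, 1.0) == 0.5

    def test_bad_arguments(self):
        with pytest.raises(ArgumentError):
            relative_response_factor(500, 0, 1, 1)
        with pytest.raises(ArgumentError):
            relative_response_factor(500, 1000, 0, 1)


class TestFit:
    def test_exact_linear(self):
        fit = fit_calibration(points_on(lambda x: 0.1 * x, XS), model="linear")
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(0.1, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rse_percent == pytest.approx(0.0, abs=1e-6)

    def test_exact_quadratic(self):
        fit = fit_calibration(points_on(lambda x: 0.01 * x**2 + 0.1 * x, XS))
        assert fit.coefficients == pytest.approx((0.0, 0.1, 0.01), abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_quadratic_on_linear_data_matches_linear_fit(self):
        lin = fit_calibration(points_on(lambda x: 0.2 * x + 0.001, XS), model="linear")
        quad = fit_calibration(points_on(lambda x: 0.2 * x + 0.001, XS))
        assert abs(quad.c) < 1e-10
        assert quad.a == pytest.approx(lin.a, abs=1e-9)
        assert quad.b == pytest.approx(lin.b, rel=1e-9)

    def test_equal_weights_reproduce_unweighted_fit(self):
        rng = np.random.default_rng(4)
        ys = [0.1 * x * (1 + 0.05 * rng.standard_normal()) for x in XS]
        pts_none = [CalibrationPoint(x, y) for x, y in zip(XS, ys)]
        pts_eq = [CalibrationPoint(x, y, weight=3.7) for x, y in zip(XS, ys)]
        f_none = fit_calibration(pts_none, weighting="none")
        f_eq = fit_calibration(pts_eq, weighting="1/x^2")  # explicit weights win
        assert f_eq.coefficients == pytest.approx(f_none.coefficients, rel=1e-9)

    def test_oracle_equivalence_normal_equations(self):
        """Weighted fit matches a brute-force normal-equations solve."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            xs = sorted(rng.uniform(0.05, 10, size=rng.integers(4, 7)))
            ys = [0.3 * x * (1 - 0.02 * x) * (1 + 0.06 * rng.standard_normal()) for x in xs]
            pts = [CalibrationPoint(x, max(y, 0)) for x, y in zip(xs, ys)]
            fit = fit_calibration(pts, model="quadratic", weighting="1/x^2")
            X = np.column_stack([np.ones(len(xs)), xs, np.square(xs)])
            W = np.diag([1 / x**2 for x in xs])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.array([p.response_ratio for p in pts]))
            assert fit.coefficients == pytest.approx(tuple(beta), rel=1e-8, abs=1e-12)

    def test_too_few_distinct_levels(self):
        pts = [CalibrationPoint(1.0, 0.1), CalibrationPoint(1.0, 0.11), CalibrationPoint(2.0, 0.2)]
        with pytest.raises(FitError):
            fit_calibration(pts, model="quadratic")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100))
    def test_rse_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(12)
        ys = [0.1 * x * (1 + 0.05 * rng.standard_normal()) for x in XS]
        base = fit_calibration([CalibrationPoint(x, y) for x, y in zip(XS, ys)])
        scaled = fit_calibration(
            [CalibrationPoint(x * scale, y * scale) for x, y in zip(XS, ys)]
        )
        assert scaled.rse_percent == pytest.approx(base.rse_percent, rel=1e-6)


class TestRSE:
    def test_hand_computed_value(self):
        """Four levels at +/-10% relative error, quadratic: 100*sqrt(0.04/1)."""
        recs = [(1.0, 110.0), (2.0, 90.0), (3.0, 110.0), (4.0, 90.0)]
        fit = CalibrationFit(
            analyte_name="x", model="quadratic", coefficients=(0, 1, 0),
            r2=1, r2_unweighted=1, rse_percent=float("nan"),
            points=[CalibrationPoint(lv, lv) for lv, _ in recs],
            p_terms=3, weighting="1/x^2", recoveries=recs,
        )
        assert calibration_rse(fit) == pytest.approx(20.0)

    def test_perfect_backcalc_gives_zero(self):
        fit = fit_calibration(points_on(lambda x: 0.5 * x, XS))
        assert fit.rse_percent == pytest.approx(0.0, abs=1e-6)

    def test_n_not_greater_than_p_raises(self):
        fit = CalibrationFit(
            analyte_name="x", model="quadratic", coefficients=(0, 1, 0),
            r2=1, r2_unweighted=1, rse_percent=float("nan"),
            points=[CalibrationPoint(1, 1)], p_terms=3, weighting="1/x^2",
            recoveries=[(1.0, 100.0), (2.0, 100.0), (3.0, 100.0)],
        )
        with pytest.raises(FitError):
            calibration_rse(fit)


class TestInversePredict:
    def test_linear_closed_form(self):
        fit = fit_calibration(points_on(lambda x: 0.1 * x, XS), model="linear")
        assert inverse_predict(fit, 0.5) == pytest.approx(5.0)

    def test_forward_then_invert_round_trip(self):
        fit = fit_calibration(points_on(lambda x: 0.1 * x - 0.002 * x**2, XS))
        y = float(fit.predict(4.0))
        assert inverse_predict(fit, y) == pytest.approx(4.0, abs=1e-9)

    def test_round_trip_across_the_range(self):
        fit = fit_calibration(points_on(lambda x: 0.3 * x * (1 - 0.03 * x), XS))
        for x in np.geomspace(0.02, 10, 40):
            y = float(fit.predict(x))
            assert inverse_predict(fit, y) == pytest.approx(x, rel=1e-6)

    def test_response_above_curve_maximum_is_over_range(self):
        fit = fit_calibration(points_on(lambda x: 0.1 * x - 0.004 * x**2, XS))
        ymax = 0.1**2 / (4 * 0.004)  # vertex of the true parabola
        with pytest.raises(OverRangeSignal):
            inverse_predict(fit, ymax * 1.5)

    def test_beyond_uloq_is_over_range_with_estimate(self):
        fit = fit_calibration(points_on(lambda x: 0.1 * x, XS), model="linear")
        with pytest.raises(OverRangeSignal) as exc:
            inverse_predict(fit, 0.1 * 20, uloq=10.0)
        assert exc.value.estimate == pytest.approx(20.0)

    def test_below_zero_is_bloq_signal(self):
        fit = fit_calibration(
            [CalibrationPoint(x, 0.1 * x + 0.01) for x in XS], model="linear"
        )
        with pytest.raises(BelowRangeSignal):
            inverse_predict(fit, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.01, 1.0),
        q=st.floats(-0.04, 0.01),
        x=st.floats(0.02, 10.0),
    )
    def test_round_trip_property(self, b, q, x):
        """inverse(forward(x)) = x for any monotone curve over the range."""
        fit = CalibrationFit(
            analyte_name="p", model="quadratic", coefficients=(0.0, b, b * q),
            r2=1, r2_unweighted=1, rse_percent=0.0,
            points=[CalibrationPoint(lv, b * lv * (1 + q * lv)) for lv in XS],
            p_terms=3, weighting="1/x^2",
        )
        y = float(fit.predict(x))
        assert inverse_predict(fit, y) == pytest.approx(x, rel=1e-6)


class TestWorkingRange:
    def _fit_with_recoveries(self, recs):
        return CalibrationFit(
            analyte_name="x", model="quadratic", coefficients=(0, 1, 0),
            r2=1, r2_unweighted=1, rse_percent=0.0,
            points=[CalibrationPoint(lv, lv) for lv, _ in recs],
            p_terms=3, weighting="1/x^2", recoveries=recs,
        )

    def test_all_levels_pass(self):
        fits = [
            self._fit_with_recoveries([(0.1, 98.0), (1.0, 101.0), (10.0, 99.0)]),
            self._fit_with_recoveries([(0.1, 103.0), (1.0, 97.0), (10.0, 102.0)]),
        ]
        wr = determine_working_range(fits)
        assert (wr.lloq, wr.uloq) == (0.1, 10.0)

    def test_noisy_bottom_levels_raise_lloq(self):
        """Bottom two levels with ~35% CV across batches fail; third passes."""
        fits = [
            self._fit_with_recoveries([(0.1, 60.0), (0.2, 140.0), (0.4, 99.0), (1.0, 100.0)]),
            self._fit_with_recoveries([(0.1, 140.0), (0.2, 60.0), (0.4, 101.0), (1.0, 100.0)]),
            self._fit_with_recoveries([(0.1, 100.0), (0.2, 100.0), (0.4, 100.0), (1.0, 100.0)]),
        ]
        wr = determine_working_range(fits)
        assert wr.lloq == 0.4

    def test_no_passing_level_raises(self):
        fits = [
            self._fit_with_recoveries([(1.0, 150.0)]),
            self._fit_with_recoveries([(1.0, 55.0)]),
        ]
        with pytest.raises(EmptyRangeError):
            determine_working_range(fits)

    def test_saturated_top_level_caps_uloq(self, panel):
        """Detector saturation at 5 mg/ml drops the 10 mg/ml level."""
        from flavorquant import generate_validation_study, saturating
        from flavorquant.quantify import assemble_batch

        inst = saturating(panel)
        study = generate_validation_study(
            inst, panel, seed=5, n_batches=2,
            include_dilution_checks=False, include_stability=False,
        )
        fits = []
        for bid, m in study.manifest.groupby("batch_id"):
            p = study.peaks[study.peaks["sample_id"].isin(m["sample_id"])]
            fits.append(assemble_batch(m, p, panel).fits["Benzyl Alcohol"])
        wr = determine_working_range(fits)
        assert wr.uloq == 5.0
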