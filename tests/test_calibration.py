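import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from platequant.calibration import (
    CalibrationCurve,
    LinearCalibrator,
    estimate_lod,
    fit_linear,
    inverse_predict,
    loq_from_lod,
)
from platequant.errors import FitError, SchemaError, UndetectableError


def ols_oracle(x, y):
    """Closed-form normal equations, independent of the fit path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestFitLinear:
    def test_exact_line(self):
        curve = fit_linear([0, 1, 2], [1, 3, 5])
        assert (curve.slope, curve.intercept) == (2.0, 1.0)
        assert curve.r_squared == 1.0
        assert curve.rmse == 0.0 and curve.rrmse_percent == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 20, size=50)
        y = 113.25 + 0.8118 * x + rng.normal(0, 2, size=50)
        curve = fit_linear(x, y)
        slope, intercept = ols_oracle(x, y)
        assert curve.slope == pytest.approx(slope, rel=1e-9)
        assert curve.intercept == pytest.approx(intercept, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_linear([0, 1], [1, 2])

    def test_no_concentration_spread_rejected(self):
        with pytest.raises(FitError):
            fit_linear([5, 5, 5], [1, 2, 3])

    def test_constant_response_has_unit_r_squared(self):
        curve = fit_linear([0, 5, 10], [7, 7, 7])
        assert curve.slope == 0.0 and curve.r_squared == 1.0

    def test_rmse_denominator_option(self):
        x, y = [0, 1, 2, 3], [1.0, 2.9, 5.2, 6.9]
        n_curve = fit_linear(x, y, rmse_denominator="n")
        n2_curve = fit_linear(x, y, rmse_denominator="n-2")
        assert n2_curve.rmse == pytest.approx(n_curve.rmse * np.sqrt(4 / 2))

    @given(scale=st.floats(0.1, 100.0))
    def test_affine_equivariance_in_response(self, scale):
        x = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        y = np.array([113.0, 118.1, 120.9, 125.4, 129.8])
        base = fit_linear(x, y)
        scaled = fit_linear(x, scale * y)
        assert scaled.slope == pytest.approx(scale * base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(scale * base.intercept, rel=1e-9)
        assert scaled.rmse == pytest.approx(scale * base.rmse, rel=1e-6)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_curve_json_round_trip(self, tmp_path):
        curve = fit_linear([0, 5, 10, 15, 20], [113.0, 118.1, 120.9, 125.4, 129.8])
        path = tmp_path / "curve.json"
        curve.save(path)
        again = CalibrationCurve.load(path)
        assert again == curve
        assert set(json.loads(path.read_text())) == {
            "slope", "intercept", "r_squared", "rmse", "rrmse_percent",
            "n_points", "channel_or_mode",
        }


class TestLinearCalibratorEstimator:
    def test_sklearn_contract(self):
        est = LinearCalibrator(channel="B")
        assert est.get_params() == {"channel": "B", "rmse_denominator": "n"}
        est.set_params(channel="absorbance")
        est.fit(np.array([[0.0], [5.0], [10.0]]), np.array([0.56, 0.59, 0.62]))
        assert est.n_points_ == 3
        assert est.to_curve().channel_or_mode == "absorbance"

    def test_predict_then_inverse_predict_round_trips(self):
        est = LinearCalibrator().fit([0, 5, 10, 15, 20], [113.25, 117.3, 121.4, 125.4, 129.5])
        x = np.array([1.0, 7.5, 18.0])
        assert est.inverse_predict(est.predict(x)) == pytest.approx(x, abs=1e-9)

    def test_unfitted_estimator_raises(self):
        with pytest.raises(FitError):
            LinearCalibrator().predict([1.0])

    def test_works_in_sklearn_clone(self):
        from sklearn.base import clone

        est = clone(LinearCalibrator(channel="G"))
        assert est.channel == "G"


class TestInversePredict:
    REFERENCE = CalibrationCurve(
        slope=0.8118, intercept=113.25, r_squared=0.9832, rmse=0.0,
        rrmse_percent=0.0, n_points=5, channel_or_mode="B",
    )

    def test_intercept_maps_to_zero(self):
        assert inverse_predict(self.REFERENCE, 113.25) == 0.0

    def test_inverse_of_forward_response(self):
        assert inverse_predict(self.REFERENCE, 121.368) == pytest.approx(10.0)

    def test_below_blank_is_negative_not_clamped(self):
        assert inverse_predict(self.REFERENCE, 112.0) < 0

    def test_zero_slope_rejected(self):
        flat = CalibrationCurve(0.0, 1.0, 1.0, 0.0, 0.0, 3, "B")
        with pytest.raises(FitError):
            inverse_predict(flat, 1.0)

    @given(x=st.floats(0, 50))
    def test_round_trip_on_exact_line(self, x):
        curve = fit_linear([0, 5, 10], [113.25, 117.309, 121.368])
        response = curve.intercept + curve.slope * x
        assert inverse_predict(curve, response) == pytest.approx(x, abs=1e-9)


def _lod_inputs(separations, sd=1.0, n=6, seed=0):
    """Replicate responses for a two-fold walk with given mean separations."""
    rng = np.random.default_rng(seed)
    blanks = rng.normal(100.0, sd, n)
    levels = {}
    for conc, sep in separations.items():
        levels[conc] = rng.normal(100.0 + sep, sd, n)
    return blanks, levels


class TestEstimateLod:
    def test_walkdown_matches_reference_validation(self):
        # levels >= 2 μg/mL clearly separated, below indistinguishable
        blanks, levels = _lod_inputs({4.0: 8.0, 2.0: 6.0, 1.0: 0.0, 0.5: 0.0, 0.25: 0.0})
        result = estimate_lod(blanks, levels)
        assert result.lod == 2.0
        assert result.loq == 6.0
        assert not result.censored
        decided = {d.concentration: d.significant for d in result.decisions}
        assert decided[4.0] and decided[2.0] and not decided[1.0]

    def test_identical_constants_are_undetectable(self):
        with pytest.raises(UndetectableError):
            estimate_lod([5.0, 5.0, 5.0], {1.0: [5.0, 5.0, 5.0]})

    def test_all_levels_distinguishable_is_censored(self):
        blanks, levels = _lod_inputs({c: 50.0 for c in (4.0, 2.0, 1.0, 0.5, 0.25)})
        result = estimate_lod(blanks, levels)
        assert result.lod == 0.25 and result.censored

    def test_isolated_low_rejection_does_not_set_lod(self):
        # 1 μg/mL indistinguishable but 0.5 strongly separated: chain stops at 2
        blanks, levels = _lod_inputs({4.0: 8.0, 2.0: 6.0, 1.0: 0.0, 0.5: 9.0, 0.25: 0.0})
        result = estimate_lod(blanks, levels)
        assert result.lod == 2.0

    def test_monotone_in_effect_size(self):
        """Increasing every level's separation from blank never raises the LOD."""
        base_sep = {4.0: 3.0, 2.0: 1.5, 1.0: 0.6, 0.5: 0.2, 0.25: 0.1}
        blanks, levels = _lod_inputs(base_sep, seed=11)
        lod_small = estimate_lod(blanks, levels).lod
        blanks2, boosted = _lod_inputs({c: s + 5.0 for c, s in base_sep.items()}, seed=11)
        lod_large = estimate_lod(blanks2, boosted).lod
        assert lod_large <= lod_small

    def test_negative_slope_direction(self):
        # red/green channels decrease with concentration
        rng = np.random.default_rng(2)
        blanks = rng.normal(180.0, 1.0, 6)
        levels = {4.0: rng.normal(172.0, 1.0, 6), 2.0: rng.normal(176.0, 1.0, 6)}
        result = estimate_lod(blanks, levels, slope_sign=-1.0)
        assert result.lod in (2.0, 4.0)

    def test_input_validation(self):
        with pytest.raises(SchemaError):
            estimate_lod([1.0], {1.0: [1.0, 2.0]})
        with pytest.raises(SchemaError):
            estimate_lod([1.0, 2.0], {})
        with pytest.raises(SchemaError):
            estimate_lod([1.0, 2.0], {1.0: [1.0]})


class TestLoqFromLod:
    @pytest.mark.parametrize("lod, loq", [(2.0, 6.0), (0.5, 1.5)])
    def test_three_times_rule(self, lod, loq):
        assert loq_from_lod(lod) == loq

    @pytest.mark.parametrize("lod", [0.0, -1.0])
    def test_nonpositive_lod_rejected(self, lod):
        with pytest.raises(SchemaError):
            loq_from_lod(lod)
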