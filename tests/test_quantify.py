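import numpy as np
import pytest
from hypothesis import given, strategies as st

from platequant.calibration import fit_linear, inverse_predict
from platequant.errors import QCError, SchemaError
from platequant.plate import DilutionScheme, PlateLayout, WellAddress, WellRole
from platequant.quantify import (
    ReplicateSummary,
    aggregate_replicates,
    compare_methods,
    content_from_concentration,
    quantify_plate,
    recovery,
    round_half_up,
    screen_outlier,
)
from platequant.synthetic import ColorResponseModel, simulate_readings


class TestAggregateReplicates:
    def test_constant_replicates(self):
        s = aggregate_replicates([5, 5, 5])
        assert (s.mean, s.sd, s.rsd_percent) == (5.0, 0.0, 0.0)

    def test_textbook_sample_sd(self):
        s = aggregate_replicates([1, 2, 3])
        assert s.mean == 2.0 and s.sd == 1.0 and s.rsd_percent == 50.0

    def test_validation_rsd_average(self):
        # mean of the two validation-sample RSDs rounds to the reported 10.6 %
        assert round_half_up(np.mean([10.3, 10.9]), 1) == 10.6

    def test_single_value_rejected(self):
        with pytest.raises(QCError):
            aggregate_replicates([1.0])

    def test_zero_mean_with_spread_rejected(self):
        with pytest.raises(QCError):
            aggregate_replicates([-1.0, 1.0])

    @given(scale=st.floats(0.01, 1000.0))
    def test_rsd_is_scale_invariant(self, scale):
        base = aggregate_replicates([1.2, 1.5, 1.8, 1.4])
        scaled = aggregate_replicates([scale * v for v in [1.2, 1.5, 1.8, 1.4]])
        assert scaled.rsd_percent == pytest.approx(base.rsd_percent, rel=1e-9)

    def test_optional_dixon_exclusion(self):
        s = aggregate_replicates([1.43, 1.57, 9.0], outlier="dixon_q")
        assert s.excluded_indices == (2,)
        assert s.n == 2 and s.mean == pytest.approx(1.5)


class TestScreenOutlier:
    def test_gross_outlier_flagged(self):
        # Q = 7.43/7.57 = 0.981 > 0.970 (n=3, 95 %)
        assert screen_outlier([1.43, 1.57, 9.0]) == 2

    def test_regular_spread_not_flagged(self):
        # Q = 0.5 < 0.970
        assert screen_outlier([1, 2, 3]) is None

    def test_low_extreme_flagged(self):
        assert screen_outlier([-9.0, 1.43, 1.57]) == 0

    def test_method_none_never_excludes(self):
        assert screen_outlier([1.43, 1.57, 9.0], method="none") is None

    def test_constant_values_not_flagged(self):
        assert screen_outlier([2.0, 2.0, 2.0]) is None

    @pytest.mark.parametrize("n", [2, 8])
    def test_replicate_count_outside_table_rejected(self, n):
        with pytest.raises(QCError):
            screen_outlier(list(range(n)))


class TestContentConversion:
    def test_reference_scheme_six_micrograms(self):
        # 6 μg/mL * 50x * 5 mL / 0.1 g = 15000 μg/g = 1.5 g/100 g
        assert content_from_concentration(6.0) == pytest.approx(1.5)

    def test_zero_maps_to_zero(self):
        assert content_from_concentration(0.0) == 0.0

    def test_upper_range_value(self):
        assert content_from_concentration(12.0) == pytest.approx(3.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(QCError):
            content_from_concentration(-0.1)

    @given(conc=st.floats(0, 20), factor=st.floats(0.5, 4.0))
    def test_linear_in_concentration_and_volumes(self, conc, factor):
        base = content_from_concentration(conc)
        assert content_from_concentration(conc, DilutionScheme(extract_volume=5.0 * factor)) == (
            pytest.approx(base * factor)
        )
        assert content_from_concentration(conc, DilutionScheme(sample_mass=0.05)) == (
            pytest.approx(base * 2)
        )


class TestRecovery:
    def test_perfect_recovery(self):
        assert recovery(3.0, 2.0, 1.0) == 100.0

    def test_reference_low_spike(self):
        assert recovery(2.936, 2.0, 1.0) == pytest.approx(93.6)

    def test_reported_average_rounds_to_integer(self):
        assert round(np.mean([93.6, 92.3])) == 93

    def test_invariant_to_common_background(self):
        assert recovery(3.0, 2.0, 1.0) == recovery(3.7, 2.7, 1.0)

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(QCError):
            recovery(3.0, 2.0, 0.0)


class TestCompareMethods:
    SMARTPHONE_SDS = [0.9, 0.4, 0.4, 0.5, 0.7, 0.7, 0.3, 0.7, 0.4, 0.9]

    @staticmethod
    def _summaries(means, sds):
        return [ReplicateSummary(m, s, 0.0, 3) for m, s in zip(means, sds)]

    def test_reference_mean_sd(self):
        summaries = self._summaries([0.0] * 10, self.SMARTPHONE_SDS)
        comparison = compare_methods({"smartphone": summaries})
        assert comparison.mean_sd["smartphone"] == pytest.approx(0.59)
        assert round_half_up(comparison.mean_sd["smartphone"], 1) == 0.6

    def test_identical_methods_have_zero_difference(self):
        s = self._summaries([1.0, 2.0], [0.1, 0.2])
        comparison = compare_methods({"a": s, "b": s})
        assert comparison.differences["b"] == [0.0, 0.0]

    def test_single_sample_mean_equals_its_sd(self):
        comparison = compare_methods(
            {"a": self._summaries([1.0], [0.3]), "b": self._summaries([1.2], [0.5])}
        )
        assert comparison.mean_sd == {"a": 0.3, "b": 0.5}
        assert comparison.differences["b"] == pytest.approx([0.2])

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(QCError):
            compare_methods(
                {"a": self._summaries([1.0], [0.1]), "b": self._summaries([1.0, 2.0], [0.1, 0.1])}
            )


def _pipeline_layout():
    wells = {}
    for i, conc in enumerate([0, 5, 10, 15, 20]):
        wells[WellAddress("A", i + 1)] = WellRole("standard", concentration=float(conc))
    for i in range(3):
        wells[WellAddress("B", i + 1)] = WellRole("sample", sample_id="S1", replicate=i + 1)
    return PlateLayout(wells)


class TestQuantifyPlate:
    def test_zero_noise_recovers_exact_content(self):
        layout = _pipeline_layout()
        readings = simulate_readings(
            layout, model=ColorResponseModel(noise_sd=0.0), sample_concentrations={"S1": 6.0}
        )
        results, curve = quantify_plate(readings, layout)
        assert curve.r_squared == pytest.approx(1.0)
        row = results.iloc[0]
        assert row["mean_conc"] == pytest.approx(6.0, abs=1e-9)
        assert row["mean_content"] == pytest.approx(1.5, abs=1e-9)
        assert row["content_1dp"] == 1.5 and not row["below_blank"]

    def test_missing_sample_well_rejected(self):
        layout = _pipeline_layout()
        readings = simulate_readings(
            layout, model=ColorResponseModel(noise_sd=0.0), sample_concentrations={"S1": 6.0}
        )
        with pytest.raises(SchemaError):
            quantify_plate(readings[:-1], layout)

    def test_full_pipeline_content_is_unbiased(self):
        """Simulated triplicates at known content, re-fit and re-quantified per
        seed, recover the true content within 3 Monte-Carlo SEs over 200 runs."""
        layout = _pipeline_layout()
        model = ColorResponseModel(noise_sd=1.0)
        true_content = content_from_concentration(8.0)
        contents = []
        for seed in range(200):
            readings = simulate_readings(
                layout, model=model, seed=seed, sample_concentrations={"S1": 8.0}
            )
            results, _ = quantify_plate(readings, layout)
            contents.append(float(results["mean_content"].iloc[0]))
        contents = np.asarray(contents)
        se = contents.std(ddof=1) / np.sqrt(contents.size)
        assert abs(contents.mean() - true_content) < 3 * se


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [(0.25, 1, 0.3), (0.59, 1, 0.6), (1.45, 1, 1.5), (0.0025, 3, 0.003), (92.95, 1, 93.0)],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
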