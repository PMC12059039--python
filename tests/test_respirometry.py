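"""Respirometry reduction arithmetic and the stable-window search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quailtherm import (
    GasTrace,
    energetics,
    ewl_from_wvp,
    reduce_trace,
    relativize,
    stable_window,
    vo2,
)
from quailtherm.datamodel import RespirometryRecord
from quailtherm.errors import InputError
from quailtherm.synthetic import TraceNoiseSpec, generate_gas_traces


class TestVO2:
    def test_hand_computed_example(self):
        assert vo2(0.2095, 0.2065, 4200.0) == pytest.approx(
            4200.0 * 0.003 / (1 - 0.2095), rel=1e-12
        )
        assert vo2(0.2095, 0.2065, 4200.0) == pytest.approx(15.94, abs=0.005)

    def test_zero_extraction_gives_zero(self):
        assert vo2(0.2095, 0.2095, 4200.0) == 0.0

    @given(fr=st.floats(100.0, 20000.0), feo2=st.floats(0.15, 0.2094))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_of_degree_one_in_flow(self, fr, feo2):
        assert vo2(0.2095, feo2, 2 * fr) == pytest.approx(2 * vo2(0.2095, feo2, fr), rel=1e-12)

    def test_negative_consumption_warns_but_is_not_clamped(self):
        with pytest.warns(RuntimeWarning, match="negative oxygen consumption"):
            value = vo2(0.2065, 0.2095, 4200.0)
        assert value < 0


class TestEWL:
    def test_hand_computed_example(self):
        expected = 4200.0 * (1.0 / 100.3) * (18.016 / 22414.0)
        assert ewl_from_wvp(1.0, 0.0, 4200.0, 101.3) == pytest.approx(expected, rel=1e-12)
        assert ewl_from_wvp(1.0, 0.0, 4200.0, 101.3) == pytest.approx(0.03366, abs=2e-5)

    def test_zero_gradient_gives_zero(self):
        assert ewl_from_wvp(0.8, 0.8, 4200.0, 101.3) == 0.0

    @given(wvpe=st.floats(0.01, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_excurrent_vapour_pressure(self, wvpe):
        low = ewl_from_wvp(wvpe, 0.0, 4200.0, 101.3)
        high = ewl_from_wvp(wvpe + 0.1, 0.0, 4200.0, 101.3)
        assert high > low

    def test_vapour_pressure_above_barometric_is_an_error(self):
        with pytest.raises(InputError):
            ewl_from_wvp(102.0, 0.0, 4200.0, 101.3)


class TestEnergetics:
    def test_oxyjoule_conversion(self):
        assert energetics(3.0, 0.0).mhp_w == pytest.approx(1.0, rel=1e-12)

    def test_zero_ewl_gives_zero_ehl_and_ece(self):
        sample = energetics(3.0, 0.0)
        assert sample.ehl_w == 0.0
        assert sample.ece == 0.0

    def test_ece_hand_example(self):
        sample = energetics(3.0, 0.0125)
        assert sample.ece == pytest.approx(0.50125, rel=1e-12)

    def test_zero_vo2_reports_missing_ece(self):
        assert energetics(0.0, 0.01).ece is None

    @given(vo2_value=st.floats(0.1, 50.0), ewl_value=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_ece_identity(self, vo2_value, ewl_value):
        sample = energetics(vo2_value, ewl_value)
        assert sample.ece == pytest.approx(
            (ewl_value * 2406.0) / (vo2_value * 20.0), rel=1e-12
        )


class TestStableWindow:
    def test_constant_trace_ties_break_to_earliest(self):
        assert stable_window(np.full(600, 0.205), 120) == (0, 120)

    def test_finds_embedded_low_noise_segment(self):
        rng = np.random.default_rng(3)
        trace = 0.206 + 0.01 * rng.standard_normal(600)
        trace[250:370] = 0.206 + 0.0001 * rng.standard_normal(120)
        start, stop = stable_window(trace, 120)
        assert 245 <= start <= 255 and stop - start == 120

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(11)
        trace = 0.2065 + 0.002 * rng.standard_normal(800)
        start, stop = stable_window(trace, 120)
        sds = [trace[i : i + 120].std() for i in range(len(trace) - 120 + 1)]
        assert start == int(np.argmin(sds))

    def test_short_trace_is_an_input_error(self):
        with pytest.raises(InputError):
            stable_window(np.zeros(90), 120)


class TestRelativize:
    def _records(self, mapping, ind="q1", age="adult"):
        return [
            RespirometryRecord(ind, age, t, v, ewl_ml_min=None) for t, v in mapping.items()
        ]

    def test_definition(self):
        profiles, excluded = relativize(self._records({30.0: 20.0, 10.0: 30.0}))
        assert not excluded
        assert profiles[0].relative == {30.0: 1.0, 10.0: 1.5}

    def test_heat_fold_change(self):
        profiles, _ = relativize(self._records({30.0: 20.0, 40.0: 21.74}))
        assert profiles[0].relative[40.0] == pytest.approx(1.087, rel=1e-12)

    def test_thermoneutral_only_profile(self):
        profiles, _ = relativize(self._records({30.0: 20.0}))
        assert profiles[0].relative == {30.0: 1.0}

    def test_missing_thermoneutral_sample_excludes_individual(self):
        profiles, excluded = relativize(self._records({10.0: 30.0, 20.0: 25.0}))
        assert profiles == []
        assert excluded == [("q1", "adult", "missing_thermoneutral_measurement")]

    def test_scale_invariance(self):
        base, _ = relativize(self._records({30.0: 20.0, 10.0: 30.0, 40.0: 22.0}))
        scaled, _ = relativize(self._records({30.0: 60.0, 10.0: 90.0, 40.0: 66.0}))
        for t in base[0].relative:
            assert scaled[0].relative[t] == pytest.approx(base[0].relative[t], rel=1e-12)


class TestTraceReduction:
    def test_zero_noise_traces_recover_targets_exactly(self):
        noise = TraceNoiseSpec(feo2_sd=0.0, stable_feo2_sd=0.0, wvp_sd_kpa=0.0)
        (trace,) = generate_gas_traces([{"vo2": 12.0, "ewl": 0.05}], noise, seed=1)
        sample = reduce_trace(trace)
        assert sample.vo2_ml_min == pytest.approx(12.0, rel=1e-9)
        assert sample.ewl_ml_min == pytest.approx(0.05, rel=1e-9)

    def test_noisy_traces_recover_vo2_within_two_percent(self):
        noise = TraceNoiseSpec(feo2_sd=5e-4)
        traces = generate_gas_traces([{"vo2": 12.0}] * 10, noise, seed=2)
        values = [reduce_trace(t).vo2_ml_min for t in traces]
        assert np.allclose(values, 12.0, rtol=0.02)

    def test_stable_segment_is_found_at_configured_offset(self):
        noise = TraceNoiseSpec(stable_start_s=200.0)
        (trace,) = generate_gas_traces([{"vo2": 12.0}], noise, seed=3)
        start, stop = stable_window(trace)
        assert abs(start - 200) <= 2


def test_gas_trace_invariants():
    with pytest.raises(InputError):
        GasTrace(time_s=[0, 1, 1], FeO2=[0.2, 0.2, 0.2], FR_ml_min=4200.0)
    with pytest.raises(InputError):
        GasTrace(time_s=[0, 1, 2], FeO2=[0.2, 0.2, 0.2], FR_ml_min=-1.0)
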