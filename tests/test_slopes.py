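"""Cold slope model, heat slopes, repeatability and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from helpers import slope_frame
from quailtherm import ColdSlopeModel, conditional_repeatability, heat_slope
from quailtherm.errors import InputError, UnidentifiableModelError
from quailtherm.respirometry import MetabolicProfile
from quailtherm.slopes import (
    SlopeModelSpec,
    default_slope_spec,
    heat_slopes,
    null_repeatability_test,
    repeatability_at,
    scramble_identities,
)


def _profile(mapping, ind="q1"):
    return MetabolicProfile(ind, "adult", mapping, vo2_at_30=20.0)


class TestHeatSlope:
    @pytest.mark.parametrize(
        "rel40, expected", [(1.0, 0.0), (1.279, 0.0279), (1.087, 0.0087)]
    )
    def test_two_point_computation(self, rel40, expected):
        assert heat_slope(_profile({30.0: 1.0, 40.0: rel40})) == pytest.approx(
            expected, rel=1e-12
        )

    def test_linear_in_fold_change(self):
        slopes = [heat_slope(_profile({30.0: 1.0, 40.0: r})) for r in (1.1, 1.2, 1.3)]
        assert np.allclose(np.diff(slopes), 0.01)

    def test_missing_40c_is_excluded_and_logged(self):
        with pytest.raises(InputError):
            heat_slope(_profile({30.0: 1.0, 10.0: 1.4}))
        table, excluded = heat_slopes(
            [_profile({30.0: 1.0, 40.0: 1.1}, "a"), _profile({30.0: 1.0}, "b")]
        )
        assert list(table["id"]) == ["a"]
        assert excluded == [("b", "adult", "missing_40c_measurement")]


class TestColdSlopeModel:
    def test_noise_free_line_recovers_slope_exactly(self):
        rows = []
        for j in range(12):
            for t in (10.0, 20.0, 30.0):
                rows.append(
                    {"id": f"q{j}", "temperature_c": t, "relative": 1.0 - 0.02 * (t - 30.0)}
                )
        fit = ColdSlopeModel(pd.DataFrame(rows)).fit(chains=2, draws=400, seed=0)
        assert np.median(fit.beta1) == pytest.approx(-0.02, abs=2e-3)
        assert np.median(fit.sigma_v) < 3e-3

    def test_single_temperature_is_unidentifiable(self):
        rows = [
            {"id": f"q{j}", "temperature_c": 10.0, "relative": 1.3} for j in range(10)
        ]
        with pytest.raises(UnidentifiableModelError):
            ColdSlopeModel(pd.DataFrame(rows))

    def test_adult_pivot_discards_thermoneutral_rows(self):
        frame = slope_frame(8, -0.018, 0.005, {10.0: 0.15, 20.0: 0.10}, seed=5)
        model = ColdSlopeModel(frame, default_slope_spec("adult"))
        assert model.spec.pivot_c == 24.0
        assert set(model.frame["temperature_c"]) == {10.0, 20.0}

    def test_posterior_predictive_pins_pivot_at_one(self, cold_fit):
        pred = cold_fit.predict_relative(cold_fit.spec.pivot_c)
        assert np.all(pred == 1.0)

    def test_recovery_of_population_slope(self, cold_fit):
        q = np.quantile(cold_fit.beta1, [0.025, 0.975])
        assert q[0] <= -0.018 <= q[1]

    def test_individual_slope_identity(self, cold_fit):
        # slope draws are exactly beta1 + v per draw
        assert np.allclose(
            cold_fit.slope_draws, cold_fit.beta1[:, None] + cold_fit.v
        )
        table = cold_fit.individual_slopes()
        assert len(table) == len(cold_fit.ids)
        assert (table["slope_q2.5"] <= table["slope_median"]).all()


class TestRepeatability:
    def test_formula_direct_arithmetic(self):
        assert repeatability_at(np.array([0.01]), np.array([0.2]), 20.0) == pytest.approx(
            [0.5]
        )

    def test_zero_individual_variance_gives_zero(self):
        assert repeatability_at(np.array([0.0]), np.array([0.2]), 20.0) == 0.0

    def test_monotone_in_sigma_v(self):
        sv = np.linspace(0.0, 0.05, 20)
        r = repeatability_at(sv, np.full_like(sv, 0.2), 15.0)
        assert np.all(np.diff(r) > 0) and np.all((r >= 0) & (r <= 1))

    def test_average_over_temperatures_and_bounds(self, cold_fit):
        rep = conditional_repeatability(cold_fit)
        per_temp = np.stack(list(rep.per_temperature.values()))
        assert np.allclose(rep.draws, per_temp.mean(axis=0))
        assert np.all((rep.draws >= 0) & (rep.draws <= 1))
        assert rep.ci95[0] <= rep.median <= rep.ci95[1]


class TestNullComparison:
    def test_scrambling_preserves_marginals(self):
        frame = slope_frame(20, -0.018, 0.01, {10.0: 0.1, 20.0: 0.08}, seed=9)
        scrambled = scramble_identities(frame, np.random.default_rng(0))
        for t in (10.0, 20.0):
            a = np.sort(frame.loc[frame.temperature_c == t, "relative"])
            b = np.sort(scrambled.loc[scrambled.temperature_c == t, "relative"])
            assert np.array_equal(a, b)
        assert sorted(scrambled["id"]) == sorted(frame["id"])

    def test_strong_individual_structure_exceeds_null(self):
        frame = slope_frame(40, -0.018, 0.012, {10.0: 0.06, 20.0: 0.05}, seed=13)
        fit = ColdSlopeModel(frame).fit(chains=2, draws=500, seed=2)
        result = null_repeatability_test(
            frame, n_scrambles=2, seed=3, chains=2, draws=400, fit=fit
        )
        assert result.exceedance > 0.9
        assert result.null_draws is not None and result.bf is not None

    def test_no_structure_gives_intermediate_exceedance(self):
        frame = slope_frame(40, -0.018, 0.0, {10.0: 0.12, 20.0: 0.1}, seed=17)
        result = null_repeatability_test(
            frame, n_scrambles=2, seed=5, chains=2, draws=400
        )
        assert 0.05 < result.exceedance < 0.95

    def test_requires_at_least_one_scramble(self):
        frame = slope_frame(10, -0.018, 0.005, {10.0: 0.1, 20.0: 0.1}, seed=1)
        with pytest.raises(InputError):
            null_repeatability_test(frame, n_scrambles=0)


def test_spec_defaults_follow_age_class():
    assert default_slope_spec("juvenile").pivot_c == 30.0
    assert default_slope_spec("adult").pivot_c == 24.0
    spec = SlopeModelSpec()
    assert spec.prior_slope.family == "skew-normal"
    assert spec.prior_slope.params == (-0.018, 0.02, -2.5)
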