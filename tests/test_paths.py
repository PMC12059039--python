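"""Path system: recovery, partial R^2, predictions, effect fields, allometry."""

import numpy as np
import pandas as pd
import pytest

from quailtherm import PathModel, PhenotypeDistribution, default_path_spec, effect_field
from quailtherm.errors import InputError, ValidationError
from quailtherm.paths import allometry, selective_disappearance


class TestSpecAndValidation:
    def test_default_spec_has_all_equations_and_priors(self):
        spec = default_path_spec("juvenile", "heat_slope")
        assert set(spec.equations) == {"mass", "tarsus", "bill", "response"}
        terminal = spec.equations["response"]
        assert terminal.error_family == "student-t"
        assert terminal.batch_varying_sigma
        assert spec.center_response

    def test_ece_spec_keeps_natural_response_scale(self):
        spec = default_path_spec("adult", "ece")
        assert not spec.center_response
        assert spec.equations["response"].coef_priors["intercept"].params[0] == 0.75

    def test_missing_columns_and_bad_rearing_raise(self, adult_heat_path):
        table, _, _ = adult_heat_path
        with pytest.raises(ValidationError, match="columns"):
            PathModel(table.drop(columns=["bill"]), default_path_spec("adult", "heat_slope"))
        bad = table.copy()
        bad.loc[bad.index[0], "rearing"] = "hot"
        with pytest.raises(ValidationError, match="rearing"):
            PathModel(bad, default_path_spec("adult", "heat_slope"))


class TestFit:
    def test_mass_coefficient_recovers_generator_truth(self, adult_heat_path):
        # Single-dataset sanity check: the posterior sits within a few of its
        # own SDs of the generating value (systematic coverage is asserted
        # over replicate studies in the acceptance suite).
        _, truth, fit = adult_heat_path
        beta = fit.coefficient("response", "mass")
        z = (truth.config.heat_slope["adult"].mass - np.median(beta)) / beta.std()
        assert abs(z) < 4.0

    def test_prediction_at_mean_state_is_the_intercept(self, adult_heat_path):
        _, _, fit = adult_heat_path
        assert np.allclose(
            fit.predict_response({}, centered=True),
            fit.coefficient("response", "intercept"),
        )

    def test_sd_and_raw_units_agree(self, adult_heat_path):
        _, _, fit = adult_heat_path
        sd_mass = fit.model.sds["mass"]
        a = fit.predict_response({"mass": 1.0}, units="sd")
        b = fit.predict_response({"mass": sd_mass}, units="raw")
        assert np.allclose(a, b)

    def test_effect_size_antisymmetry_and_scale(self, adult_heat_path):
        _, _, fit = adult_heat_path
        up = fit.effect_size({"mass": 1.0})
        down = fit.effect_size({}, {"mass": 1.0})
        assert up.mean == pytest.approx(-down.mean, rel=1e-9)


@pytest.fixture(scope="module")
def single_predictor_fit():
    # response = beta*mass + noise, tuned so the population R^2 is 0.25;
    # every other predictor has a true effect of exactly zero.
    rng = np.random.default_rng(31)
    n = 400
    mass = rng.normal(210.0, 25.0, n)
    signal = 3.0e-4 * (mass - mass.mean())
    noise_sd = np.sqrt(3.0) * signal.std()
    frame = pd.DataFrame(
        {
            "id": [f"q{i}" for i in range(n)],
            "batch": rng.integers(1, 4, n),
            "rearing": np.resize(["cold", "mild", "warm"], n),
            "mass": mass,
            "tarsus": rng.normal(37.5, 1.5, n),
            "bill": rng.normal(15.7, 1.0, n),
            "heat_slope": signal + noise_sd * rng.standard_normal(n),
        }
    )
    return PathModel(frame, default_path_spec("adult", "heat_slope")).fit(
        equations=["response"], chains=2, draws=400, seed=3
    )


class TestPartialR2:
    def test_single_predictor_variance_ratio_oracle(self, single_predictor_fit):
        s = single_predictor_fit.partial_r2("mass")
        assert s.median == pytest.approx(0.25, abs=0.06)

    def test_null_predictor_has_near_zero_partial_r2(self, single_predictor_fit):
        s = single_predictor_fit.partial_r2("tarsus")
        assert s.median < 0.05
        assert s.ci95[0] >= 0.0  # floored at zero by definition


class TestEffectField:
    def test_field_matches_monte_carlo_integration(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        field = effect_field(fit, dist, grid=np.linspace(-5, 5, 161))
        pts = dist.rvs(400_000, np.random.default_rng(8))
        d = field.d_at(pts[:, 0], pts[:, 1])
        for thr, frac in field.rarity.items():
            assert frac == pytest.approx(float((d >= thr).mean()), abs=0.005)

    def test_modal_phenotype_has_zero_effect(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        field = effect_field(fit, dist)
        assert field.d_at(dist.mean[0], dist.mean[1]) == 0.0
        centre = len(field.mass_grid_sd) // 2
        assert field.d_mean[centre, centre] == pytest.approx(0.0, abs=1e-12)

    def test_rarity_monotone_in_threshold(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        field = effect_field(fit, dist, thresholds=(0.2, 0.5, 0.8, 1.2))
        values = [field.rarity[t] for t in (0.2, 0.5, 0.8, 1.2)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_narrow_grid_warns(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        with pytest.warns(RuntimeWarning, match="3 SD"):
            effect_field(fit, dist, grid=np.linspace(-2, 2, 21))

    def test_covariance_must_be_positive_definite(self):
        with pytest.raises(InputError):
            PhenotypeDistribution(mean=np.zeros(2), cov=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestAllometryAndDisappearance:
    def test_tarsus_allometry_recovers_configured_slope(self, adult_heat_path):
        table, truth, fit = adult_heat_path
        slope = fit.coefficient("tarsus", "mass")
        lo, hi = np.quantile(slope, [0.025, 0.975])
        assert lo <= truth.config.growth["tarsus"].mass_coef <= hi

    def test_uncorrelated_bill_has_weak_support(self, adult_heat_path):
        _, _, fit = adult_heat_path
        assert float(fit.coefficient_bf("bill", "mass")) < 3.0

    def test_allometry_wrapper_runs_without_response_column(self, adult_heat_path):
        table, _, _ = adult_heat_path
        result = allometry(
            table.drop(columns=["heat_slope"]), trait="tarsus", chains=2, draws=400, seed=1
        )
        assert result.summary.bf is not None
        assert result.slope_draws.size >= 800

    def test_no_removal_means_exactly_zero_change(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        field = effect_field(fit, dist)
        result = selective_disappearance(table, fit, field, threshold=50.0)
        assert result.removed_ids == ()
        assert np.all(result.delta_draws == 0.0) and result.mean == 0.0

    def test_removal_emptying_a_treatment_group_raises(self, adult_heat_path):
        table, _, fit = adult_heat_path
        dist = PhenotypeDistribution.from_data(table["mass"], table["tarsus"])
        field = effect_field(fit, dist)
        biased = table.copy()
        # Push every cold-reared bird into the removal region by moving it
        # along the fitted cost gradient, whatever its sign.
        cold = biased["rearing"] == "cold"
        biased.loc[cold, "mass"] += np.sign(field.coef_mass or 1.0) * 500.0
        biased.loc[cold, "tarsus"] += np.sign(field.coef_tarsus or 1.0) * 50.0
        with pytest.raises(InputError, match="empties"):
            selective_disappearance(biased, fit, field, threshold=0.05)


def test_student_t_with_huge_df_matches_normal_error(adult_heat_path):
    """With nu pinned very large the Student-t terminal fit is the normal fit."""
    import quailtherm.bayes as qb
    from quailtherm.paths import EquationSpec

    table, _, _ = adult_heat_path
    spec_t = default_path_spec("adult", "heat_slope")
    base = spec_t.equations["response"]
    eq_normal = EquationSpec(
        predictors=base.predictors,
        coef_priors=base.coef_priors,
        batch_scale_prior=base.batch_scale_prior,
        error_family="normal",
        sigma_prior=base.sigma_prior,
    )
    eq_t = EquationSpec(
        predictors=base.predictors,
        coef_priors=base.coef_priors,
        batch_scale_prior=base.batch_scale_prior,
        error_family="student-t",
        sigma_prior=base.sigma_prior,
        # Effectively fixed at 1000 degrees of freedom.
        nu_prior=qb.gamma_prior(1.0e6, 1.0e3),
    )
    results = {}
    for label, eq in (("normal", eq_normal), ("student", eq_t)):
        spec = default_path_spec("adult", "heat_slope")
        equations = dict(spec.equations)
        equations["response"] = eq
        from quailtherm.paths import PathSpec

        fit = PathModel(
            table, PathSpec("adult", "heat_slope", equations)
        ).fit(equations=["response"], chains=2, draws=500, seed=6)
        results[label] = fit.coefficient("response", "mass")
    m1, m2 = np.median(results["normal"]), np.median(results["student"])
    pooled_sd = np.std(results["normal"])
    assert abs(m1 - m2) < 0.5 * pooled_sd
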