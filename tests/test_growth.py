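"""Gompertz curve arithmetic and the hierarchical growth model."""

import numpy as np
import pandas as pd
import pytest

from quailtherm import GompertzModel, default_gompertz_spec, gompertz, treatment_contrast
from quailtherm.errors import ConfigurationError, InputError, UnidentifiableModelError


class TestCurve:
    def test_hand_computed_value(self):
        assert gompertz(250.0, 3.0, 0.5, 4.0) == pytest.approx(
            250.0 * np.exp(-3.0 * np.exp(-2.0)), rel=1e-12
        )

    def test_origin_and_asymptote(self):
        assert gompertz(250.0, 3.0, 0.5, 0.0) == pytest.approx(250.0 * np.exp(-3.0))
        assert gompertz(250.0, 3.0, 0.5, 1e4) == pytest.approx(250.0, rel=1e-12)

    def test_monotone_with_inflection_at_ln_b_over_c(self):
        t = np.linspace(0.0, 12.0, 500)
        y = gompertz(250.0, 3.0, 0.5, t)
        assert np.all(np.diff(y) > 0)
        growth_rate = np.gradient(y, t)
        t_inflection = t[np.argmax(growth_rate)]
        assert t_inflection == pytest.approx(np.log(3.0) / 0.5, abs=0.1)


def _growth_frame(seed=11, n_per_treatment=8, noise=1.0, delta_a=13.0, delta_c=0.06):
    rng = np.random.default_rng(seed)
    rows = []
    j = 0
    for rearing in ("cold", "mild", "warm"):
        a = 250.0 + {"cold": delta_a / 2, "mild": 0.0, "warm": -delta_a / 2}[rearing]
        c = 0.5 + {"cold": -delta_c / 2, "mild": 0.0, "warm": delta_c / 2}[rearing]
        for _ in range(n_per_treatment):
            u = 6.0 * rng.standard_normal()
            for t in range(9):
                sd = noise * (1.0 + 0.8 * np.log(t + 1.0))
                rows.append(
                    {
                        "id": f"q{j}",
                        "batch": 1 + j % 3,
                        "rearing": rearing,
                        "age_weeks": t,
                        "mass_g": gompertz(a, 3.0, c, t) + u + sd * rng.standard_normal(),
                    }
                )
            j += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def mass_fit():
    frame = _growth_frame()
    spec = default_gompertz_spec("mass", include_batch=False)
    return GompertzModel(frame, spec).fit(chains=2, draws=500, seed=2)


class TestFit:
    def test_near_noise_free_posteriors_concentrate_at_truth(self):
        frame = _growth_frame(seed=3, n_per_treatment=4, noise=0.05, delta_a=0.0, delta_c=0.0)
        spec = default_gompertz_spec("mass", include_batch=False)
        fit = GompertzModel(frame, spec).fit(chains=2, draws=400, seed=1)
        assert np.median(fit.draws.flat("a0")) == pytest.approx(250.0, rel=0.02)
        assert np.median(fit.draws.flat("b0")) == pytest.approx(3.0, rel=0.05)
        assert np.median(fit.draws.flat("c0")) == pytest.approx(0.5, rel=0.05)

    def test_treatment_contrasts_cover_truth(self, mass_fit):
        s_a, _ = treatment_contrast(mass_fit, "a", ("warm", "cold"))
        assert s_a.ci95[0] <= -13.0 <= s_a.ci95[1]
        s_c, _ = treatment_contrast(mass_fit, "c", ("warm", "cold"))
        assert s_c.ci95[0] <= 0.06 <= s_c.ci95[1]

    def test_contrast_with_itself_is_identically_zero(self, mass_fit):
        _, delta = treatment_contrast(mass_fit, "a", ("warm", "warm"))
        assert np.all(delta == 0.0)

    def test_absent_treatment_is_an_error(self, mass_fit):
        with pytest.raises(InputError):
            mass_fit.parameter_draws("a", "scorching")
        with pytest.raises(InputError):
            mass_fit.parameter_draws("asymptote", "warm")

    def test_residual_sd_grows_with_log_age_when_tau1_positive(self, mass_fit):
        sd = mass_fit.residual_sd(np.array([0.0, 2.0, 8.0]))
        positive_tau1 = mass_fit.draws.flat("tau1") > 0
        diffs = np.diff(sd, axis=1)
        assert np.all(diffs[positive_tau1] > 0)

    def test_predicted_curves_table_shape(self, mass_fit):
        table = mass_fit.predicted_curves(weeks=[0, 4, 8])
        assert len(table) == 9  # 3 treatments x 3 weeks
        assert (table["q2.5"] <= table["median"]).all()
        assert (table["median"] <= table["q97.5"]).all()


class TestPreconditions:
    def test_single_week_is_unidentifiable(self):
        frame = _growth_frame().query("age_weeks == 4")
        with pytest.raises(UnidentifiableModelError):
            GompertzModel(frame, default_gompertz_spec("mass", include_batch=False))

    def test_single_treatment_is_unidentifiable(self):
        frame = _growth_frame().query("rearing == 'mild'")
        with pytest.raises(UnidentifiableModelError):
            GompertzModel(frame, default_gompertz_spec("mass", include_batch=False))

    def test_unknown_trait_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            default_gompertz_spec("wing")


class TestStructure:
    def test_appendage_without_mass_covariate_reduces_to_mass_structure(self, tiny_study):
        """Dropping the mass covariate leaves exactly the mass-model blocks."""
        import dataclasses

        data, _ = tiny_study
        frame = data.morphometry.merge(data.individuals[["id", "batch", "rearing"]], on="id")
        spec_t = default_gompertz_spec("tarsus", include_batch=False)
        spec_reduced = dataclasses.replace(spec_t, prior_mass_coef=None)
        blocks_reduced = [b.name for b in GompertzModel(frame, spec_reduced)._blocks()]
        spec_m = default_gompertz_spec("mass", include_batch=False)
        blocks_mass = [b.name for b in GompertzModel(frame, spec_m)._blocks()]
        assert blocks_reduced == blocks_mass
        full = [b.name for b in GompertzModel(frame, spec_t)._blocks()]
        assert set(full) - set(blocks_reduced) == {"mass_coef"}

    def test_log_linear_sigma_link(self, tiny_study):
        data, _ = tiny_study
        frame = data.morphometry.merge(data.individuals[["id", "batch", "rearing"]], on="id")
        import dataclasses

        spec = dataclasses.replace(
            default_gompertz_spec("mass", include_batch=False), sigma_link="log-linear"
        )
        model = GompertzModel(frame, spec)
        sd = model._sigma_t({"tau0": np.array([2.0]), "tau1": np.array([0.5])}, np.array([0.0, 8.0]))
        assert sd[0, 0] == pytest.approx(2.0)
        assert sd[0, 1] == pytest.approx(np.exp(np.log(2.0) + 0.5 * np.log(9.0)))
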