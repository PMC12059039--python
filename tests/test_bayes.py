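"""Priors, the posterior-sampling contract, Savage-Dickey BFs, summaries, Cohen's D."""

import numpy as np
import pytest
from scipy import stats

from quailtherm import bayes as qb
from quailtherm.bayes import (
    BayesianModel,
    HierarchicalNormal,
    ParamBlock,
    cohens_d,
    sample_posterior,
    savage_dickey_bf,
    summarize,
)
from quailtherm.errors import InputError, SpecificationError


@pytest.mark.parametrize(
    "prior, grid",
    [
        (qb.normal(0.3, 2.0), np.linspace(-5, 5, 9)),
        (qb.skew_normal(-0.018, 0.02, -2.5), np.linspace(-0.1, 0.05, 9)),
        (qb.exponential(2.5), np.array([-0.5, 0.1, 1.0, 3.0])),
        (qb.gamma_prior(5.0, 1.0), np.array([-1.0, 0.5, 2.0, 10.0])),
        (qb.PriorSpec("student-t", (5.0, 0.1, 0.3)), np.linspace(-2, 2, 9)),
    ],
)
def test_prior_logpdf_matches_reference_density(prior, grid):
    assert np.allclose(prior.logpdf(grid), prior.dist.logpdf(grid), equal_nan=True)


def test_prior_validation():
    with pytest.raises(SpecificationError):
        qb.normal(0.0, -1.0)
    with pytest.raises(SpecificationError):
        qb.PriorSpec("cauchy", (0.0, 1.0))
    with pytest.raises(SpecificationError):
        qb.PriorSpec("normal", (0.0,))


def test_unpriored_parameter_is_a_specification_error():
    with pytest.raises(SpecificationError, match="prior"):
        ParamBlock("beta", None)


@pytest.fixture(scope="module")
def conjugate_fit():
    """Normal likelihood (sd 1), normal prior: posterior is closed-form."""
    rng = np.random.default_rng(0)
    y = rng.normal(1.5, 1.0, 20)
    prior = qb.normal(0.0, 2.0)

    def loglike(params):
        return -0.5 * np.sum((y[None, :] - params["mu"][:, None]) ** 2, axis=1)

    model = BayesianModel("conjugate", [ParamBlock("mu", prior)], loglike)
    draws = sample_posterior(model, chains=4, draws=1000, seed=3)
    var = 1.0 / (1.0 / 4.0 + 20.0)
    return prior, draws, var * y.sum(), np.sqrt(var)


def test_conjugate_posterior_matches_closed_form(conjugate_fit):
    _, draws, post_mean, post_sd = conjugate_fit
    mu = draws.flat("mu")
    mc_err = 3 * post_sd / np.sqrt(200)  # generous: draws are near-independent
    assert mu.mean() == pytest.approx(post_mean, abs=mc_err)
    assert mu.std() == pytest.approx(post_sd, rel=0.1)


def test_well_specified_model_passes_convergence_gates(conjugate_fit):
    _, draws, *_ = conjugate_fit
    assert 0.99 <= draws.rhat["mu"] <= 1.01
    assert draws.ess_ratio["mu"] > 0.75
    assert draws.healthy


def test_same_seed_gives_identical_draws(conjugate_fit):
    prior, draws, *_ = conjugate_fit
    rng = np.random.default_rng(0)
    y = rng.normal(1.5, 1.0, 20)

    def loglike(params):
        return -0.5 * np.sum((y[None, :] - params["mu"][:, None]) ** 2, axis=1)

    model = BayesianModel("conjugate", [ParamBlock("mu", prior)], loglike)
    again = sample_posterior(model, chains=4, draws=1000, seed=3)
    assert np.array_equal(draws.flat("mu"), again.flat("mu"))


def test_hierarchical_block_samples_and_shrinks():
    rng = np.random.default_rng(5)
    groups = rng.normal(0.0, 0.3, 4)
    y = groups[None, :] + 0.2 * rng.standard_normal((8, 4))

    def loglike(params):
        mu = params["group"]  # (W, 4)
        return -0.5 * np.sum((y[None, :, :] - mu[:, None, :]) ** 2, axis=(1, 2)) / 0.04

    model = BayesianModel(
        "hier",
        [
            ParamBlock("scale", qb.exponential(1.0, "log-sample")),
            ParamBlock("group", HierarchicalNormal("scale"), size=4),
        ],
        loglike,
    )
    draws = sample_posterior(model, chains=2, draws=500, seed=9)
    est = draws.flat("group").mean(axis=0)
    assert np.corrcoef(est, groups)[0, 1] > 0.9


class TestSavageDickey:
    def test_posterior_equal_to_prior_gives_bf_near_one(self):
        prior = qb.normal(0.0, 1.0)
        samples = prior.rvs(np.random.default_rng(1), 20000)
        bf = savage_dickey_bf(prior, samples)
        assert bf.value == pytest.approx(1.0, rel=0.1)

    def test_displaced_posterior_truncates_above_1000(self):
        prior = qb.normal(0.0, 1.0)
        samples = np.random.default_rng(2).normal(2.0, 0.5, 8000)
        bf = savage_dickey_bf(prior, samples)
        assert bf.truncated
        assert bf.display == "BF > 1000"
        assert float(bf) == 1000.0

    def test_concentrated_null_posterior_halves_the_bf(self):
        prior = qb.normal(0.0, 1.0)
        samples = np.random.default_rng(3).normal(0.0, 0.5, 20000)
        bf = savage_dickey_bf(prior, samples)
        expected = stats.norm(0, 1).pdf(0) / stats.norm(0, 0.5).pdf(0)
        assert bf.value == pytest.approx(expected, rel=0.05)

    def test_degenerate_draws_report_truncated_not_infinite_error(self):
        prior = qb.normal(0.0, 1.0)
        bf = savage_dickey_bf(prior, np.full(2000, 3.0))
        assert bf.truncated

    def test_prior_must_be_on_natural_scale(self):
        with pytest.raises(SpecificationError):
            savage_dickey_bf(qb.normal(0, 1, transform="log"), np.zeros(10))


class TestSummarize:
    def test_quantiles_of_1_to_100(self):
        with pytest.warns(RuntimeWarning, match="fewer than 1000"):
            s = summarize(np.arange(1.0, 101.0))
        assert s.median == 50.5
        assert s.ci95 == (pytest.approx(3.475), pytest.approx(97.525))
        assert s.ci50[0] > s.ci95[0] and s.ci50[1] < s.ci95[1]

    def test_constant_draws(self):
        with pytest.warns(RuntimeWarning):
            s = summarize(np.full(100, 7.0))
        assert s.median == 7.0 and s.ci95 == (7.0, 7.0)

    def test_negation_equivariance(self):
        x = np.random.default_rng(0).gamma(2.0, size=5000)
        assert summarize(-x).median == -summarize(x).median

    def test_draws_object_requires_parameter_name(self, conjugate_fit):
        _, draws, *_ = conjugate_fit
        with pytest.raises(InputError):
            summarize(draws)
        s = summarize(draws, "mu")
        assert np.isfinite(s.rhat) and s.n == draws.n_chains * draws.n_draws


class TestCohensD:
    def test_identical_states_give_zero(self):
        a = np.ones(100)
        assert cohens_d(a, a, 0.5).mean == 0.0

    def test_direct_arithmetic(self):
        a = np.full(100, 0.15)
        b = np.full(100, 0.10)
        assert cohens_d(a, b, 0.10).mean == pytest.approx(0.5, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b, sd = rng.normal(size=100), rng.normal(size=100), rng.gamma(2.0, size=100)
        assert cohens_d(a, b, sd).mean == pytest.approx(-cohens_d(b, a, sd).mean, rel=1e-12)

    def test_zero_reference_sd_is_missing(self):
        effect = cohens_d(np.ones(10), np.zeros(10), 0.0)
        assert effect.missing
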