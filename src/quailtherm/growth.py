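"""Hierarchical Gompertz growth models with rearing-treatment effects.

Each morphometric trait (body mass, tarsus length, bill length) follows a
Gompertz curve of developmental age t in weeks,

    y_ij ~ a_j * exp(-b_j * exp(-c_j * t)) [+ beta_m * masscov_ij] + u0_j + eps_ij,

where a is the asymptote, b the x-displacement and c the growth rate, and
each of (a, b, c) is a linear function of the cold- and warm-rearing
indicators (mild rearing is the reference) plus an exchangeable egg-batch
effect.  ``u0_j`` is an individual intercept (accounting for repeated
measures) and, for the appendage traits, ``masscov`` is the individual's
body mass standardised within its measurement week (mean-centred, in
within-week SD units), adjusting appendage lengths for size scaling.
Measurement error grows with age:

    sd(eps at age t) = tau0 + tau1 * ln(t + 1)

with tau0 constrained positive via a prior on its natural log (an
alternative fully log-linear link, sd = exp(log tau0 + tau1 ln(t+1)), is
available behind ``sigma_link="log-linear"``).

Individual intercepts enter the mean linearly and are marginalised
analytically (rank-one covariance update per individual), so MCMC only has
to explore the population-level parameters.  Growth rates are constrained
non-negative (no negative growth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bayes as qb
from .bayes import (
    BayesFactor,
    BayesianModel,
    Draws,
    ParamBlock,
    PosteriorSummary,
    PriorSpec,
    sample_posterior,
    savage_dickey_bf,
    summarize,
)
from .errors import ConfigurationError, InputError, UnidentifiableModelError

TRAIT_COLUMNS = {"mass": "mass_g", "tarsus": "tarsus_mm", "bill": "bill_mm"}
GOMPERTZ_PARAMETERS = ("a", "b", "c")
TREATMENTS = ("cold", "mild", "warm")


def gompertz(a, b, c, t):
    """Gompertz growth curve a * exp(-b * exp(-c * t)).

    ``a`` is the asymptote (trait units), ``b`` the dimensionless
    x-displacement and ``c`` the weekly growth rate; the inflection point
    sits at t = ln(b)/c.
    """
    return np.asarray(a) * np.exp(-np.asarray(b) * np.exp(-np.asarray(c) * np.asarray(t)))


@dataclass(frozen=True)
class GompertzSpec:
    """Priors for one trait's hierarchical Gompertz model."""

    trait: str
    prior_a: tuple[PriorSpec, PriorSpec, PriorSpec]  # intercept, cold, warm
    prior_b: tuple[PriorSpec, PriorSpec, PriorSpec]
    prior_c: tuple[PriorSpec, PriorSpec, PriorSpec]
    prior_batch_scale: Mapping[str, PriorSpec] = field(default_factory=dict)
    prior_individual_scale: PriorSpec = field(
        default_factory=lambda: qb.exponential(1.0, transform="log-sample")
    )
    prior_mass_coef: PriorSpec | None = None
    prior_log_tau0: PriorSpec = field(
        default_factory=lambda: qb.skew_normal(1.0, 0.5, -10.0, transform="log")
    )
    prior_tau1: PriorSpec = field(default_factory=lambda: qb.skew_normal(1.0, 0.5, 10.0))
    include_batch: bool = True
    sigma_link: str = "additive-sd"  # or "log-linear"

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_COLUMNS:
            raise ConfigurationError(f"unknown trait {self.trait!r}")
        if self.sigma_link not in ("additive-sd", "log-linear"):
            raise ConfigurationError(f"unknown sigma link {self.sigma_link!r}")
        if self.include_batch:
            missing = [p for p in GOMPERTZ_PARAMETERS if p not in self.prior_batch_scale]
            if missing:
                raise ConfigurationError(f"batch-scale priors missing for {missing}")


def default_gompertz_spec(trait: str, include_batch: bool = True) -> GompertzSpec:
    """The study's prior ledger for one trait's growth model."""
    if trait == "mass":
        return GompertzSpec(
            trait="mass",
            prior_a=(qb.normal(250, 25), qb.normal(7.5, 25), qb.normal(-7.5, 25)),
            prior_b=(qb.normal(3, 1), qb.normal(0, 0.5), qb.normal(0, 0.5)),
            prior_c=(qb.skew_normal(0.5, 0.1, 2.5), qb.normal(0, 0.2), qb.normal(0, 0.2)),
            prior_batch_scale={
                "a": qb.exponential(2.5),
                "b": qb.exponential(10.0),
                "c": qb.exponential(25.0),
            },
            prior_individual_scale=qb.exponential(0.5, "log-sample"),
            prior_log_tau0=qb.skew_normal(1.0, 0.5, -10.0, transform="log"),
            prior_tau1=qb.skew_normal(1.0, 0.5, 10.0),
            include_batch=include_batch,
        )
    if trait == "tarsus":
        return GompertzSpec(
            trait="tarsus",
            prior_a=(qb.normal(37.5, 2.5), qb.normal(-0.35, 2), qb.normal(0.35, 2)),
            prior_b=(qb.skew_normal(0.6, 0.5, 2.5), qb.normal(0, 0.5), qb.normal(0, 0.5)),
            prior_c=(qb.skew_normal(0.5, 0.1, 2.5), qb.normal(0, 0.25), qb.normal(0, 0.25)),
            prior_batch_scale={
                "a": qb.exponential(1.0),
                "b": qb.exponential(10.0),
                "c": qb.exponential(25.0),
            },
            prior_individual_scale=qb.exponential(1.5, "log-sample"),
            prior_mass_coef=qb.skew_normal(0.5, 0.15, 5.0),
            prior_log_tau0=qb.skew_normal(1.0, 0.5, 10.0, transform="log"),
            prior_tau1=qb.skew_normal(1.0, 0.5, 10.0),
            include_batch=include_batch,
        )
    if trait == "bill":
        return GompertzSpec(
            trait="bill",
            prior_a=(qb.normal(15.7, 2.5), qb.normal(-0.22, 1), qb.normal(0.22, 1)),
            prior_b=(qb.skew_normal(1.7, 0.5, 2.5), qb.normal(0, 0.5), qb.normal(0, 0.5)),
            prior_c=(qb.skew_normal(0.5, 0.1, 2.5), qb.normal(0, 0.25), qb.normal(0, 0.25)),
            prior_batch_scale={
                "a": qb.exponential(5.0),
                "b": qb.exponential(10.0),
                "c": qb.exponential(25.0),
            },
            prior_individual_scale=qb.exponential(2.5, "log-sample"),
            prior_mass_coef=qb.skew_normal(0.5, 0.15, 5.0),
            prior_log_tau0=qb.skew_normal(1.0, 0.25, 5.0, transform="log"),
            prior_tau1=qb.skew_normal(0.2, 0.25, 5.0),
            include_batch=include_batch,
        )
    raise ConfigurationError(f"unknown trait {trait!r}")


class GompertzModel:
    """Hierarchical Gompertz model of one trait's growth.

    ``data`` is a long table with columns ``id``, ``batch``, ``rearing``,
    ``age_weeks``, ``mass_g`` and (for appendages) the trait column; the
    within-week mass covariate for appendage models is computed from
    ``mass_g`` automatically.
    """

    def __init__(self, data: pd.DataFrame, spec: GompertzSpec) -> None:
        self.spec = spec
        column = TRAIT_COLUMNS[spec.trait]
        needed = ["id", "batch", "rearing", "age_weeks", column]
        if spec.trait != "mass":
            needed.append("mass_g")
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise InputError(f"growth data lacks columns {missing}")
        frame = data.loc[:, list(dict.fromkeys(needed))].dropna(subset=[column]).copy()
        if frame.empty:
            raise InputError("no observations for trait " + spec.trait)
        weeks = np.sort(frame["age_weeks"].unique())
        if weeks.size < 2:
            raise UnidentifiableModelError("a single observation week cannot identify a growth curve")
        treatments = sorted(frame["rearing"].unique())
        if len(treatments) < 2:
            raise UnidentifiableModelError("at least two rearing treatments are required")
        self.treatments = tuple(treatments)
        self.batch_levels = tuple(sorted(frame["batch"].unique()))
        # Within-week standardised mass covariate for appendage traits: an
        # individual's mass relative to the mean of its measurement week, in
        # SD units, so the coefficient is in trait units per within-week SD
        # of body mass.
        if spec.trait != "mass" and spec.prior_mass_coef is not None:
            week_mean = frame.groupby("age_weeks")["mass_g"].transform("mean")
            week_sd = frame.groupby("age_weeks")["mass_g"].transform("std").replace(0.0, 1.0)
            frame["masscov"] = ((frame["mass_g"] - week_mean) / week_sd).fillna(0.0)
        else:
            frame["masscov"] = 0.0
        self.frame = frame
        self.column = column
        self._build_arrays()

    def _build_arrays(self) -> None:
        frame = self.frame
        treat_idx = {t: k for k, t in enumerate(self.treatments)}
        batch_idx = {b: k for k, b in enumerate(self.batch_levels)}
        patterns: dict[tuple, dict] = {}
        self.ids = tuple(str(i) for i in pd.unique(frame["id"]))
        for ind, sub in frame.groupby("id", sort=False):
            sub = sub.sort_values("age_weeks")
            key = tuple(sub["age_weeks"])
            entry = patterns.setdefault(
                key, {"y": [], "cov": [], "combo": [], "ids": []}
            )
            entry["y"].append(sub[self.column].to_numpy(float))
            entry["cov"].append(sub["masscov"].to_numpy(float))
            entry["combo"].append(
                (treat_idx[sub["rearing"].iloc[0]], batch_idx[sub["batch"].iloc[0]])
            )
            entry["ids"].append(str(ind))
        # Enumerate the treatment x batch combinations actually present.
        combos: list[tuple[int, int]] = sorted(
            {c for e in patterns.values() for c in e["combo"]}
        )
        self.combos = combos
        combo_idx = {c: k for k, c in enumerate(combos)}
        self.combo_cold = np.array([self.treatments[c[0]] == "cold" for c in combos], float)
        self.combo_warm = np.array([self.treatments[c[0]] == "warm" for c in combos], float)
        self.combo_batch = np.array([c[1] for c in combos], int)
        self.groups = []
        for key, entry in patterns.items():
            self.groups.append(
                {
                    "t": np.asarray(key, float),
                    "Y": np.asarray(entry["y"]),
                    "cov": np.asarray(entry["cov"]),
                    "combo": np.array([combo_idx[c] for c in entry["combo"]], int),
                    "ids": entry["ids"],
                }
            )
        self.weeks = np.sort(frame["age_weeks"].unique()).astype(float)

    # -- model assembly ---------------------------------------------------
    def _blocks(self) -> list[ParamBlock]:
        s = self.spec
        blocks = []
        for par, priors in zip(GOMPERTZ_PARAMETERS, (s.prior_a, s.prior_b, s.prior_c)):
            blocks.append(ParamBlock(f"{par}0", priors[0]))
            blocks.append(ParamBlock(f"{par}_cold", priors[1]))
            blocks.append(ParamBlock(f"{par}_warm", priors[2]))
        if s.include_batch:
            n_batch = len(self.batch_levels)
            for par in GOMPERTZ_PARAMETERS:
                blocks.append(ParamBlock(f"batch_sd_{par}", s.prior_batch_scale[par]))
                blocks.append(ParamBlock(f"batch_z_{par}", qb.normal(0, 1), size=n_batch))
        if s.prior_mass_coef is not None and s.trait != "mass":
            blocks.append(ParamBlock("mass_coef", s.prior_mass_coef))
        blocks.append(ParamBlock("ind_sd", s.prior_individual_scale))
        blocks.append(ParamBlock("tau0", s.prior_log_tau0))
        blocks.append(ParamBlock("tau1", s.prior_tau1))
        return blocks

    def _combo_params(self, params: Mapping[str, np.ndarray], par: str) -> np.ndarray:
        """Parameter value per (treatment, batch) combination: (W, C)."""
        value = (
            params[f"{par}0"][:, None]
            + params[f"{par}_cold"][:, None] * self.combo_cold[None, :]
            + params[f"{par}_warm"][:, None] * self.combo_warm[None, :]
        )
        if self.spec.include_batch:
            u = params[f"batch_sd_{par}"][:, None] * params[f"batch_z_{par}"]
            value = value + u[:, self.combo_batch]
        return value

    def _sigma_t(self, params: Mapping[str, np.ndarray], t: np.ndarray) -> np.ndarray:
        log_age = np.log(t + 1.0)
        if self.spec.sigma_link == "log-linear":
            return np.exp(
                np.log(params["tau0"])[:, None] + params["tau1"][:, None] * log_age[None, :]
            )
        return params["tau0"][:, None] + params["tau1"][:, None] * log_age[None, :]

    def loglike(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        a = self._combo_params(params, "a")  # (W, C)
        b = self._combo_params(params, "b")
        c = self._combo_params(params, "c")
        w = a.shape[0]
        total = np.zeros(w)
        bad = (c <= 0).any(axis=1) | (a <= 0).any(axis=1)
        su2 = params["ind_sd"] ** 2
        mass_coef = params.get("mass_coef")
        for g in self.groups:
            t = g["t"]
            sd = self._sigma_t(params, t)  # (W, M)
            bad |= (sd <= 1e-6).any(axis=1)
            d = sd**2
            curve = a[:, :, None] * np.exp(
                -b[:, :, None] * np.exp(-c[:, :, None] * t[None, None, :])
            )  # (W, C, M)
            mu = curve[:, g["combo"], :]  # (W, J, M)
            if mass_coef is not None:
                mu = mu + mass_coef[:, None, None] * g["cov"][None, :, :]
            r = g["Y"][None, :, :] - mu
            rd = r / d[:, None, :]
            quad0 = np.sum(r * rd, axis=2)  # (W, J)
            s1 = np.sum(rd, axis=2)  # (W, J)
            a_sum = np.sum(1.0 / d, axis=1)  # (W,)
            denom = 1.0 + su2 * a_sum
            quad = quad0 - (su2 / denom)[:, None] * s1**2
            logdet = np.sum(np.log(d), axis=1) + np.log(denom)
            n_j = g["Y"].shape[0]
            total += -0.5 * (
                np.sum(quad, axis=1) + n_j * (logdet + t.size * np.log(2 * np.pi))
            )
        total[bad] = -np.inf
        return total

    def _data_init(self) -> dict:
        frame = self.frame
        y_late = frame.loc[frame["age_weeks"] == frame["age_weeks"].max(), self.column]
        a0 = float(y_late.mean())
        y0 = frame.loc[frame["age_weeks"] == frame["age_weeks"].min(), self.column].mean()
        b0 = float(np.clip(-np.log(max(y0 / a0, 1e-3)), 0.05, 6.0))
        init: dict = {"a0": a0, "b0": b0, "c0": 0.5}
        for par in GOMPERTZ_PARAMETERS:
            init[f"{par}_cold"] = 0.0
            init[f"{par}_warm"] = 0.0
            if self.spec.include_batch:
                init[f"batch_sd_{par}"] = self.spec.prior_batch_scale[par].median()
                init[f"batch_z_{par}"] = np.zeros(len(self.batch_levels))
        if self.spec.prior_mass_coef is not None and self.spec.trait != "mass":
            init["mass_coef"] = max(self.spec.prior_mass_coef.median(), 0.01)
        init["ind_sd"] = self.spec.prior_individual_scale.median()
        resid = float(frame.groupby("age_weeks")[self.column].std().mean())
        init["tau0"] = max(resid * 0.5 if np.isfinite(resid) else 1.0, 0.05)
        init["tau1"] = 0.3
        return init

    def fit(
        self, chains: int = 4, draws: int = 2000, seed: int = 0, **kwargs
    ) -> "GompertzResults":
        model = BayesianModel(
            f"gompertz_{self.spec.trait}", self._blocks(), self.loglike, init=self._data_init()
        )
        kwargs.setdefault("burn", max(500, 25 * model.dim))
        if self.spec.include_batch:
            # Batch-effect scales mix slowly (their posteriors hug zero when
            # batches are homogeneous); allow much deeper thinning.
            kwargs.setdefault("max_thin", 400)
        post = sample_posterior(model, chains=chains, draws=draws, seed=seed, **kwargs)
        return GompertzResults(self, post)


class GompertzResults:
    """Posterior of a hierarchical Gompertz growth fit."""

    def __init__(self, model: GompertzModel, draws: Draws) -> None:
        self.model = model
        self.spec = model.spec
        self.draws = draws

    @property
    def healthy(self) -> bool:
        return self.draws.healthy

    def parameter_draws(self, parameter: str, treatment: str) -> np.ndarray:
        """Population-level Gompertz parameter draws for one treatment."""
        if parameter not in GOMPERTZ_PARAMETERS:
            raise InputError(f"parameter must be one of {GOMPERTZ_PARAMETERS}")
        if treatment not in self.model.treatments:
            raise InputError(f"treatment {treatment!r} absent from the fit")
        value = self.draws.flat(f"{parameter}0").copy()
        if treatment == "cold":
            value += self.draws.flat(f"{parameter}_cold")
        elif treatment == "warm":
            value += self.draws.flat(f"{parameter}_warm")
        return value

    def asymptote_draws(self) -> dict[str, np.ndarray]:
        return {t: self.parameter_draws("a", t) for t in self.model.treatments}

    def residual_sd(self, t) -> np.ndarray:
        """Residual SD draws at age t weeks: tau0 + tau1 ln(t+1)."""
        return self.model._sigma_t(
            {"tau0": self.draws.flat("tau0"), "tau1": self.draws.flat("tau1")},
            np.atleast_1d(np.asarray(t, float)),
        )

    def predicted_curves(self, weeks: Sequence[float] | None = None) -> pd.DataFrame:
        """Median and 95% quantile interval of the population curve per treatment x week."""
        weeks = np.asarray(weeks if weeks is not None else self.model.weeks, float)
        rows = []
        for treat in self.model.treatments:
            a = self.parameter_draws("a", treat)[:, None]
            b = self.parameter_draws("b", treat)[:, None]
            c = self.parameter_draws("c", treat)[:, None]
            curve = a * np.exp(-b * np.exp(-c * weeks[None, :]))
            q = np.quantile(curve, [0.025, 0.5, 0.975], axis=0)
            for k, week in enumerate(weeks):
                rows.append(
                    {
                        "treatment": treat,
                        "age_weeks": week,
                        "median": q[1, k],
                        "q2.5": q[0, k],
                        "q97.5": q[2, k],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for par in GOMPERTZ_PARAMETERS:
                for suffix in ("0", "_cold", "_warm"):
                    name = f"{par}{suffix}"
                    s = summarize(self.draws, name)
                    rows.append(
                        {
                            "parameter": name,
                            "median": s.median,
                            "q2.5": s.ci95[0],
                            "q97.5": s.ci95[1],
                            "rhat": s.rhat,
                            "ess_ratio": s.ess_ratio,
                        }
                    )
            for name in ("ind_sd", "tau0", "tau1"):
                s = summarize(self.draws, name)
                rows.append(
                    {
                        "parameter": name,
                        "median": s.median,
                        "q2.5": s.ci95[0],
                        "q97.5": s.ci95[1],
                        "rhat": s.rhat,
                        "ess_ratio": s.ess_ratio,
                    }
                )
        return pd.DataFrame(rows)

    def treatment_contrast(
        self, parameter: str, pair: tuple[str, str] = ("warm", "cold")
    ) -> tuple[PosteriorSummary, np.ndarray]:
        return treatment_contrast(self, parameter, pair)

    def plot_curves(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.predicted_curves()
        for treat, sub in table.groupby("treatment"):
            ax.plot(sub["age_weeks"], sub["median"], label=treat)
            ax.fill_between(sub["age_weeks"], sub["q2.5"], sub["q97.5"], alpha=0.2)
        ax.set_xlabel("age (weeks)")
        ax.set_ylabel(self.model.column)
        ax.legend(title="rearing")
        return ax


def _effect_prior(spec: GompertzSpec, parameter: str, treatment: str) -> PriorSpec:
    priors = {"a": spec.prior_a, "b": spec.prior_b, "c": spec.prior_c}[parameter]
    return priors[1] if treatment == "cold" else priors[2]


def treatment_contrast(
    fit: GompertzResults, parameter: str, pair: tuple[str, str] = ("warm", "cold")
) -> tuple[PosteriorSummary, np.ndarray]:
    """Posterior contrast of a Gompertz parameter between two treatments.

    Returns the summary (with a Savage-Dickey Bayes factor against a zero
    difference, under the prior implied by the two rearing-effect priors)
    and the per-draw difference ``pair[0] - pair[1]``.
    """
    first, second = pair
    delta = fit.parameter_draws(parameter, first) - fit.parameter_draws(parameter, second)
    if first == second:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return summarize(delta), delta
    # Prior of the difference: difference of the (normal) rearing-effect
    # priors; the reference level contributes no prior term.
    mean, var = 0.0, 0.0
    for treat, sign in ((first, 1.0), (second, -1.0)):
        if treat == "mild":
            continue
        prior = _effect_prior(fit.spec, parameter, treat)
        mean += sign * float(prior.dist.mean())
        var += float(prior.dist.var())
    prior_diff = qb.normal(mean, float(np.sqrt(max(var, 1e-12))))
    bf = savage_dickey_bf(prior_diff, delta, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return summarize(delta, bf=bf), delta
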