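"""Bayesian path analyses of rearing and morphometry effects on thermoregulatory cost.

The path system is four linked regressions with a fixed DAG (rearing
treatments are exogenous; body mass mediates appendage lengths; all three
morphometric traits plus rearing predict the terminal response):

    mass     ~ b0 + b1*cold + b2*warm                                + u0[batch] + eps
    tarsus   ~ b0 + b1*cold + b2*warm + b3*mass                      + u0[batch] + eps
    bill     ~ b0 + b1*cold + b2*warm + b3*mass                      + u0[batch] + eps
    response ~ b0 + b1*cold + b2*warm + b3*mass + b4*tarsus + b5*bill + u0[batch] + eps

with residuals assumed uncorrelated between equations, so the system is
fitted equation by equation (exact under that assumption).  ``cold`` and
``warm`` are 0/1 indicators (mild rearing is the reference); continuous
predictors are mean-centred, as is the response when it is a metabolic
slope.  Egg-batch intercepts are exchangeable normal effects sampled
non-centred (u0 = batch_sd * z, z ~ N(0,1)) to avoid funnel geometry.  The
terminal error family is normal for cold slopes, Student-t (df estimated)
for heat slopes, and optionally batch-heteroscedastic on the log scale.

Each coefficient gets a Savage-Dickey Bayes factor against 0 under its own
prior.  Derived quantities: per-draw partial R^2 (variance-ratio reduction,
floored at 0), posterior predictions at phenotype states in SD units,
Cohen's D effect fields over a bivariate (mass, tarsus) phenotype
distribution with rarity fractions, mass-allometry slopes, and a
selective-disappearance contrast (allometry refitted after removing
high-cost phenotypes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from . import bayes as qb
from .bayes import (
    BayesFactor,
    BayesianModel,
    Draws,
    EffectSize,
    ParamBlock,
    PosteriorSummary,
    PriorSpec,
    cohens_d,
    sample_posterior,
    savage_dickey_bf,
    summarize,
)
from .errors import ConfigurationError, InputError, ValidationError

EQUATION_ORDER = ("mass", "tarsus", "bill", "response")
RESPONSES = ("cold_slope", "heat_slope", "ece")


@dataclass(frozen=True)
class EquationSpec:
    """Priors and error family for one equation of the path system."""

    predictors: tuple[str, ...]
    coef_priors: Mapping[str, PriorSpec]
    batch_scale_prior: PriorSpec
    error_family: str = "normal"  # or "student-t"
    sigma_prior: PriorSpec | None = None
    nu_prior: PriorSpec | None = None
    # (log sigma in batch 1, change to batch 2, change to batch 3)
    batch_sigma_priors: tuple[PriorSpec, PriorSpec, PriorSpec] | None = None

    def __post_init__(self) -> None:
        missing = [p for p in ("intercept", *self.predictors) if p not in self.coef_priors]
        if missing:
            raise ConfigurationError(f"equation lacks priors for {missing}")
        if self.error_family not in ("normal", "student-t"):
            raise ConfigurationError(f"unknown error family {self.error_family!r}")
        if self.sigma_prior is None and self.batch_sigma_priors is None:
            raise ConfigurationError("equation needs sigma_prior or batch_sigma_priors")
        if self.error_family == "student-t" and self.nu_prior is None:
            raise ConfigurationError("student-t error requires a nu prior")

    @property
    def batch_varying_sigma(self) -> bool:
        return self.batch_sigma_priors is not None


@dataclass(frozen=True)
class PathSpec:
    """Full specification of one path analysis (age class x terminal response)."""

    age_class: str
    response: str
    equations: Mapping[str, EquationSpec]
    center_response: bool = True

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ConfigurationError(f"unknown terminal response {self.response!r}")
        missing = [e for e in EQUATION_ORDER if e not in self.equations]
        if missing:
            raise ConfigurationError(f"path spec lacks equations {missing}")


_ALLOMETRY_PRIOR = ("skew-normal", (0.0, 0.25, 5.0))


def _morph_equations(age_class: str) -> dict[str, EquationSpec]:
    mass_on_appendage = PriorSpec(*_ALLOMETRY_PRIOR)
    if age_class == "juvenile":
        mass_eq = EquationSpec(
            predictors=("cold", "warm"),
            coef_priors={
                "intercept": qb.normal(0, 5),
                "cold": qb.normal(0, 15),
                "warm": qb.normal(0, 15),
            },
            batch_scale_prior=qb.exponential(1.5),
            sigma_prior=qb.exponential(0.15, "log-sample"),
        )
    else:
        mass_eq = EquationSpec(
            predictors=("cold", "warm"),
            coef_priors={
                "intercept": qb.normal(0, 10),
                "cold": qb.normal(0, 25),
                "warm": qb.normal(0, 25),
            },
            batch_scale_prior=qb.exponential(2.5),
            sigma_prior=qb.exponential(0.15, "log-sample"),
        )
    tarsus_eq = EquationSpec(
        predictors=("cold", "warm", "mass"),
        coef_priors={
            "intercept": qb.normal(0, 2.5),
            "cold": qb.normal(0, 2.5),
            "warm": qb.normal(0, 2.5),
            "mass": mass_on_appendage,
        },
        batch_scale_prior=qb.exponential(2.0),
        sigma_prior=qb.exponential(1.0, "log-sample"),
    )
    bill_eq = EquationSpec(
        predictors=("cold", "warm", "mass"),
        coef_priors={
            "intercept": qb.normal(0, 1),
            "cold": qb.normal(0, 0.5),
            "warm": qb.normal(0, 0.5),
            "mass": mass_on_appendage,
        },
        batch_scale_prior=qb.exponential(5.0),
        sigma_prior=qb.exponential(2.5, "log-sample"),
    )
    return {"mass": mass_eq, "tarsus": tarsus_eq, "bill": bill_eq}


def _terminal_equation(age_class: str, response: str) -> EquationSpec:
    if response == "cold_slope":
        return EquationSpec(
            predictors=("cold", "warm", "mass", "tarsus", "bill"),
            coef_priors={
                "intercept": qb.normal(0, 0.01),
                "cold": qb.normal(0, 0.025),
                "warm": qb.normal(0, 0.025),
                "mass": qb.normal(0, 1.0e-3),
                "tarsus": qb.normal(0, 2.5e-3),
                "bill": qb.normal(0, 1.0e-3),
            },
            batch_scale_prior=qb.exponential(50.0),
            sigma_prior=qb.exponential(10.0, "log-sample"),
        )
    if response == "heat_slope":
        if age_class == "juvenile":
            return EquationSpec(
                predictors=("cold", "warm", "mass", "tarsus", "bill"),
                coef_priors={
                    "intercept": qb.normal(0, 0.125),
                    "cold": qb.normal(0, 0.125),
                    "warm": qb.normal(0, 0.125),
                    "mass": qb.normal(0, 4.0e-3),
                    "tarsus": qb.normal(0, 0.015),
                    "bill": qb.normal(0, 0.06),
                },
                batch_scale_prior=qb.exponential(50.0),
                error_family="student-t",
                nu_prior=qb.gamma_prior(5.0, 1.0, "log-sample"),
                batch_sigma_priors=(
                    qb.normal(-3.0, 1.5),
                    qb.normal(0.0, 0.5),
                    qb.normal(1.0, 1.5),
                ),
            )
        return EquationSpec(
            predictors=("cold", "warm", "mass", "tarsus", "bill"),
            coef_priors={
                "intercept": qb.normal(0, 0.1),
                "cold": qb.normal(0, 0.1),
                "warm": qb.normal(0, 0.1),
                "mass": qb.normal(0, 2.5e-3),
                "tarsus": qb.normal(0, 0.03),
                "bill": qb.normal(0, 0.1),
            },
            batch_scale_prior=qb.exponential(50.0),
            error_family="student-t",
            sigma_prior=qb.exponential(10.0, "log-sample"),
            nu_prior=qb.gamma_prior(10.0, 1.0, "log-sample"),
        )
    # Evaporative cooling efficiency: natural (uncentred) response scale.
    if age_class == "juvenile":
        return EquationSpec(
            predictors=("cold", "warm", "mass", "tarsus", "bill"),
            coef_priors={
                "intercept": qb.normal(0.5, 0.2),
                "cold": qb.normal(0, 0.25),
                "warm": qb.normal(0, 0.25),
                "mass": qb.normal(0, 0.01),
                "tarsus": qb.normal(0, 0.1),
                "bill": qb.normal(0, 0.075),
            },
            batch_scale_prior=qb.exponential(15.0),
            batch_sigma_priors=(
                qb.normal(-2.0, 1.0),
                qb.normal(0.0, 0.5),
                qb.normal(1.0, 1.0),
            ),
        )
    return EquationSpec(
        predictors=("cold", "warm", "mass", "tarsus", "bill"),
        coef_priors={
            "intercept": qb.normal(0.75, 0.2),
            "cold": qb.normal(0, 0.25),
            "warm": qb.normal(0, 0.25),
            "mass": qb.normal(0, 0.01),
            "tarsus": qb.normal(0, 0.1),
            "bill": qb.normal(0, 0.15),
        },
        batch_scale_prior=qb.exponential(15.0),
        sigma_prior=qb.exponential(5.0, "log-sample"),
    )


def default_path_spec(age_class: str, response: str) -> PathSpec:
    """The study's prior ledger for one age class and terminal response."""
    if age_class not in ("juvenile", "adult"):
        raise ConfigurationError(f"unknown age class {age_class!r}")
    equations = _morph_equations(age_class)
    equations["response"] = _terminal_equation(age_class, response)
    return PathSpec(
        age_class=age_class,
        response=response,
        equations=equations,
        center_response=response != "ece",
    )


class PathModel:
    """Four-equation Bayesian path analysis, fitted equation by equation.

    ``data`` needs columns ``id``, ``batch``, ``rearing``, ``mass``,
    ``tarsus``, ``bill`` and the response column named by ``spec.response``.
    Only complete cases enter the fit.
    """

    def __init__(self, data: pd.DataFrame, spec: PathSpec) -> None:
        self.spec = spec
        needed = ["id", "batch", "rearing", "mass", "tarsus", "bill", spec.response]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValidationError(f"path data lacks columns {missing}")
        frame = data.loc[:, needed].dropna().reset_index(drop=True)
        if frame.empty:
            raise ValidationError("no complete cases for the path system")
        if frame["batch"].isna().any():
            raise ValidationError("missing batch labels")
        bad = set(frame["rearing"]) - {"cold", "mild", "warm"}
        if bad:
            raise ValidationError(f"rearing must be cold/mild/warm, found {sorted(bad)}")
        self.frame = frame
        self.n = len(frame)
        self.batch_levels = tuple(sorted(frame["batch"].unique()))
        self.batch_index = frame["batch"].map(
            {b: i for i, b in enumerate(self.batch_levels)}
        ).to_numpy()
        self.cold = (frame["rearing"] == "cold").to_numpy(float)
        self.warm = (frame["rearing"] == "warm").to_numpy(float)
        self.means = {c: float(frame[c].mean()) for c in ("mass", "tarsus", "bill")}
        self.sds = {c: float(frame[c].std(ddof=1)) for c in ("mass", "tarsus", "bill")}
        self.centered = {
            c: frame[c].to_numpy() - self.means[c] for c in ("mass", "tarsus", "bill")
        }
        resp = frame[spec.response].to_numpy(float)
        self.response_mean = float(resp.mean()) if spec.center_response else 0.0
        self.response_values = resp - self.response_mean

    def _design(self, equation: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        eq = self.spec.equations[equation]
        columns = {"cold": self.cold, "warm": self.warm}
        for trait in ("mass", "tarsus", "bill"):
            columns[trait] = self.centered[trait]
        names = ["intercept", *eq.predictors]
        X = np.column_stack(
            [np.ones(self.n)] + [columns[p] for p in eq.predictors]
        )
        if equation == "response":
            y = self.response_values
        else:
            y = self.centered[equation]
        return X, y, names

    def _equation_model(self, equation: str) -> tuple[BayesianModel, list[str]]:
        eq = self.spec.equations[equation]
        X, y, names = self._design(equation)
        bidx = self.batch_index
        n_batch = len(self.batch_levels)
        blocks = [ParamBlock(name, eq.coef_priors[name]) for name in names]
        blocks.append(ParamBlock("batch_sd", eq.batch_scale_prior))
        blocks.append(ParamBlock("batch_z", qb.normal(0.0, 1.0), size=n_batch))
        if eq.batch_varying_sigma:
            p1, p2, p3 = eq.batch_sigma_priors
            blocks.append(
                ParamBlock("sigma_b1", PriorSpec(p1.family, p1.params, transform="log"))
            )
            if n_batch > 1:
                blocks.append(ParamBlock("dsigma_b2", p2))
            if n_batch > 2:
                blocks.append(ParamBlock("dsigma_b3", p3))
        else:
            blocks.append(ParamBlock("sigma", eq.sigma_prior))
        if eq.error_family == "student-t":
            blocks.append(ParamBlock("nu", eq.nu_prior))

        def loglike(params: Mapping[str, np.ndarray]) -> np.ndarray:
            B = np.column_stack([params[name] for name in names])  # (W, p)
            mu = B @ X.T  # (W, n)
            u0 = params["batch_sd"][:, None] * params["batch_z"]  # (W, n_batch)
            r = y[None, :] - mu - u0[:, bidx]
            if eq.batch_varying_sigma:
                log_s1 = np.log(params["sigma_b1"])
                log_sig = [log_s1]
                if n_batch > 1:
                    log_sig.append(log_s1 + params["dsigma_b2"])
                if n_batch > 2:
                    log_sig.append(log_s1 + params["dsigma_b3"])
                log_sigma_b = np.column_stack(log_sig)  # (W, n_batch)
                sig = np.exp(log_sigma_b)[:, bidx]
            else:
                sig = params["sigma"][:, None]
            sig = np.maximum(sig, 1e-8)
            z2 = (r / sig) ** 2
            if eq.error_family == "student-t":
                nu = params["nu"][:, None]
                ll = (
                    gammaln((nu + 1) / 2)
                    - gammaln(nu / 2)
                    - 0.5 * np.log(nu * np.pi)
                    - np.log(sig)
                    - (nu + 1) / 2 * np.log1p(z2 / nu)
                )
            else:
                ll = -0.5 * z2 - np.log(sig) - 0.5 * np.log(2 * np.pi)
            return ll.sum(axis=1)

        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_sd = max(float(np.std(y - X @ beta_hat)), 1e-4)
        init: dict = {name: beta_hat[i] for i, name in enumerate(names)}
        init["batch_sd"] = self.spec.equations[equation].batch_scale_prior.median()
        init["batch_z"] = np.zeros(n_batch)
        if eq.batch_varying_sigma:
            init["sigma_b1"] = resid_sd
            if n_batch > 1:
                init["dsigma_b2"] = 0.0
            if n_batch > 2:
                init["dsigma_b3"] = 0.0
        else:
            init["sigma"] = resid_sd
        if eq.error_family == "student-t":
            init["nu"] = eq.nu_prior.median()
        model = BayesianModel(f"path_{self.spec.response}_{equation}", blocks, loglike, init=init)
        return model, names

    def fit(
        self,
        equations: Sequence[str] | None = None,
        chains: int = 4,
        draws: int = 2000,
        seed: int = 0,
        **kwargs,
    ) -> "PathResults":
        """Sample the posterior of each equation; returns :class:`PathResults`."""
        equations = list(equations) if equations is not None else list(EQUATION_ORDER)
        fits: dict[str, Draws] = {}
        coef_names: dict[str, list[str]] = {}
        for k, equation in enumerate(equations):
            model, names = self._equation_model(equation)
            fits[equation] = sample_posterior(
                model, chains=chains, draws=draws, seed=int(np.uint32(seed) + 13 * k), **kwargs
            )
            coef_names[equation] = names
        return PathResults(self, fits, coef_names)


class PathResults:
    """Posterior draws and derived quantities of a fitted path system."""

    def __init__(
        self,
        model: PathModel,
        fits: dict[str, Draws],
        coef_names: dict[str, list[str]],
    ) -> None:
        self.model = model
        self.spec = model.spec
        self.fits = fits
        self.coef_names = coef_names

    @property
    def healthy(self) -> bool:
        return all(d.healthy for d in self.fits.values())

    def coefficient(self, equation: str, name: str) -> np.ndarray:
        return self.fits[equation].flat(name)

    def coefficient_bf(self, equation: str, name: str) -> BayesFactor:
        prior = self.spec.equations[equation].coef_priors[name]
        return savage_dickey_bf(prior, self.coefficient(equation, name), 0.0)

    def batch_effects(self, equation: str) -> np.ndarray:
        d = self.fits[equation]
        return d.flat("batch_sd")[:, None] * d.flat("batch_z")

    def residual_sigma(self, equation: str) -> np.ndarray:
        """Per-draw residual SD; batch-heteroscedastic equations return the
        observation-count-weighted root mean square across batches."""
        eq = self.spec.equations[equation]
        d = self.fits[equation]
        if not eq.batch_varying_sigma:
            return d.flat("sigma")
        log_s1 = np.log(d.flat("sigma_b1"))
        logs = [log_s1]
        if len(self.model.batch_levels) > 1:
            logs.append(log_s1 + d.flat("dsigma_b2"))
        if len(self.model.batch_levels) > 2:
            logs.append(log_s1 + d.flat("dsigma_b3"))
        sig_b = np.exp(np.column_stack(logs))  # (N, n_batch)
        counts = np.bincount(self.model.batch_index, minlength=sig_b.shape[1])
        w = counts / counts.sum()
        return np.sqrt((sig_b**2 * w[None, :]).sum(axis=1))

    def _error_variance(self, equation: str) -> np.ndarray:
        eq = self.spec.equations[equation]
        var = self.residual_sigma(equation) ** 2
        if eq.error_family == "student-t":
            nu = np.maximum(self.fits[equation].flat("nu"), 2.2)
            var = var * nu / (nu - 2.0)
        return var

    def linear_predictor(self, equation: str) -> np.ndarray:
        """Fitted values (draws x observations), including batch effects."""
        X, _, names = self.model._design(equation)
        B = np.column_stack([self.coefficient(equation, n) for n in names])
        mu = B @ X.T
        mu += self.batch_effects(equation)[:, self.model.batch_index]
        return mu

    def reference_sd(self, equation: str = "response") -> np.ndarray:
        """Per-draw posterior-predictive SD of the equation's response.

        Combines the spread of fitted values across the analysed individuals
        with the residual variance; this is the denominator used for
        posterior-prediction Cohen's D.
        """
        mu = self.linear_predictor(equation)
        return np.sqrt(mu.var(axis=1) + self._error_variance(equation))

    def predict_response(
        self,
        state: Mapping[str, float] | None = None,
        equation: str = "response",
        units: str = "sd",
        centered: bool = False,
    ) -> np.ndarray:
        """Posterior prediction draws at a phenotype/rearing state.

        ``state`` maps predictor names to values — SD units of the analysis
        subset for continuous traits by default (``units="raw"`` for natural
        units as deviations from the subset mean), 0/1 for ``cold``/``warm``.
        Unlisted predictors are held at their means (0).  At the all-mean
        state the prediction equals the intercept draws exactly.
        """
        state = dict(state or {})
        eq_names = self.coef_names[equation]
        pred = self.coefficient(equation, "intercept").copy()
        for name, value in state.items():
            if name not in eq_names:
                raise InputError(f"{name!r} is not a predictor of equation {equation!r}")
            x = float(value)
            if units == "sd" and name in ("mass", "tarsus", "bill"):
                x *= self.model.sds[name]
            pred = pred + self.coefficient(equation, name) * x
        if not centered and equation == "response":
            pred = pred + self.model.response_mean
        return pred

    def effect_size(
        self,
        state_a: Mapping[str, float],
        state_b: Mapping[str, float] | None = None,
        equation: str = "response",
        units: str = "sd",
    ) -> EffectSize:
        """Cohen's D between two states, scaled by the reference SD."""
        a = self.predict_response(state_a, equation, units, centered=True)
        b = self.predict_response(state_b or {}, equation, units, centered=True)
        return cohens_d(a, b, self.reference_sd(equation))

    def partial_r2(self, predictor: str, equation: str = "response") -> PosteriorSummary:
        """Per-draw partial R^2 of one predictor, floored at zero.

        Computed as the proportional reduction in residual variance when the
        predictor's contribution is added back:
        (V_without - V_with) / V_without per draw.
        """
        X, y, names = self.model._design(equation)
        if predictor not in names:
            raise InputError(f"{predictor!r} is not a predictor of equation {equation!r}")
        mu = self.linear_predictor(equation)
        r_full = y[None, :] - mu
        col = X[:, names.index(predictor)]
        r_reduced = r_full + self.coefficient(equation, predictor)[:, None] * col[None, :]
        v_full = r_full.var(axis=1)
        v_reduced = r_reduced.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr2 = np.where(v_reduced > 0, 1.0 - v_full / v_reduced, 0.0)
        pr2 = np.maximum(pr2, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return summarize(pr2)

    def summary(self, equation: str | None = None) -> pd.DataFrame:
        return self.coefficient_table(equation)

    def coefficient_table(self, equation: str | None = None) -> pd.DataFrame:
        """Coefficient, median, 50% and 95% quantile intervals, and BF per row."""
        equations = [equation] if equation else list(self.fits)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for eq in equations:
                for name in self.coef_names[eq]:
                    s = summarize(self.fits[eq], name)
                    bf = self.coefficient_bf(eq, name)
                    rows.append(
                        {
                            "equation": eq,
                            "coefficient": name,
                            "median": s.median,
                            "q25": s.ci50[0],
                            "q75": s.ci50[1],
                            "q2.5": s.ci95[0],
                            "q97.5": s.ci95[1],
                            "bf": float(bf),
                            "bf_display": bf.display,
                            "rhat": s.rhat,
                            "ess_ratio": s.ess_ratio,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Bivariate normal distribution of (mass, tarsus) phenotypes."""

    mean: np.ndarray  # (2,) mass g, tarsus mm
    cov: np.ndarray  # (2, 2)

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise InputError("covariance must be a symmetric 2x2 matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise InputError("phenotype covariance must be positive-definite") from None

    @classmethod
    def from_data(cls, mass: np.ndarray, tarsus: np.ndarray) -> "PhenotypeDistribution":
        xy = np.column_stack([np.asarray(mass, float), np.asarray(tarsus, float)])
        xy = xy[~np.isnan(xy).any(axis=1)]
        return cls(mean=xy.mean(axis=0), cov=np.cov(xy.T))

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def pdf(self, points: np.ndarray) -> np.ndarray:
        return stats.multivariate_normal(self.mean, self.cov).pdf(points)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=n)


@dataclass
class EffectField:
    """Mean Cohen's D over a (mass, tarsus) grid, relative to the modal phenotype.

    For a linear terminal equation the mean-D surface is itself linear:
    D(dm, dt) = a*dm + b*dt in raw trait deviations from the mode, with
    a = E[beta_mass / SD_ref] and b = E[beta_tarsus / SD_ref] over posterior
    draws.  ``rarity`` maps each threshold to the probability mass of the
    phenotype distribution in the region where D exceeds it in the cost
    direction (higher response = higher thermoregulatory cost).
    """

    mass_grid_sd: np.ndarray
    tarsus_grid_sd: np.ndarray
    d_mean: np.ndarray  # (len(mass), len(tarsus))
    rarity: dict[float, float]
    coef_mass: float  # E[beta_mass / SD_ref], per gram
    coef_tarsus: float  # E[beta_tarsus / SD_ref], per mm
    distribution: PhenotypeDistribution
    thresholds: tuple[float, ...] = (0.5, 0.8)

    def d_at(self, mass: np.ndarray, tarsus: np.ndarray, units: str = "raw") -> np.ndarray:
        """Mean Cohen's D at arbitrary phenotypes (raw units or SD units)."""
        mass = np.asarray(mass, float)
        tarsus = np.asarray(tarsus, float)
        if units == "sd":
            mass = self.distribution.mean[0] + mass * self.distribution.sds[0]
            tarsus = self.distribution.mean[1] + tarsus * self.distribution.sds[1]
        dm = mass - self.distribution.mean[0]
        dt = tarsus - self.distribution.mean[1]
        return self.coef_mass * dm + self.coef_tarsus * dt

    def plot(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m, t = np.meshgrid(self.mass_grid_sd, self.tarsus_grid_sd, indexing="ij")
        cs = ax.contourf(m, t, self.d_mean, levels=21, cmap="RdBu_r")
        ax.figure.colorbar(cs, ax=ax, label="mean Cohen's D vs modal phenotype")
        ax.set_xlabel("body mass (SD units)")
        ax.set_ylabel("tarsus length (SD units)")
        return ax


def effect_field(
    fit: PathResults,
    dist: PhenotypeDistribution,
    grid: np.ndarray | None = None,
    thresholds: Sequence[float] = (0.5, 0.8),
    direction: str = "cost",
) -> EffectField:
    """Cohen's D field of combined mass and tarsus effects on the response.

    D at each grid node is the posterior-prediction effect size of that
    phenotype versus the modal (mean) phenotype, holding bill length and
    rearing at their means.  Rarity fractions integrate the fitted bivariate
    normal over the region where mean D exceeds each threshold in the cost
    direction (``direction="benefit"`` flips the sign convention).
    """
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 81)
    grid = np.asarray(grid, float)
    if grid.min() > -3.0 or grid.max() < 3.0:
        warnings.warn("effect-field grid does not cover +/-3 SD", RuntimeWarning, stacklevel=2)
    sd_ref = fit.reference_sd("response")
    beta_m = fit.coefficient("response", "mass")
    beta_t = fit.coefficient("response", "tarsus")
    coef_mass = float(np.mean(beta_m / sd_ref))
    coef_tarsus = float(np.mean(beta_t / sd_ref))
    sds = dist.sds
    dm = grid * sds[0]
    dt = grid * sds[1]
    d_mean = coef_mass * dm[:, None] + coef_tarsus * dt[None, :]

    sign = 1.0 if direction == "cost" else -1.0
    mass_raw = dist.mean[0] + dm
    tarsus_raw = dist.mean[1] + dt
    mg, tg = np.meshgrid(mass_raw, tarsus_raw, indexing="ij")
    pdf = dist.pdf(np.dstack([mg, tg]))
    cell = np.trapezoid(np.trapezoid(pdf, tarsus_raw, axis=1), mass_raw)
    rarity: dict[float, float] = {}
    for thr in thresholds:
        inside = pdf * (sign * d_mean >= thr)
        mass_frac = np.trapezoid(np.trapezoid(inside, tarsus_raw, axis=1), mass_raw)
        rarity[float(thr)] = float(mass_frac / cell) if cell > 0 else 0.0
    return EffectField(
        mass_grid_sd=grid,
        tarsus_grid_sd=grid,
        d_mean=d_mean,
        rarity=rarity,
        coef_mass=coef_mass,
        coef_tarsus=coef_tarsus,
        distribution=dist,
        thresholds=tuple(float(t) for t in thresholds),
    )


@dataclass
class AllometryResult:
    """Posterior slope of an appendage on body mass (mm per g), with BF."""

    trait: str
    slope_draws: np.ndarray
    summary: PosteriorSummary
    bf: BayesFactor
    fit: PathResults


def allometry(
    data: pd.DataFrame,
    trait: str = "tarsus",
    spec: PathSpec | None = None,
    chains: int = 4,
    draws: int = 2000,
    seed: int = 0,
    **kwargs,
) -> AllometryResult:
    """Allometric slope of tarsus or bill length on body mass.

    Uses the appendage equation of the path system (rearing-adjusted, batch
    effects included); the slope is the mass coefficient in mm per g.
    """
    if trait not in ("tarsus", "bill"):
        raise InputError("allometry trait must be 'tarsus' or 'bill'")
    if spec is None:
        # Response values are irrelevant for the appendage equation; any
        # placeholder column works.
        spec = default_path_spec("adult", "heat_slope")
    frame = data.copy()
    if spec.response not in frame.columns:
        frame[spec.response] = 0.0
    model = PathModel(frame, spec)
    fit = model.fit(equations=[trait], chains=chains, draws=draws, seed=seed, **kwargs)
    slope = fit.coefficient(trait, "mass")
    bf = fit.coefficient_bf(trait, "mass")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = summarize(slope, bf=bf)
    return AllometryResult(trait=trait, slope_draws=slope, summary=s, bf=bf, fit=fit)


@dataclass
class SelectiveDisappearanceResult:
    """Change in the mass-allometry slope after removing high-cost phenotypes."""

    removed_ids: tuple[str, ...]
    delta_draws: np.ndarray
    mean: float
    sd: float
    bf: BayesFactor | None
    slope_with: np.ndarray
    slope_without: np.ndarray


def selective_disappearance(
    data: pd.DataFrame,
    fit: PathResults,
    field: EffectField,
    threshold: float = 0.5,
    trait: str = "tarsus",
    spec: PathSpec | None = None,
    chains: int = 4,
    draws: int = 2000,
    seed: int = 0,
    **kwargs,
) -> SelectiveDisappearanceResult:
    """Simulate selective disappearance of thermally costly phenotypes.

    Individuals whose (mass, tarsus) phenotype has mean Cohen's D at or above
    ``threshold`` (cost direction) are removed and the allometry slope is
    refitted; the contrast is slope(with) - slope(without), reported as mean
    +/- SD with a Savage-Dickey Bayes factor on the difference.
    """
    frame = data.dropna(subset=["mass", "tarsus"]).reset_index(drop=True)
    d_values = field.d_at(frame["mass"].to_numpy(), frame["tarsus"].to_numpy())
    flagged = d_values >= threshold
    removed = tuple(str(i) for i in frame.loc[flagged, "id"])
    slope_with = fit.coefficient(trait, "mass")
    if not flagged.any():
        zeros = np.zeros_like(slope_with)
        return SelectiveDisappearanceResult(
            removed_ids=(),
            delta_draws=zeros,
            mean=0.0,
            sd=0.0,
            bf=None,
            slope_with=slope_with,
            slope_without=slope_with.copy(),
        )
    reduced = frame.loc[~flagged]
    for level in ("cold", "mild", "warm"):
        if level in set(frame["rearing"]) and level not in set(reduced["rearing"]):
            raise InputError(f"removal empties the {level!r} rearing group")
    result = allometry(
        reduced, trait=trait, spec=spec or fit.spec, chains=chains, draws=draws, seed=seed, **kwargs
    )
    slope_without = result.slope_draws
    n = min(slope_with.size, slope_without.size)
    delta = slope_with[:n] - slope_without[:n]
    prior = fit.spec.equations[trait].coef_priors["mass"]
    prior_diff = qb.normal(0.0, float(np.sqrt(2.0) * prior.dist.std()))
    bf = savage_dickey_bf(prior_diff, delta, 0.0)
    return SelectiveDisappearanceResult(
        removed_ids=removed,
        delta_draws=delta,
        mean=float(delta.mean()),
        sd=float(delta.std()),
        bf=bf,
        slope_with=slope_with,
        slope_without=slope_without,
    )


def partial_r2(fit: PathResults, predictor: str, equation: str = "response") -> PosteriorSummary:
    """Module-level convenience wrapper; see :meth:`PathResults.partial_r2`."""
    return fit.partial_r2(predictor, equation)


def predict_response(fit: PathResults, state: Mapping[str, float], **kwargs) -> np.ndarray:
    """Module-level convenience wrapper; see :meth:`PathResults.predict_response`."""
    return fit.predict_response(state, **kwargs)
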