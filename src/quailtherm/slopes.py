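"""Metabolic slopes below thermoneutrality, repeatability, and the permutation null.

The cold response model is a fixed-intercept random-slope regression of
relative resting metabolism on ambient temperature,

    RM_ij ~ 1 + (beta1 + v_j) * (Ta_ij - pivot) + eps_ij,

where the intercept is pinned at 1 at the pivot temperature (30 degC for
juveniles; 24 degC for adults, whose thermoneutral zone extends down to
~24 degC), v_j ~ N(0, sigma_v^2) is individual j's slope deviation, and the
residual SD is temperature-specific.  Because relative metabolism is exactly
1 at the pivot by construction, pivot-temperature rows carry no information
and are excluded from the likelihood.

Individual slope deviations enter the mean linearly, so they are
marginalised analytically (each individual's measurements are jointly normal
with a rank-one covariance update), leaving a handful of population
parameters for MCMC; v_j posterior draws are recovered exactly afterwards
from their conjugate conditional.

Conditional repeatability at a temperature T (offset dT = pivot - T) with
random slopes only is

    R(T) = sigma_v^2 dT^2 / (sigma_v^2 dT^2 + sigma_eps(T)^2),

reported per temperature and averaged over the measured sub-thermoneutral
temperatures.  The permutation null refits the model with individual
identities scrambled among measurements (within temperature, which preserves
the design and every marginal distribution) and compares repeatability
between the true and scrambled fits.

Above thermoneutrality only two temperatures were measured, so the heat
slope is computed directly as (RM(40) - 1) / 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

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
from .errors import InputError, UnidentifiableModelError
from .respirometry import MetabolicProfile

JUVENILE_PIVOT_C = 30.0
ADULT_PIVOT_C = 24.0


@dataclass(frozen=True)
class SlopeModelSpec:
    """Specification of the fixed-intercept random-slope cold model.

    ``prior_log_sigma_base`` is the prior on the natural log of the residual
    SD at the coldest measured temperature; ``prior_sigma_decrement`` is the
    prior on each successive drop in log residual SD toward warmer
    temperatures (metabolism is less variable nearer thermoneutrality, hence
    the positive prior mean).
    """

    pivot_c: float = JUVENILE_PIVOT_C
    temperatures: tuple[float, ...] = (10.0, 20.0, 30.0)
    prior_slope: PriorSpec = field(
        default_factory=lambda: qb.skew_normal(-0.018, 0.02, -2.5)
    )
    prior_sigma_v: PriorSpec = field(
        default_factory=lambda: qb.exponential(2.5, transform="log-sample")
    )
    prior_log_sigma_base: PriorSpec = field(
        default_factory=lambda: qb.skew_normal(-0.2, 1.0, -5.0, transform="log")
    )
    prior_sigma_decrement: PriorSpec = field(default_factory=lambda: qb.normal(0.25, 0.25))


def default_slope_spec(age_class: str) -> SlopeModelSpec:
    """The study's cold-model specification for an age class."""
    if age_class == "adult":
        return SlopeModelSpec(pivot_c=ADULT_PIVOT_C)
    return SlopeModelSpec(pivot_c=JUVENILE_PIVOT_C)


def profiles_to_frame(profiles: Iterable[MetabolicProfile]) -> pd.DataFrame:
    rows = [
        {"id": p.id, "temperature_c": t, "relative": v}
        for p in profiles
        for t, v in sorted(p.relative.items())
    ]
    return pd.DataFrame(rows, columns=["id", "temperature_c", "relative"])


class ColdSlopeModel:
    """Fixed-intercept random-slope model of cold-induced metabolic increase.

    Parameters
    ----------
    data
        Metabolic profiles or a tidy frame with columns ``id``,
        ``temperature_c`` and ``relative`` (fold change from 30 degC).
    spec
        Pivot, included temperatures and the prior ledger.
    """

    def __init__(
        self,
        data: pd.DataFrame | Iterable[MetabolicProfile],
        spec: SlopeModelSpec | None = None,
    ) -> None:
        self.spec = spec or SlopeModelSpec()
        frame = data if isinstance(data, pd.DataFrame) else profiles_to_frame(data)
        frame = frame.loc[
            frame["temperature_c"].isin(self.spec.temperatures)
            & (frame["temperature_c"] < self.spec.pivot_c)
        ].copy()
        if frame.empty:
            raise UnidentifiableModelError("no sub-thermoneutral measurements in data")
        temps = np.sort(frame["temperature_c"].unique())
        if temps.size < 2:
            raise UnidentifiableModelError(
                "a single measurement temperature cannot identify individual slopes"
            )
        self.temperatures = tuple(float(t) for t in temps)
        self.ids = tuple(str(i) for i in pd.unique(frame["id"]))
        frame["x"] = frame["temperature_c"] - self.spec.pivot_c
        frame["y"] = frame["relative"] - 1.0
        self.frame = frame
        self._tindex = {t: k for k, t in enumerate(self.temperatures)}
        self._groups = self._build_groups(frame)
        self._n_sigma = len(self.temperatures)

    def _build_groups(self, frame: pd.DataFrame):
        groups = []
        patterns: dict[tuple, list] = {}
        for ind, sub in frame.groupby("id", sort=False):
            key = tuple(sorted(sub["temperature_c"]))
            patterns.setdefault(key, []).append((ind, sub))
        for key, members in patterns.items():
            x = np.array([t - self.spec.pivot_c for t in key])
            tidx = np.array([self._tindex[t] for t in key], dtype=int)
            Y = np.empty((len(members), len(key)))
            ids = []
            for row, (ind, sub) in enumerate(members):
                sub = sub.sort_values("temperature_c")
                Y[row] = sub["y"].to_numpy()
                ids.append(ind)
            groups.append({"x": x, "tidx": tidx, "Y": Y, "ids": ids})
        return groups

    # -- marginal likelihood --------------------------------------------
    def _log_sigmas(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        log_base = np.log(params["sigma_base"])  # (W,)
        if self._n_sigma == 1:
            return log_base[:, None]
        dec = np.atleast_2d(params["sigma_decrement"].T).T  # (W, K-1)
        return np.concatenate(
            [log_base[:, None], log_base[:, None] - np.cumsum(dec, axis=1)], axis=1
        )

    def loglike(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        beta1 = params["beta1"]
        sv2 = params["sigma_v"] ** 2
        log_sig = self._log_sigmas(params)
        sig2 = np.exp(2.0 * log_sig)  # (W, K)
        total = np.zeros_like(beta1)
        # Floor residual SDs at 1e-5 fold-change units: keeps the posterior
        # proper on degenerate (noise-free) inputs.
        bad = (log_sig < np.log(1e-5)).any(axis=1)
        for g in self._groups:
            x, Y = g["x"], g["Y"]
            d = sig2[:, g["tidx"]]  # (W, m)
            r = Y[None, :, :] - beta1[:, None, None] * x[None, None, :]  # (W, J, m)
            rd = r / d[:, None, :]
            quad0 = np.sum(r * rd, axis=2)  # (W, J)
            bx = np.sum(x[None, None, :] * rd, axis=2)  # (W, J)
            a = np.sum(x[None, :] ** 2 / d, axis=1)  # (W,)
            denom = 1.0 + sv2 * a
            quad = quad0 - (sv2 / denom)[:, None] * bx**2
            logdet = np.sum(np.log(d), axis=1) + np.log(denom)
            n_j = Y.shape[0]
            total += -0.5 * (
                np.sum(quad, axis=1) + n_j * (logdet + x.size * np.log(2 * np.pi))
            )
        total[bad] = -np.inf
        return total

    def _build_model(self) -> BayesianModel:
        blocks = [
            ParamBlock("beta1", self.spec.prior_slope),
            ParamBlock("sigma_v", self.spec.prior_sigma_v),
            ParamBlock("sigma_base", self.spec.prior_log_sigma_base),
        ]
        if self._n_sigma > 1:
            blocks.append(
                ParamBlock("sigma_decrement", self.spec.prior_sigma_decrement, self._n_sigma - 1)
            )
        init = self._data_init()
        return BayesianModel("cold_slope", blocks, self.loglike, init=init)

    def _data_init(self) -> dict:
        # Pooled least-squares slope and per-individual slope spread.
        f = self.frame
        beta = float((f["x"] * f["y"]).sum() / (f["x"] ** 2).sum())
        per_ind = [
            float((s["x"] * s["y"]).sum() / (s["x"] ** 2).sum())
            for _, s in f.groupby("id", sort=False)
        ]
        sv = float(np.std(per_ind)) if len(per_ind) > 2 else 0.01
        resid_sd = float(np.std(f["y"] - beta * f["x"]))
        init: dict = {
            "beta1": beta,
            "sigma_v": max(sv, 1e-3),
            "sigma_base": max(resid_sd, 1e-3),
        }
        if self._n_sigma > 1:
            init["sigma_decrement"] = np.full(self._n_sigma - 1, 0.25)
        return init

    def fit(
        self,
        chains: int = 4,
        draws: int = 2000,
        seed: int = 0,
        **kwargs,
    ) -> "ColdSlopeResults":
        model = self._build_model()
        post = sample_posterior(model, chains=chains, draws=draws, seed=seed, **kwargs)
        v = self._conditional_slope_deviations(post, seed)
        return ColdSlopeResults(self, post, v)

    def _conditional_slope_deviations(self, post: Draws, seed: int) -> np.ndarray:
        """Exact conjugate draws of v_j given the population parameters."""
        rng = np.random.default_rng(np.uint32(seed) + 104729)
        beta1 = post.flat("beta1")
        sv2 = post.flat("sigma_v") ** 2
        log_sig = self._log_sigmas(
            {
                "sigma_base": post.flat("sigma_base"),
                **(
                    {"sigma_decrement": post.flat("sigma_decrement")}
                    if self._n_sigma > 1
                    else {}
                ),
            }
        )
        sig2 = np.exp(2.0 * log_sig)  # (N, K)
        n = beta1.size
        v = np.empty((n, len(self.ids)))
        col = {ind: j for j, ind in enumerate(self.ids)}
        for g in self._groups:
            x = g["x"]
            d = sig2[:, g["tidx"]]  # (N, m)
            a = np.sum(x[None, :] ** 2 / d, axis=1)  # (N,)
            var = 1.0 / (1.0 / np.maximum(sv2, 1e-300) + a)
            sd = np.sqrt(var)
            for row, ind in enumerate(g["ids"]):
                r = g["Y"][row][None, :] - beta1[:, None] * x[None, :]
                c = np.sum(x[None, :] * r / d, axis=1)
                v[:, col[ind]] = var * c + sd * rng.standard_normal(n)
        return v


class ColdSlopeResults:
    """Posterior of the cold slope model.

    Exposes population draws (``beta1``, ``sigma_v``, per-temperature
    residual SDs), exact per-individual slope draws ``beta1 + v_j``, and the
    conditional-repeatability computation.
    """

    def __init__(self, model: ColdSlopeModel, draws: Draws, v: np.ndarray) -> None:
        self.model = model
        self.spec = model.spec
        self.draws = draws
        self.v = v  # (N, J) individual slope deviations
        self.ids = model.ids
        self.temperatures = model.temperatures

    @property
    def healthy(self) -> bool:
        return self.draws.healthy

    @property
    def beta1(self) -> np.ndarray:
        return self.draws.flat("beta1")

    @property
    def sigma_v(self) -> np.ndarray:
        return self.draws.flat("sigma_v")

    def sigma_eps(self) -> dict[float, np.ndarray]:
        """Residual SD draws per measurement temperature."""
        params = {"sigma_base": self.draws.flat("sigma_base")}
        if self.model._n_sigma > 1:
            params["sigma_decrement"] = self.draws.flat("sigma_decrement")
        log_sig = self.model._log_sigmas(params)
        return {t: np.exp(log_sig[:, k]) for k, t in enumerate(self.temperatures)}

    @property
    def slope_draws(self) -> np.ndarray:
        """Per-individual metabolic slope draws beta1 + v_j, shape (N, J)."""
        return self.beta1[:, None] + self.v

    def individual_slopes(self) -> pd.DataFrame:
        s = self.slope_draws
        q = np.quantile(s, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "slope_median": q[1],
                "slope_q2.5": q[0],
                "slope_q97.5": q[2],
            }
        )

    def predict_relative(self, temperature_c: float) -> np.ndarray:
        """Posterior predictive mean of relative metabolism at a temperature.

        Equals exactly 1 at the pivot for every individual and every draw
        (the fixed-intercept constraint); shape (N, J).
        """
        dt = temperature_c - self.spec.pivot_c
        return 1.0 + self.slope_draws * dt

    def repeatability(
        self, temperatures: Sequence[float] | None = None
    ) -> "RepeatabilityResult":
        return conditional_repeatability(self, temperatures)

    def summary(self) -> pd.DataFrame:
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for name in ("beta1", "sigma_v"):
                s = summarize(self.draws, name)
                rows.append(_summary_row(name, s))
            for t, sig in self.sigma_eps().items():
                s = summarize(sig)
                rows.append(_summary_row(f"sigma_eps({t:g}degC)", s))
        return pd.DataFrame(rows)


def _summary_row(name: str, s: PosteriorSummary) -> dict:
    return {
        "parameter": name,
        "median": s.median,
        "q25": s.ci50[0],
        "q75": s.ci50[1],
        "q2.5": s.ci95[0],
        "q97.5": s.ci95[1],
        "rhat": s.rhat,
        "ess_ratio": s.ess_ratio,
    }


@dataclass
class RepeatabilityResult:
    """Conditional repeatability draws with optional permutation-null comparison."""

    draws: np.ndarray
    per_temperature: dict[float, np.ndarray]
    median: float
    ci95: tuple[float, float]
    null_draws: np.ndarray | None = None
    exceedance: float | None = None
    bf: BayesFactor | None = None

    def to_dict(self) -> dict:
        out = {
            "median": self.median,
            "ci95": list(self.ci95),
            "per_temperature": {
                str(t): float(np.median(d)) for t, d in self.per_temperature.items()
            },
        }
        if self.null_draws is not None:
            out["null_median"] = float(np.median(self.null_draws))
            out["exceedance_probability"] = self.exceedance
            out["bf"] = self.bf.display if self.bf is not None else None
        return out


def repeatability_at(
    sigma_v: np.ndarray, sigma_eps: np.ndarray, delta_t: float
) -> np.ndarray:
    """R(dT) = sigma_v^2 dT^2 / (sigma_v^2 dT^2 + sigma_eps^2), elementwise."""
    between = sigma_v**2 * delta_t**2
    return between / (between + sigma_eps**2)


def conditional_repeatability(
    fit: ColdSlopeResults, temperatures: Sequence[float] | None = None
) -> RepeatabilityResult:
    """Among-individual fraction of variance, conditional on temperature.

    With random slopes only, the between-individual variance at temperature
    offset dT is sigma_v^2 dT^2.  Per-temperature values are reported and
    the headline number averages them over the measured sub-thermoneutral
    temperatures.
    """
    if temperatures is None:
        temperatures = fit.temperatures
    sv = fit.sigma_v
    sig = fit.sigma_eps()
    per_temp: dict[float, np.ndarray] = {}
    for t in temperatures:
        dt = fit.spec.pivot_c - t
        per_temp[float(t)] = repeatability_at(sv, sig[float(t)], dt)
    draws = np.mean(np.stack(list(per_temp.values())), axis=0)
    q = np.quantile(draws, [0.025, 0.5, 0.975])
    return RepeatabilityResult(
        draws=draws,
        per_temperature=per_temp,
        median=float(q[1]),
        ci95=(float(q[0]), float(q[2])),
    )


def scramble_identities(frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly reassign individual labels among measurements.

    Labels are permuted within each measurement temperature, which preserves
    the design (each pseudo-individual keeps one measurement per temperature)
    and every marginal distribution, while destroying any true association
    between measurements of the same bird.
    """
    out = frame.copy()
    for _, idx in out.groupby("temperature_c", sort=False).groups.items():
        idx = np.asarray(idx)
        out.loc[idx, "id"] = out.loc[rng.permutation(idx), "id"].to_numpy()
    return out


def null_repeatability_test(
    data: pd.DataFrame | Iterable[MetabolicProfile],
    spec: SlopeModelSpec | None = None,
    n_scrambles: int = 100,
    seed: int = 0,
    chains: int = 2,
    draws: int = 500,
    fit: ColdSlopeResults | None = None,
    prior_difference: PriorSpec | None = None,
    **fit_kwargs,
) -> RepeatabilityResult:
    """Test observed repeatability against the scrambled-identity null.

    The cold model is refitted ``n_scrambles`` times with individual
    identities scrambled among measurements; null repeatability draws are
    pooled across scrambles.  The exceedance probability is
    Pr(R_true > R_null) over pairs of draws and a one-way Bayes factor is
    computed by Savage-Dickey on the true-minus-null difference (prior on
    the difference: normal(0, 0.5) unless supplied).
    """
    if n_scrambles < 1:
        raise InputError("at least one scramble is required")
    spec = spec or SlopeModelSpec()
    frame = data if isinstance(data, pd.DataFrame) else profiles_to_frame(data)
    if fit is None:
        fit = ColdSlopeModel(frame, spec).fit(
            chains=max(chains, 2), draws=max(draws, 500), seed=seed, **fit_kwargs
        )
    true_rep = conditional_repeatability(fit)

    rng = np.random.default_rng(np.uint32(seed) + 7)
    null_parts = []
    for k in range(n_scrambles):
        scrambled = scramble_identities(frame, rng)
        null_fit = ColdSlopeModel(scrambled, spec).fit(
            chains=chains, draws=draws, seed=int(np.uint32(seed) + 1000 + k), **fit_kwargs
        )
        null_parts.append(conditional_repeatability(null_fit).draws)
    null_draws = np.concatenate(null_parts)

    # Exact Pr(true > null) over all cross pairs via ranking.
    sorted_null = np.sort(null_draws)
    exceedance = float(
        np.mean(np.searchsorted(sorted_null, true_rep.draws, side="left") / null_draws.size)
    )
    n_pairs = min(true_rep.draws.size, null_draws.size)
    t_sub = rng.choice(true_rep.draws, n_pairs, replace=False)
    n_sub = rng.choice(null_draws, n_pairs, replace=False)
    prior_diff = prior_difference or qb.normal(0.0, 0.5)
    bf = savage_dickey_bf(prior_diff, t_sub - n_sub, 0.0)
    return replace(
        true_rep, null_draws=null_draws, exceedance=exceedance, bf=bf
    )


def heat_slope(profile: MetabolicProfile) -> float:
    """Metabolic slope in the heat: (RM_rel(40) - 1) / 10, per degC.

    Only two temperatures were measured above thermoneutrality, so the heat
    slope is a direct two-point computation rather than a model estimate.
    """
    if 40.0 not in profile.relative:
        raise InputError(f"profile {profile.id!r} has no 40 degC measurement")
    return (profile.relative[40.0] - 1.0) / 10.0


def heat_slopes(
    profiles: Iterable[MetabolicProfile],
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Heat slopes for many profiles; individuals lacking 40 degC are logged."""
    rows = []
    excluded = []
    for p in profiles:
        try:
            rows.append({"id": p.id, "age_class": p.age_class, "heat_slope": heat_slope(p)})
        except InputError:
            excluded.append((p.id, p.age_class, "missing_40c_measurement"))
    return pd.DataFrame(rows, columns=["id", "age_class", "heat_slope"]), excluded
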