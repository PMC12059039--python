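"""Shared Bayesian machinery.

Models are specified as named parameter blocks, each with an explicit prior,
plus a vectorised log-likelihood.  Posteriors are drawn with an
affine-invariant ensemble sampler (emcee); walkers are grouped into chains
and thinned by the estimated integrated autocorrelation time so that
retained draws are close to independent, then convergence is summarised with
rank-normalised R-hat and effective-sample-size ratios (arviz).  A fit is
flagged unhealthy when R-hat leaves [0.99, 1.05] or ESS/N drops below 0.75.

Random effects that enter a model linearly are marginalised analytically in
the model-specific likelihoods (see :mod:`quailtherm.slopes` and
:mod:`quailtherm.growth`), which keeps the sampled dimension small enough
for ensemble MCMC to mix well.

Hypothesis tests use the Savage-Dickey density ratio: for a nested point
null the Bayes factor BF10 equals the prior density at the null value
divided by the posterior density there.  Matching common reporting practice,
Bayes factors above 1000 are reported as ">1000".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, log_ndtr

from .errors import InputError, SamplingError, SpecificationError

_FAMILIES = ("normal", "skew-normal", "exponential", "gamma", "student-t")


@dataclass(frozen=True)
class PriorSpec:
    """One univariate prior.

    Parameters use the field's conventional names: ``normal(mean, sd)``,
    ``skew-normal(xi, omega, alpha)`` (location, scale, shape),
    ``exponential(lam)`` (rate), ``gamma(alpha, beta)`` (shape, rate) and
    ``student-t(nu, centre, scale)``.  Transforms: ``"log"`` declares that
    the prior is placed on the natural log of the quantity (the sampler then
    works on the log scale and exposes the exponentiated value to the
    likelihood); ``"log-sample"`` keeps the prior on the natural value but
    samples its log (with the Jacobian correction), which removes the zero
    boundary and greatly improves mixing for scale parameters.
    """

    family: str
    params: tuple[float, ...]
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SpecificationError(f"unknown prior family {self.family!r}")
        if self.transform not in ("identity", "log", "log-sample"):
            raise SpecificationError(f"unknown transform {self.transform!r}")
        n_params = {"normal": 2, "skew-normal": 3, "exponential": 1, "gamma": 2, "student-t": 3}
        if len(self.params) != n_params[self.family]:
            raise SpecificationError(
                f"{self.family} prior takes {n_params[self.family]} parameters, got {len(self.params)}"
            )
        scale_index = {"normal": 1, "skew-normal": 1, "exponential": 0, "gamma": 1, "student-t": 2}
        scale = self.params[scale_index[self.family]]
        if scale <= 0:
            raise SpecificationError(f"{self.family} prior needs a positive scale/rate")

    @property
    def dist(self):
        cached = self.__dict__.get("_dist")
        if cached is not None:
            return cached
        p = self.params
        if self.family == "normal":
            d = stats.norm(loc=p[0], scale=p[1])
        elif self.family == "skew-normal":
            d = stats.skewnorm(p[2], loc=p[0], scale=p[1])
        elif self.family == "exponential":
            d = stats.expon(scale=1.0 / p[0])
        elif self.family == "gamma":
            d = stats.gamma(p[0], scale=1.0 / p[1])
        else:
            d = stats.t(p[0], loc=p[1], scale=p[2])
        self.__dict__["_dist"] = d
        return d

    def logpdf(self, x):
        # Analytic fast paths: called once per MCMC step per block, where
        # scipy's frozen-distribution dispatch would dominate the step cost.
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "normal":
            z = (x - p[0]) / p[1]
            return -0.5 * z**2 - np.log(p[1]) - 0.5 * np.log(2 * np.pi)
        if self.family == "skew-normal":
            z = (x - p[0]) / p[1]
            return (
                np.log(2.0)
                - 0.5 * z**2
                - np.log(p[1])
                - 0.5 * np.log(2 * np.pi)
                + log_ndtr(p[2] * z)
            )
        if self.family == "exponential":
            return np.where(x >= 0, np.log(p[0]) - p[0] * x, -np.inf)
        if self.family == "gamma":
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(
                    x > 0,
                    p[0] * np.log(p[1]) - gammaln(p[0]) + (p[0] - 1) * np.log(np.maximum(x, 1e-300)) - p[1] * x,
                    -np.inf,
                )
        nu, loc, scale = p
        z2 = ((x - loc) / scale) ** 2
        return (
            gammaln((nu + 1) / 2)
            - gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi)
            - np.log(scale)
            - (nu + 1) / 2 * np.log1p(z2 / nu)
        )

    def pdf(self, x):
        return self.dist.pdf(x)

    def rvs(self, rng: np.random.Generator, size=None):
        return self.dist.rvs(size=size, random_state=rng)

    def median(self) -> float:
        return float(self.dist.median())

    def spread(self) -> float:
        sd = float(self.dist.std())
        return sd if np.isfinite(sd) and sd > 0 else 1.0


# Convenience constructors --------------------------------------------------

def normal(mean: float, sd: float, transform: str = "identity") -> PriorSpec:
    return PriorSpec("normal", (mean, sd), transform)


def skew_normal(xi: float, omega: float, alpha: float, transform: str = "identity") -> PriorSpec:
    return PriorSpec("skew-normal", (xi, omega, alpha), transform)


def exponential(lam: float, transform: str = "identity") -> PriorSpec:
    return PriorSpec("exponential", (lam,), transform)


def gamma_prior(alpha: float, beta: float, transform: str = "identity") -> PriorSpec:
    return PriorSpec("gamma", (alpha, beta), transform)


@dataclass(frozen=True)
class HierarchicalNormal:
    """Zero-mean normal block whose SD is another (positive) model parameter.

    Standard encoding for exchangeable group effects (egg batches): the
    entries share N(0, scale) with ``scale`` given its own prior, e.g.
    exponential.
    """

    scale_param: str


@dataclass(frozen=True)
class ParamBlock:
    name: str
    prior: PriorSpec | HierarchicalNormal
    size: int = 1

    def __post_init__(self) -> None:
        if self.prior is None or not isinstance(self.prior, (PriorSpec, HierarchicalNormal)):
            raise SpecificationError(f"parameter {self.name!r} lacks a valid prior")
        if self.size < 1:
            raise SpecificationError(f"parameter {self.name!r} has invalid size {self.size}")


class BayesianModel:
    """A named-parameter model with explicit priors and vectorised likelihood.

    ``loglike`` receives a dict mapping block names to arrays of shape
    ``(walkers,)`` (scalar blocks) or ``(walkers, size)`` (vector blocks) on
    the natural scale (log-transformed blocks arrive exponentiated) and must
    return log-likelihoods of shape ``(walkers,)``.
    """

    def __init__(
        self,
        name: str,
        blocks: Sequence[ParamBlock],
        loglike: Callable[[Mapping[str, np.ndarray]], np.ndarray],
        init: Mapping[str, float | np.ndarray] | None = None,
    ) -> None:
        self.name = name
        self.blocks = list(blocks)
        self.loglike = loglike
        self.init = dict(init or {})
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise SpecificationError(f"duplicate parameter names in model {name!r}")
        for b in self.blocks:
            if isinstance(b.prior, HierarchicalNormal) and b.prior.scale_param not in names:
                raise SpecificationError(
                    f"hierarchical block {b.name!r} references unknown scale {b.prior.scale_param!r}"
                )
        self._offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for b in self.blocks:
            self._offsets[b.name] = (pos, pos + b.size)
            pos += b.size
        self.dim = pos

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Split a (walkers, dim) matrix into natural-scale named blocks."""
        theta = np.atleast_2d(theta)
        out: dict[str, np.ndarray] = {}
        for b in self.blocks:
            lo, hi = self._offsets[b.name]
            chunk = theta[:, lo] if b.size == 1 else theta[:, lo:hi]
            if isinstance(b.prior, PriorSpec) and b.prior.transform in ("log", "log-sample"):
                chunk = np.exp(chunk)
            out[b.name] = chunk
        return out

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = np.zeros(theta.shape[0])
        scales: dict[str, np.ndarray] = {}
        # Extreme proposals may overflow exp(); they end up at -inf density.
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for b in self.blocks:
                lo, hi = self._offsets[b.name]
                if isinstance(b.prior, PriorSpec):
                    if b.prior.transform == "log-sample":
                        # Prior on the natural value, sampled on the log scale.
                        lp += b.prior.logpdf(np.exp(theta[:, lo:hi])).sum(axis=1)
                        lp += theta[:, lo:hi].sum(axis=1)
                    else:
                        lp += b.prior.logpdf(theta[:, lo:hi]).sum(axis=1)
                    scales[b.name] = (
                        np.exp(theta[:, lo])
                        if b.prior.transform in ("log", "log-sample")
                        else theta[:, lo]
                    )
            for b in self.blocks:
                if isinstance(b.prior, HierarchicalNormal):
                    lo, hi = self._offsets[b.name]
                    sd = scales.get(b.prior.scale_param)
                    if sd is None:
                        lo2, hi2 = self._offsets[b.prior.scale_param]
                        sd = theta[:, lo2]
                    sd = np.maximum(np.asarray(sd, dtype=float), 1e-12)
                    x = theta[:, lo:hi]
                    lp += -0.5 * np.sum((x / sd[:, None]) ** 2, axis=1) - x.shape[1] * (
                        np.log(sd) + 0.5 * np.log(2 * np.pi)
                    )
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore", under="ignore"):
                ll = np.asarray(self.loglike(self.unpack(theta[ok])), dtype=float)
            ll = np.where(np.isfinite(ll), ll, -np.inf)
            out[ok] = lp[ok] + ll
        return out

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """One sampling-scale starting vector near prior (or supplied) centres."""
        theta = np.empty(self.dim)
        for b in self.blocks:
            lo, hi = self._offsets[b.name]
            if isinstance(b.prior, HierarchicalNormal):
                centre, spread = 0.0, 0.1
            else:
                centre, spread = b.prior.median(), b.prior.spread()
                if b.prior.transform == "log-sample":
                    # Sampling scale is the log of the natural value.
                    centre = np.log(max(centre, 1e-10))
                    spread = 0.75
            override = self.init.get(b.name)
            if override is not None:
                centre = np.asarray(override, dtype=float)
                if isinstance(b.prior, PriorSpec) and b.prior.transform in ("log", "log-sample"):
                    centre = np.log(np.maximum(centre, 1e-10))
            theta[lo:hi] = centre + jitter * spread * rng.standard_normal(hi - lo)
        return theta


@dataclass
class Draws:
    """Posterior draws organised as chains x iterations (x block size).

    ``params`` holds natural-scale values.  Diagnostics (R-hat, ESS ratio)
    are per parameter block; ``healthy`` aggregates the gates R-hat in
    [0.99, 1.05] and ESS/N >= 0.75.
    """

    params: dict[str, np.ndarray]
    seed: int
    rhat: dict[str, float] = field(default_factory=dict)
    ess_ratio: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def healthy(self) -> bool:
        rh = [v for v in self.rhat.values() if np.isfinite(v)]
        es = [v for v in self.ess_ratio.values() if np.isfinite(v)]
        ok_r = all(0.99 <= v <= 1.05 for v in rh) if rh else True
        ok_e = all(v >= 0.75 for v in es) if es else True
        return ok_r and ok_e

    def flat(self, name: str) -> np.ndarray:
        """All draws of one block pooled across chains: (N,) or (N, size)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def names(self) -> list[str]:
        return list(self.params)


def _diagnostics(params: dict[str, np.ndarray]) -> tuple[dict[str, float], dict[str, float]]:
    import arviz as az

    rhat: dict[str, float] = {}
    ess_ratio: dict[str, float] = {}
    for name, arr in params.items():
        n_total = arr.shape[0] * arr.shape[1]
        if arr.shape[0] < 2 or arr.shape[1] < 4 or np.allclose(arr.std(), 0):
            rhat[name] = 1.0
            ess_ratio[name] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr))
            e = az.ess(az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr))
        rhat[name] = float(np.nanmax(r.to_array().values))
        ess_ratio[name] = float(min(np.nanmin(e.to_array().values) / n_total, 1.0))
    return rhat, ess_ratio


def sample_posterior(
    model: BayesianModel,
    chains: int = 4,
    draws: int = 2000,
    seed: int = 0,
    burn: int | None = None,
    thin: int | None = None,
    max_thin: int = 160,
) -> Draws:
    """Draw from a model's posterior with a reproducible ensemble sampler.

    ``chains * draws`` (at least) natural-scale samples are retained after a
    burn-in of ``burn`` steps and thinning by the estimated integrated
    autocorrelation time.  The same seed always yields identical draws.
    """
    import emcee

    if chains < 2:
        raise SpecificationError("at least 2 chains are required for diagnostics")
    for b in model.blocks:
        if not isinstance(b.prior, (PriorSpec, HierarchicalNormal)):
            raise SpecificationError(f"parameter {b.name!r} has no prior")

    dim = model.dim
    per_chain = max(int(np.ceil(max(2 * dim + 2, 64) / chains)), 2)
    n_walkers = chains * per_chain
    rng = np.random.default_rng(np.uint32(seed) + 1)

    p0 = np.empty((n_walkers, dim))
    lp0 = np.full(n_walkers, -np.inf)
    jitter = 0.15
    for attempt in range(60):
        bad = ~np.isfinite(lp0)
        if not bad.any():
            break
        for i in np.nonzero(bad)[0]:
            p0[i] = model.initial_point(rng, jitter=jitter)
        lp0[bad] = model.log_prob(p0[bad])
        jitter = max(jitter * 0.7, 0.01)
    if not np.isfinite(lp0).all():
        raise SamplingError(
            f"could not initialise model {model.name!r}: log-density not finite at any start point"
        )

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, dim, model.log_prob, vectorize=True, moves=moves)
    # The sampler expects a full RandomState *state tuple*; anything else is
    # silently ignored, which would leave the run irreproducible.
    sampler.random_state = np.random.RandomState(np.uint32(seed)).get_state()

    if burn is None:
        burn = max(300, 20 * dim)
    state = sampler.run_mcmc(p0, burn, progress=False)
    if np.mean(sampler.acceptance_fraction) < 0.01:
        raise SamplingError(
            f"model {model.name!r}: ensemble acceptance collapsed during burn-in"
        )
    if thin is None:
        import logging

        logging.getLogger("emcee.autocorr").setLevel(logging.ERROR)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                tau = sampler.get_autocorr_time(quiet=True)
                tau_max = float(np.nanmax(tau))
            except Exception:
                tau_max = 6.0
        if not np.isfinite(tau_max):
            tau_max = 6.0
        thin = int(np.clip(np.ceil(1.25 * tau_max), 1, max_thin))

    retained = int(np.ceil(chains * draws / n_walkers))

    def _collect(thin_now: int) -> dict[str, np.ndarray]:
        chain = sampler.get_chain(discard=burn, thin=thin_now)[-retained:]
        arr = chain.transpose(1, 0, 2).reshape(chains, per_chain, chain.shape[0], dim)
        arr = arr.reshape(chains, -1, dim)
        out: dict[str, np.ndarray] = {}
        for b in model.blocks:
            lo, hi = model._offsets[b.name]
            block = arr[:, :, lo] if b.size == 1 else arr[:, :, lo:hi]
            if isinstance(b.prior, PriorSpec) and b.prior.transform in ("log", "log-sample"):
                block = np.exp(block)
            out[b.name] = block
        return out

    state = sampler.run_mcmc(state, retained * thin, progress=False)
    params = _collect(thin)
    rhat, ess_ratio = _diagnostics(params)
    # The burn-phase autocorrelation estimate is often too low; when the
    # effective-sample gate fails, extend the chain and double the thinning
    # (reusing everything sampled so far) up to three times.
    for _ in range(5):
        if min(ess_ratio.values(), default=1.0) >= 0.75 or thin >= max_thin:
            break
        state = sampler.run_mcmc(state, retained * thin, progress=False)
        thin = min(2 * thin, max_thin)
        params = _collect(thin)
        rhat, ess_ratio = _diagnostics(params)
    meta = {
        "model": model.name,
        "walkers": n_walkers,
        "burn": burn,
        "thin": thin,
        "acceptance": float(np.mean(sampler.acceptance_fraction)),
    }
    return Draws(params=params, seed=seed, rhat=rhat, ess_ratio=ess_ratio, meta=meta)


@dataclass(frozen=True)
class BayesFactor:
    """A Savage-Dickey Bayes factor (BF10) with the >1000 reporting cap."""

    value: float
    truncated: bool = False

    @property
    def display(self) -> str:
        return "BF > 1000" if self.truncated else f"BF = {self.value:.3f}"

    def __float__(self) -> float:
        return float(min(self.value, 1000.0)) if self.truncated else float(self.value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BayesFactor({self.display})"


def savage_dickey_bf(prior: PriorSpec, samples: np.ndarray, point: float = 0.0) -> BayesFactor:
    """Savage-Dickey density-ratio Bayes factor for a point null.

    BF10 = prior density at ``point`` / posterior density at ``point``.  The
    posterior density is estimated from the draws with a Gaussian kernel
    (Silverman bandwidth); when the KDE is degenerate a moment-matched
    normal approximation is used instead.  Ratios above 1000 (including an
    estimated posterior density of zero) are flagged ``truncated`` and
    reported as ">1000".
    """
    if prior.transform != "identity":
        raise SpecificationError("Savage-Dickey requires the prior on the natural scale")
    samples = np.asarray(samples, dtype=float).ravel()
    p_prior = float(prior.pdf(point))
    if not np.isfinite(p_prior) or p_prior <= 0:
        raise InputError("prior density at the test point must be finite and positive")
    sd = samples.std()
    if samples.size < 10 or sd == 0:
        p_post = float(stats.norm(samples.mean(), max(sd, 1e-300)).pdf(point)) if sd > 0 else 0.0
    else:
        try:
            kde = stats.gaussian_kde(samples, bw_method="silverman")
            p_post = float(kde(point)[0])
        except np.linalg.LinAlgError:
            p_post = float(stats.norm(samples.mean(), sd).pdf(point))
    if p_post <= 0:
        return BayesFactor(np.inf, truncated=True)
    bf = p_prior / p_post
    return BayesFactor(bf, truncated=bf > 1000.0)


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and central quantile intervals of one marginal posterior."""

    median: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    rhat: float = np.nan
    ess_ratio: float = np.nan
    bf: BayesFactor | None = None
    n: int = 0

    def __str__(self) -> str:
        s = (
            f"median={self.median:.4g} "
            f"50%[{self.ci50[0]:.4g}, {self.ci50[1]:.4g}] "
            f"95%[{self.ci95[0]:.4g}, {self.ci95[1]:.4g}]"
        )
        if self.bf is not None:
            s += f" {self.bf.display}"
        return s


def summarize(
    draws: Draws | np.ndarray,
    parameter: str | None = None,
    bf: BayesFactor | None = None,
) -> PosteriorSummary:
    """Median plus 50% and 95% central quantile intervals of one parameter.

    Medians and quantile intervals (rather than means and HPDs) are robust
    to the skewed posteriors common in variance parameters.  Fewer than 1000
    retained draws triggers a warning but still produces a summary.
    """
    if isinstance(draws, Draws):
        if parameter is None:
            raise InputError("parameter name required when summarising a Draws object")
        samples = draws.flat(parameter)
        rhat = draws.rhat.get(parameter, np.nan)
        ess = draws.ess_ratio.get(parameter, np.nan)
    else:
        samples = np.asarray(draws, dtype=float)
        rhat, ess = np.nan, np.nan
    samples = samples.ravel()
    if samples.size < 1000:
        warnings.warn(
            f"only {samples.size} draws available for summary (fewer than 1000)",
            RuntimeWarning,
            stacklevel=2,
        )
    q = np.quantile(samples, [0.025, 0.25, 0.5, 0.75, 0.975])
    return PosteriorSummary(
        median=float(q[2]),
        ci50=(float(q[1]), float(q[3])),
        ci95=(float(q[0]), float(q[4])),
        rhat=float(rhat),
        ess_ratio=float(ess),
        bf=bf,
        n=int(samples.size),
    )


@dataclass(frozen=True)
class EffectSize:
    """Posterior-prediction Cohen's D: per-draw values plus mean and SD."""

    d: np.ndarray
    mean: float | None
    sd: float | None

    @property
    def missing(self) -> bool:
        return self.mean is None


def cohens_d(
    pred_a: np.ndarray, pred_b: np.ndarray, reference_sd: np.ndarray | float
) -> EffectSize:
    """Effect size between two posterior-prediction states.

    Per draw, D = (A - B) / SD where SD is the reference posterior-predictive
    standard deviation (scalar or per-draw).  A zero reference SD makes D
    undefined; such draws are dropped and, if none remain, the effect is
    reported missing.
    """
    a = np.asarray(pred_a, dtype=float).ravel()
    b = np.asarray(pred_b, dtype=float).ravel()
    if a.size != b.size:
        raise InputError("prediction draws must have equal length")
    sd = np.broadcast_to(np.asarray(reference_sd, dtype=float).ravel(), a.shape).copy()
    valid = sd > 0
    if not valid.any():
        return EffectSize(d=np.full(a.shape, np.nan), mean=None, sd=None)
    d = np.where(valid, (a - b) / np.where(valid, sd, 1.0), np.nan)
    return EffectSize(
        d=d, mean=float(np.nanmean(d)), sd=float(np.nanstd(d))
    )
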