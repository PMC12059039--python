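"""Synthetic quail studies with recorded ground truth.

The generator emulates the structure of the real experiment: three egg
batches crossed with three rearing treatments (10/20/30 degC), weekly
morphometry from hatching to week 8 (appendages measured weekly to week 3
and again at week 8), and flow-through respirometry at 10/20/30/40 degC in
two age classes (juveniles at week 3, adults at week 8).

Ground truth is drawn from the same generative models the package fits:
Gompertz growth with treatment effects on (a, b, c), individual intercepts,
batch effects, age-growing residual SD and mass-allometry of the appendages;
individual metabolic slopes from the linear path equations (rearing +
morphometry effects + batch effect + residual); relative resting metabolism
built from those slopes through the age-specific pivot with
temperature-specific noise; evaporative cooling efficiency from its own
terminal equation.  Every latent quantity (individual slopes, batch effects)
is recorded in :class:`SyntheticTruth` so parameter-recovery tests can score
estimates against the exact generating values.

Default parameter values mirror the study's scales: asymptotic mass ~250 g,
tarsus ~37.5 mm, bill ~15.7 mm, warm-minus-cold contrasts of -13 g (mass a),
+0.66 mm (tarsus a) and +0.44 mm (bill a), population cold slope -0.018 per
degC with individual SD 0.005, heat slope ~0.0087 per degC rising 3e-4 per
gram of body mass, and trait coefficients of variation near 13% (mass),
6% (tarsus) and 9% (bill).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import StudyData
from .errors import InputError
from .respirometry import GasTrace, JOULES_PER_ML_H2O, JOULES_PER_ML_O2, VAPOUR_TO_LIQUID

MASS_WEEKS = tuple(range(0, 9))
APPENDAGE_WEEKS = (0, 1, 2, 3, 8)
JUVENILE_WEEK = 3
ADULT_WEEK = 8


@dataclass(frozen=True)
class GrowthTruth:
    """True Gompertz system for one trait."""

    a0: float
    a_cold: float
    a_warm: float
    b0: float
    c0: float
    c_cold: float
    c_warm: float
    b_cold: float = 0.0
    b_warm: float = 0.0
    ind_sd: float = 1.0
    tau0: float = 1.0
    tau1: float = 0.5
    batch_sd_a: float = 0.0
    mass_coef: float = 0.0  # allometry: trait mm per g of within-week mass deviation


@dataclass(frozen=True)
class PathTruth:
    """True linear equation for a terminal response (slopes or ECE).

    Continuous-trait coefficients apply to deviations from the population
    mean at the relevant age class; ``sd`` is the residual SD among
    individuals (for cold slopes this is the true sigma_v when all
    coefficients are zero).
    """

    intercept: float
    mass: float = 0.0
    tarsus: float = 0.0
    bill: float = 0.0
    cold: float = 0.0
    warm: float = 0.0
    sd: float = 0.005
    batch_sd: float = 0.0
    #: residual degrees of freedom; None draws normal residuals, a number
    #: draws Student-t residuals with ``sd`` as the scale parameter (heat
    #: slopes were heavy-tailed in the study).
    nu: float | None = None


def _default_growth() -> dict[str, GrowthTruth]:
    return {
        # Individual SDs sized so trait coefficients of variation land near
        # the study's printed values (mass ~13%, tarsus ~6%, bill ~9%).
        "mass": GrowthTruth(
            a0=250.0, a_cold=6.5, a_warm=-6.5, b0=3.0,
            c0=0.5, c_cold=-0.03, c_warm=0.03,
            ind_sd=25.0, tau0=1.5, tau1=1.0, batch_sd_a=2.0,
        ),
        "tarsus": GrowthTruth(
            a0=37.5, a_cold=-0.33, a_warm=0.33, b0=0.6,
            c0=0.5, c_cold=-0.044, c_warm=0.044,
            ind_sd=1.8, tau0=0.6, tau1=0.25, batch_sd_a=0.3, mass_coef=0.029,
        ),
        "bill": GrowthTruth(
            a0=15.7, a_cold=-0.22, a_warm=0.22, b0=1.7,
            c0=0.5, c_cold=0.045, c_warm=-0.045,
            ind_sd=1.3, tau0=0.35, tau1=0.12, batch_sd_a=0.15,
        ),
    }


def _default_cold_slopes() -> dict[str, PathTruth]:
    return {
        "juvenile": PathTruth(
            intercept=-0.018, mass=2.0e-4, tarsus=-4.0e-4, bill=0.0,
            cold=3.6e-3, warm=-9.0e-4, sd=0.004, batch_sd=1.0e-3,
        ),
        "adult": PathTruth(intercept=-0.018, sd=0.005, batch_sd=1.0e-3),
    }


def _default_heat_slopes() -> dict[str, PathTruth]:
    return {
        # Residual SDs sized so morphometry explains a few percent of the
        # response variance, as in the study (heat partial R^2 ~ 0.05, and
        # phenotypes with moderate whole-body heat costs rare).
        "juvenile": PathTruth(
            intercept=0.0087, mass=5.0e-4, tarsus=-1.0e-3, bill=-0.011,
            cold=-7.5e-3, warm=-0.017, sd=0.035, batch_sd=1.0e-3, nu=5.0,
        ),
        "adult": PathTruth(
            intercept=0.0087, mass=3.0e-4, tarsus=-2.4e-3, bill=-5.6e-3,
            sd=0.035, batch_sd=1.0e-3, nu=10.0,
        ),
    }


def _default_ece() -> dict[str, PathTruth]:
    return {
        "juvenile": PathTruth(
            intercept=0.5, mass=-2.6e-3, tarsus=0.0, bill=0.02,
            sd=0.12, batch_sd=0.02,
        ),
        "adult": PathTruth(
            intercept=0.75, mass=-1.4e-3, tarsus=4.6e-3, bill=0.049,
            sd=0.12, batch_sd=0.02,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of a synthetic study.

    ``n_per_group`` individuals are generated per rearing treatment x egg
    batch (default 15, i.e. 45 per treatment and 135 in total, the scale of
    the real experiment).
    """

    n_per_group: int = 15
    seed: int = 0
    growth: Mapping[str, GrowthTruth] = field(default_factory=_default_growth)
    cold_slope: Mapping[str, PathTruth] = field(default_factory=_default_cold_slopes)
    heat_slope: Mapping[str, PathTruth] = field(default_factory=_default_heat_slopes)
    ece: Mapping[str, PathTruth] = field(default_factory=_default_ece)
    #: residual SD of relative metabolism by sub-thermoneutral temperature
    sigma_eps_cold: Mapping[float, float] = field(
        default_factory=lambda: {10.0: 0.15, 20.0: 0.10}
    )
    #: residual SD of relative metabolism at 40 degC
    sigma_eps_heat: float = 0.03
    #: thermoneutral VO2 per gram of body mass (mL O2 min^-1 g^-1)
    vo2_per_gram: float = 0.018

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        payload = dataclasses.asdict(self)
        payload["sigma_eps_cold"] = {str(k): v for k, v in self.sigma_eps_cold.items()}
        return json.dumps(payload, indent=2, sort_keys=True, default=enc)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        for key, factory in (
            ("growth", GrowthTruth),
            ("cold_slope", PathTruth),
            ("heat_slope", PathTruth),
            ("ece", PathTruth),
        ):
            if key in raw:
                raw[key] = {k: factory(**v) for k, v in raw[key].items()}
        if "sigma_eps_cold" in raw:
            raw["sigma_eps_cold"] = {float(k): v for k, v in raw["sigma_eps_cold"].items()}
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Realised ground truth of one generated study."""

    config: GeneratorConfig
    individual: pd.DataFrame  # per-individual latent values
    batch_effects: dict

    def to_json_file(self, path: str | Path) -> None:
        payload = {
            "config": json.loads(self.config.to_json()),
            "individual": self.individual.to_dict(orient="list"),
            "batch_effects": self.batch_effects,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def _treatment_value(truth, par: str, rearing: str) -> float:
    base = getattr(truth, f"{par}0")
    if rearing == "cold":
        return base + getattr(truth, f"{par}_cold")
    if rearing == "warm":
        return base + getattr(truth, f"{par}_warm")
    return base


def _gompertz(a, b, c, t):
    return a * np.exp(-b * np.exp(-c * np.asarray(t, dtype=float)))


def generate_population(config: GeneratorConfig) -> tuple[StudyData, SyntheticTruth]:
    """Generate a complete synthetic study and its ground truth.

    The same config (including its seed) always produces bit-identical
    output.  Returns the dataset in the canonical schema plus the
    :class:`SyntheticTruth` needed to score recovery.
    """
    if config.n_per_group < 1:
        raise InputError("n_per_group must be at least 1")
    rng = np.random.default_rng(np.uint32(config.seed))
    treatments = ("cold", "mild", "warm")
    batches = (1, 2, 3)

    individuals = []
    for rearing in treatments:
        for batch in batches:
            for k in range(config.n_per_group):
                individuals.append(
                    {
                        "id": f"B{batch}-{rearing[0].upper()}{k + 1:02d}",
                        "batch": batch,
                        "rearing": rearing,
                        "sex": ("female", "male")[k % 2],
                    }
                )
    ind = pd.DataFrame(individuals)
    n = len(ind)

    batch_effects: dict = {}
    # -- growth trajectories ------------------------------------------------
    trait_values: dict[str, np.ndarray] = {}
    weeks = np.asarray(MASS_WEEKS, dtype=float)
    latent = {"id": ind["id"], "batch": ind["batch"], "rearing": ind["rearing"]}
    # Iterate traits in a fixed order so the random stream (and hence the
    # output) does not depend on the mapping's insertion order.
    for trait in ("mass", "tarsus", "bill"):
        truth = config.growth[trait]
        u_batch = truth.batch_sd_a * rng.standard_normal(len(batches))
        batch_effects[f"growth_{trait}_a"] = u_batch.tolist()
        u_ind = truth.ind_sd * rng.standard_normal(n)
        latent[f"u_{trait}"] = u_ind
        a = np.array([_treatment_value(truth, "a", r) for r in ind["rearing"]])
        a = a + u_batch[ind["batch"].to_numpy() - 1]
        b = np.array([_treatment_value(truth, "b", r) for r in ind["rearing"]])
        c = np.array([_treatment_value(truth, "c", r) for r in ind["rearing"]])
        curve = _gompertz(a[:, None], b[:, None], c[:, None], weeks[None, :])
        sd_t = truth.tau0 + truth.tau1 * np.log(weeks + 1.0)
        values = curve + u_ind[:, None] + sd_t[None, :] * rng.standard_normal((n, weeks.size))
        trait_values[trait] = values
    # Allometry: couple appendages to within-week mass deviations.
    mass_dev = trait_values["mass"] - trait_values["mass"].mean(axis=0, keepdims=True)
    for trait in ("tarsus", "bill"):
        coef = config.growth[trait].mass_coef
        if coef:
            trait_values[trait] = trait_values[trait] + coef * mass_dev
    for trait in trait_values:
        np.clip(trait_values[trait], 0.1, None, out=trait_values[trait])

    morph_rows = []
    for i in range(n):
        for w in MASS_WEEKS:
            morph_rows.append(
                {
                    "id": ind.at[i, "id"],
                    "age_weeks": w,
                    "mass_g": trait_values["mass"][i, w],
                    "tarsus_mm": trait_values["tarsus"][i, w] if w in APPENDAGE_WEEKS else np.nan,
                    "bill_mm": trait_values["bill"][i, w] if w in APPENDAGE_WEEKS else np.nan,
                    "calibration": "grid-under",
                }
            )
    morph = pd.DataFrame(morph_rows)

    # -- thermoregulatory responses per age class --------------------------
    resp_rows = []
    age_weeks = {"juvenile": JUVENILE_WEEK, "adult": ADULT_WEEK}
    pivots = {"juvenile": 30.0, "adult": 24.0}
    for age_class, week in age_weeks.items():
        mass = trait_values["mass"][:, week]
        tarsus = trait_values["tarsus"][:, week]
        bill = trait_values["bill"][:, week]
        centred = {
            "mass": mass - mass.mean(),
            "tarsus": tarsus - tarsus.mean(),
            "bill": bill - bill.mean(),
        }

        def draw_response(truth: PathTruth, key: str) -> np.ndarray:
            u_batch = truth.batch_sd * rng.standard_normal(len(batches))
            batch_effects[key] = u_batch.tolist()
            value = (
                truth.intercept
                + truth.mass * centred["mass"]
                + truth.tarsus * centred["tarsus"]
                + truth.bill * centred["bill"]
                + truth.cold * (ind["rearing"] == "cold").to_numpy(float)
                + truth.warm * (ind["rearing"] == "warm").to_numpy(float)
                + u_batch[ind["batch"].to_numpy() - 1]
                + truth.sd
                * (
                    rng.standard_t(truth.nu, n)
                    if truth.nu is not None
                    else rng.standard_normal(n)
                )
            )
            return value

        cold_slopes = draw_response(config.cold_slope[age_class], f"cold_slope_{age_class}")
        heat_slopes = draw_response(config.heat_slope[age_class], f"heat_slope_{age_class}")
        ece = np.clip(draw_response(config.ece[age_class], f"ece_{age_class}"), 0.02, None)
        latent[f"cold_slope_{age_class}"] = cold_slopes
        latent[f"heat_slope_{age_class}"] = heat_slopes
        latent[f"ece_{age_class}"] = ece

        vo2_30 = config.vo2_per_gram * mass
        pivot = pivots[age_class]
        for i in range(n):
            rel = {30.0: 1.0}
            for t, sd in config.sigma_eps_cold.items():
                rel[t] = 1.0 + cold_slopes[i] * (t - pivot) + sd * rng.standard_normal()
            rel[40.0] = 1.0 + 10.0 * heat_slopes[i] + config.sigma_eps_heat * rng.standard_normal()
            for t, r in sorted(rel.items()):
                vo2 = max(r, 0.05) * vo2_30[i]
                if t == 40.0:
                    # EWL chosen so the reduced ECE equals the latent value.
                    ewl = ece[i] * vo2 * JOULES_PER_ML_O2 / JOULES_PER_ML_H2O
                else:
                    ewl = np.nan
                resp_rows.append(
                    {
                        "id": ind.at[i, "id"],
                        "age_class": age_class,
                        "temperature_c": t,
                        "vo2_ml_min": vo2,
                        "ewl_ml_min": ewl,
                        "body_temp_c": np.nan,
                    }
                )
    resp = pd.DataFrame(resp_rows)

    data = StudyData(ind, morph, resp)
    truth = SyntheticTruth(
        config=config, individual=pd.DataFrame(latent), batch_effects=batch_effects
    )
    return data, truth


@dataclass(frozen=True)
class TraceNoiseSpec:
    """Noise model for synthetic gas traces.

    The trace carries baseline FeO2 noise of ``feo2_sd`` everywhere except a
    designated low-noise segment of ``stable_duration_s`` starting at
    ``stable_start_s`` (emulating the bird settling), plus optional linear
    drift over the recording.
    """

    feo2_sd: float = 5.0e-4
    stable_feo2_sd: float = 1.0e-5
    wvp_sd_kpa: float = 2.0e-3
    stable_start_s: float = 300.0
    stable_duration_s: float = 120.0
    duration_s: float = 600.0
    dt_s: float = 1.0
    drift_per_s: float = 0.0


def generate_gas_traces(
    targets: Sequence[Mapping[str, float]],
    noise: TraceNoiseSpec | None = None,
    seed: int = 0,
    FR_ml_min: float = 4200.0,
    FiO2: float = 0.2095,
    BP_kpa: float = 101.3,
) -> list[GasTrace]:
    """Synthesise gas traces whose stable-window reduction recovers targets.

    Each target is a mapping with keys ``vo2`` (mL O2 min^-1) and optionally
    ``ewl`` (mL liquid water min^-1).  With a zero-noise spec the reduction
    recovers the targets exactly; the designated low-noise segment is where
    :func:`quailtherm.respirometry.stable_window` should land.
    """
    noise = noise or TraceNoiseSpec()
    rng = np.random.default_rng(np.uint32(seed))
    time_s = np.arange(0.0, noise.duration_s, noise.dt_s)
    i0 = int(round(noise.stable_start_s / noise.dt_s))
    i1 = i0 + int(round(noise.stable_duration_s / noise.dt_s))
    traces = []
    for target in targets:
        vo2 = float(target["vo2"])
        ewl = float(target.get("ewl", 0.0))
        if vo2 <= 0:
            raise InputError("target VO2 must be positive")
        feo2_level = FiO2 - vo2 * (1.0 - FiO2) / FR_ml_min
        sd = np.full(time_s.size, noise.feo2_sd)
        sd[i0:i1] = noise.stable_feo2_sd
        feo2 = feo2_level + sd * rng.standard_normal(time_s.size)
        feo2 += noise.drift_per_s * (time_s - time_s[i0:i1].mean())
        feo2[i0:i1] = feo2_level + sd[i0:i1] * rng.standard_normal(i1 - i0)
        if ewl > 0:
            vapour = ewl / VAPOUR_TO_LIQUID
            wvpe_level = vapour * BP_kpa / (FR_ml_min + vapour)
            wsd = np.full(time_s.size, noise.wvp_sd_kpa)
            wsd[i0:i1] = noise.wvp_sd_kpa * 0.01
            wvpe = np.clip(wvpe_level + wsd * rng.standard_normal(time_s.size), 0.0, None)
        else:
            wvpe = np.zeros(time_s.size)
        traces.append(
            GasTrace(
                time_s=time_s,
                FeO2=feo2,
                FR_ml_min=FR_ml_min,
                FiO2=FiO2,
                WVPe_kpa=wvpe,
                WVPi_kpa=0.0,
                BP_kpa=BP_kpa,
            )
        )
    return traces
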