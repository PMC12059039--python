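"""Flow-through respirometry reduction and relativised metabolic profiles.

Raw gas traces (fractional excurrent O2, water vapour pressure, flow rate)
are reduced to oxygen consumption, evaporative water loss, heat-production
and heat-loss rates, and evaporative cooling efficiency (ECE).  Conversion
constants follow standard animal-energetics practice: 20 J per mL O2
consumed and 2406 J per mL of liquid water evaporated.  With water vapour
and CO2 scrubbed upstream of the O2 analyser, oxygen consumption is

    VO2 = FR * (FiO2 - FeO2) / (1 - FiO2)    [mL O2 min^-1, FR in mL min^-1 STPD]

Resting metabolism is relativised per individual as the fold change from the
value measured at thermoneutrality (30 degC), so every individual's profile
equals exactly 1 at 30 degC and among-individual variation is restricted to
the *response* to temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .datamodel import RespirometryRecord
from .errors import InputError

#: Oxy-joule equivalent: joules of heat produced per mL O2 consumed.
JOULES_PER_ML_O2 = 20.0
#: Latent heat: joules consumed per mL of liquid water evaporated.
JOULES_PER_ML_H2O = 2406.0
#: Molar mass of water (g mol^-1) over molar gas volume at STP (mL mol^-1):
#: converts a vapour volume flow to a liquid-water volume flow.
VAPOUR_TO_LIQUID = 18.016 / 22414.0

THERMONEUTRAL_C = 30.0


@dataclass
class GasTrace:
    """One chamber recording: channels sampled on a common time base.

    ``FiO2`` and ``WVPi`` describe the (dried) incurrent air and may be
    scalars; all excurrent channels are arrays aligned with ``time_s``.
    """

    time_s: np.ndarray
    FeO2: np.ndarray
    FR_ml_min: float
    FiO2: float | np.ndarray = 0.2095
    WVPe_kpa: np.ndarray | None = None
    WVPi_kpa: float = 0.0
    BP_kpa: float = 101.3
    chamber_temp_c: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.FeO2 = np.asarray(self.FeO2, dtype=float)
        if self.WVPe_kpa is not None:
            self.WVPe_kpa = np.asarray(self.WVPe_kpa, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise InputError("trace time base must be strictly increasing")
        if self.FR_ml_min <= 0:
            raise InputError("flow rate must be positive")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class EnergeticsSample:
    """Reduced energetics of one measurement."""

    vo2_ml_min: float
    ewl_ml_min: float
    mhp_w: float
    ehl_w: float
    ece: float | None

    def __post_init__(self) -> None:
        if self.vo2_ml_min < 0:
            warnings.warn("negative VO2 in EnergeticsSample", RuntimeWarning, stacklevel=2)


@dataclass(frozen=True)
class MetabolicProfile:
    """One individual's relative resting metabolism across temperatures.

    ``relative`` maps ambient temperature (degC) to the fold change from the
    30 degC value; it equals exactly 1.0 at 30 degC by construction.
    """

    id: str
    age_class: str
    relative: Mapping[float, float]
    vo2_at_30: float
    ece: Mapping[float, float] = field(default_factory=dict)


def _window_samples(time_s: np.ndarray, duration_s: float) -> int:
    dt = float(np.median(np.diff(time_s))) if time_s.size > 1 else 1.0
    return max(2, int(round(duration_s / dt)))


def stable_window(trace: GasTrace | np.ndarray, duration_s: float = 120.0) -> tuple[int, int]:
    """Locate the most stable contiguous window of ``duration_s`` seconds.

    Stability is the standard deviation of the FeO2 channel within the
    window; the window with the smallest SD wins and ties break to the
    earliest start.  Returns ``(start, stop)`` indices with ``stop``
    exclusive, so ``FeO2[start:stop]`` is the selected segment.
    """
    if isinstance(trace, GasTrace):
        values = trace.FeO2
        n = _window_samples(trace.time_s, duration_s)
    else:
        values = np.asarray(trace, dtype=float)
        n = max(2, int(round(duration_s)))
    if values.size < n:
        raise InputError(
            f"trace of {values.size} samples is shorter than the {n}-sample window"
        )
    # Rolling variance via cumulative sums (O(N)); centre first for accuracy.
    x = values - values.mean()
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[n:] - c1[:-n]
    s2 = c2[n:] - c2[:-n]
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0)
    # Earliest window within numerical jitter of the minimum.
    tol = 1e-14 * max(1.0, float(var.max(initial=0.0)))
    start = int(np.nonzero(var <= var.min() + tol)[0][0])
    return start, start + n


def vo2(FiO2, FeO2, FR_ml_min):
    """Oxygen consumption (mL O2 min^-1) with H2O and CO2 scrubbed upstream.

    A negative result (FeO2 > FiO2) is returned as-is with a warning rather
    than clamped, so instrument problems stay visible downstream.
    """
    FiO2 = np.asarray(FiO2, dtype=float)
    value = np.asarray(FR_ml_min, dtype=float) * (FiO2 - np.asarray(FeO2, dtype=float)) / (1.0 - FiO2)
    if np.any(value < 0):
        warnings.warn(
            "negative oxygen consumption (FeO2 > FiO2); returning value unclamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return value.item() if value.ndim == 0 else value


def ewl_from_wvp(WVPe_kpa, WVPi_kpa, FR_ml_min, BP_kpa):
    """Evaporative water loss as liquid-water volume (mL min^-1).

    The vapour volume flow FR*(WVPe-WVPi)/(BP-WVPe) (mL min^-1 at STP) is
    converted to liquid water via 18.016 g mol^-1 / 22414 mL mol^-1 at a
    density of 1 g mL^-1.
    """
    WVPe = np.asarray(WVPe_kpa, dtype=float)
    BP = np.asarray(BP_kpa, dtype=float)
    if np.any(WVPe >= BP):
        raise InputError("excurrent water vapour pressure must be below barometric pressure")
    vapour = np.asarray(FR_ml_min, dtype=float) * (WVPe - np.asarray(WVPi_kpa, dtype=float)) / (BP - WVPe)
    value = vapour * VAPOUR_TO_LIQUID
    return value.item() if value.ndim == 0 else value


def energetics(vo2_ml_min: float, ewl_ml_min: float) -> EnergeticsSample:
    """Convert VO2 and EWL to heat production/loss rates (W) and ECE.

    MHP = VO2 * 20/60 W and EHL = EWL * 2406/60 W; ECE = EHL/MHP is the
    fraction of metabolic heat offset evaporatively, undefined (None) when
    MHP is zero.
    """
    if vo2_ml_min < 0:
        raise InputError("VO2 must be non-negative")
    if ewl_ml_min < 0:
        raise InputError("EWL must be non-negative")
    mhp = vo2_ml_min * JOULES_PER_ML_O2 / 60.0
    ehl = ewl_ml_min * JOULES_PER_ML_H2O / 60.0
    ece = ehl / mhp if mhp > 0 else None
    return EnergeticsSample(vo2_ml_min, ewl_ml_min, mhp, ehl, ece)


def reduce_trace(
    trace: GasTrace,
    duration_s: float = 120.0,
    initial_baseline: tuple[int, int] | None = None,
    terminal_baseline: tuple[int, int] | None = None,
) -> EnergeticsSample:
    """Reduce a full trace to one :class:`EnergeticsSample`.

    The most stable window of ``duration_s`` is selected on the FeO2
    channel; VO2 and (if water vapour was recorded) EWL are computed from
    channel means over that same window.  When baseline segments are given,
    incurrent FiO2 is drift-corrected by linear interpolation between the
    mean FeO2 of the initial and terminal baselines.
    """
    start, stop = stable_window(trace, duration_s)
    if initial_baseline is not None and terminal_baseline is not None:
        b0 = slice(*initial_baseline)
        b1 = slice(*terminal_baseline)
        t0 = float(trace.time_s[b0].mean())
        t1 = float(trace.time_s[b1].mean())
        f0 = float(trace.FeO2[b0].mean())
        f1 = float(trace.FeO2[b1].mean())
        t_mid = float(trace.time_s[start:stop].mean())
        fio2 = f0 + (f1 - f0) * (t_mid - t0) / (t1 - t0) if t1 != t0 else f0
    else:
        fio2 = float(np.mean(trace.FiO2))
    feo2 = float(trace.FeO2[start:stop].mean())
    vo2_value = vo2(fio2, feo2, trace.FR_ml_min)
    if trace.WVPe_kpa is not None:
        wvpe = float(trace.WVPe_kpa[start:stop].mean())
        ewl_value = ewl_from_wvp(wvpe, trace.WVPi_kpa, trace.FR_ml_min, trace.BP_kpa)
    else:
        ewl_value = 0.0
    return energetics(max(vo2_value, 0.0) if vo2_value >= 0 else vo2_value, ewl_value)


def relativize(
    records: Iterable[RespirometryRecord],
) -> tuple[list[MetabolicProfile], list[tuple[str, str, str]]]:
    """Build per-individual relative metabolic profiles.

    Every (individual, age class) group is divided by its 30 degC VO2, so
    the profile equals exactly 1 at thermoneutrality and is invariant to
    rescaling all of an individual's measurements.  Groups lacking a 30 degC
    measurement are excluded and logged as ``(id, age_class, reason)``.
    """
    groups: dict[tuple[str, str], list[RespirometryRecord]] = {}
    for rec in records:
        groups.setdefault((rec.id, rec.age_class), []).append(rec)
    profiles: list[MetabolicProfile] = []
    excluded: list[tuple[str, str, str]] = []
    for (ind, age), recs in groups.items():
        base = [r for r in recs if r.temperature_c == THERMONEUTRAL_C]
        if not base:
            excluded.append((ind, age, "missing_thermoneutral_measurement"))
            continue
        vo2_30 = base[0].vo2_ml_min
        if vo2_30 <= 0:
            excluded.append((ind, age, "nonpositive_thermoneutral_vo2"))
            continue
        relative = {float(r.temperature_c): r.vo2_ml_min / vo2_30 for r in recs}
        ece_map: dict[float, float] = {}
        for r in recs:
            if r.ewl_ml_min is not None and not np.isnan(r.ewl_ml_min):
                sample = energetics(r.vo2_ml_min, r.ewl_ml_min)
                if sample.ece is not None:
                    ece_map[float(r.temperature_c)] = sample.ece
        profiles.append(MetabolicProfile(ind, age, relative, vo2_30, ece_map))
    return profiles, excluded
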