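"""Shared fixtures: small synthetic studies and pre-fitted models.

Model fits are session-scoped because MCMC is the expensive step; tests
assert different properties of the same posterior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from helpers import slope_frame
from quailtherm import (
    ColdSlopeModel,
    GeneratorConfig,
    PathModel,
    default_path_spec,
    generate_population,
)


@pytest.fixture(scope="session")
def tiny_study():
    """18-bird synthetic study (2 per treatment x batch)."""
    return generate_population(GeneratorConfig(n_per_group=2, seed=42))


@pytest.fixture(scope="session")
def study45():
    """45-bird synthetic study (15 per treatment, 5 per treatment x batch)."""
    return generate_population(GeneratorConfig(n_per_group=5, seed=7))


@pytest.fixture(scope="session")
def cold_fit():
    """Cold slope fit on 40 individuals with known generating values."""
    frame = slope_frame(40, -0.018, 0.005, {10.0: 0.15, 20.0: 0.10}, seed=21)
    return ColdSlopeModel(frame).fit(chains=2, draws=600, seed=4)


@pytest.fixture(scope="session")
def adult_heat_path(study45):
    """Full four-equation adult heat path fit on the 45-bird study."""
    data, truth = study45
    table = _adult_heat_table(data, truth)
    spec = default_path_spec("adult", "heat_slope")
    fit = PathModel(table, spec).fit(chains=2, draws=600, seed=11)
    return table, truth, fit


def _adult_heat_table(data, truth) -> pd.DataFrame:
    morph = data.morphometry.query("age_weeks == 8")[["id", "mass_g", "tarsus_mm", "bill_mm"]]
    morph = morph.rename(columns={"mass_g": "mass", "tarsus_mm": "tarsus", "bill_mm": "bill"})
    table = data.individuals.merge(morph, on="id")
    resp40 = data.respirometry.query("age_class == 'adult' and temperature_c == 40")
    resp30 = data.respirometry.query("age_class == 'adult' and temperature_c == 30")
    rel40 = resp40.merge(resp30[["id", "vo2_ml_min"]], on="id", suffixes=("", "_30"))
    rel40["heat_slope"] = (rel40["vo2_ml_min"] / rel40["vo2_ml_min_30"] - 1.0) / 10.0
    return table.merge(rel40[["id", "heat_slope"]], on="id")
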