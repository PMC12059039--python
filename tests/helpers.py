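"""Small data-construction helpers shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd


def slope_frame(n: int, beta1: float, sigma_v: float, sigma_eps, seed: int, pivot: float = 30.0):
    """Independent cold-response data generator used for recovery checks.

    Builds relative-metabolism rows from an explicit linear model through
    the pivot, bypassing the package's own synthetic generator so recovery
    tests have an oracle that shares no code with the implementation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n):
        slope = beta1 + sigma_v * rng.standard_normal()
        for t, sd in sigma_eps.items():
            rows.append(
                {
                    "id": f"q{j:03d}",
                    "temperature_c": t,
                    "relative": 1.0 + slope * (t - pivot) + sd * rng.standard_normal(),
                }
            )
        rows.append({"id": f"q{j:03d}", "temperature_c": 30.0, "relative": 1.0})
    return pd.DataFrame(rows)
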