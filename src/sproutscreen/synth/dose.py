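"""Synthetic dose-response series.

Responses follow the four-parameter logistic (4PL)

    r(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

with multiplicative log-normal noise, generated in duplicate per
concentration.  The default concentration series is an 8-point 4-fold
serial dilution from 10 µM (10000, 2500, 625, 156.25, 39.06, 9.77, 2.44,
0.61 nM).  Micro-vessel nuclei counts — the toxicity readout — are drawn
around a baseline with an optional planted decay that grows linearly in
log-concentration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import TAG_DOSE, substream
from ..dose_response import four_pl


def default_series(top_nM: float = 10_000.0, fold: float = 4.0, n_points: int = 8) -> np.ndarray:
    """Serial-dilution concentration series, highest first, in nM."""
    return top_nM / fold ** np.arange(n_points)


def generate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 0.0,
    bottom: float = -20.0,
    series: np.ndarray | list[float] | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
    n_replicates: int = 2,
    count_base: float = 150.0,
    count_decay: float = 0.0,
    count_cv: float = 0.08,
    compound_id: str = "CMPD",
) -> pd.DataFrame:
    """Simulate a duplicate dose series of Z*-scale responses.

    ``count_decay`` is the fraction of the vessel nuclei count lost at the
    top concentration relative to the lowest (0 = stable vessel).

    Returns a DataFrame with columns
    ``compound_id, concentration_nM, replicate, response, vessel_nuclei_count``.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    series = np.asarray(default_series() if series is None else series, dtype=float)
    if series.size < 4:
        raise ValueError("series must contain at least 4 concentrations")
    if np.any(series <= 0):
        raise ValueError("all concentrations must be > 0")

    rng = substream(seed, TAG_DOSE)
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0
    csigma = float(np.sqrt(np.log1p(count_cv**2))) if count_cv > 0 else 0.0

    logc = np.log(series)
    logpos = (logc - logc.min()) / (logc.max() - logc.min()) if series.size > 1 else logc * 0

    rows = []
    for i, c in enumerate(series):
        mean_r = four_pl(c, top=top, bottom=bottom, ic50=ic50, hill=hill)
        mean_count = count_base * (1.0 - count_decay * logpos[i])
        for rep in range(1, n_replicates + 1):
            noise = np.exp(sigma * rng.standard_normal()) if sigma > 0 else 1.0
            cnoise = np.exp(csigma * rng.standard_normal()) if csigma > 0 else 1.0
            rows.append(
                {
                    "compound_id": compound_id,
                    "concentration_nM": float(c),
                    "replicate": rep,
                    "response": float(mean_r * noise),
                    "vessel_nuclei_count": int(round(mean_count * cnoise)),
                }
            )
    return pd.DataFrame(rows)
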