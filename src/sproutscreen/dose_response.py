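"""Four-parameter logistic (4PL) dose-response fitting and toxicity profiling.

The model is

    r(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

fit by least squares on log-concentration with multi-start initialisation
over the IC50 grid and both hill orientations.  Replicates are pooled in
the residuals, not averaged first.  IC50 is the midpoint concentration
regardless of curve direction.  Micro-vessel nuclei counts at each
concentration are the toxicity readout: a series is "stable" when no
concentration's mean count falls below a configured fraction of the
vehicle reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def four_pl(c, top: float, bottom: float, ic50: float, hill: float):
    """4PL response at concentration ``c`` (same units as ``ic50``)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass(frozen=True)
class FitResult:
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    residual_sd: float

    def __post_init__(self) -> None:
        if self.converged and self.ic50 <= 0:
            raise ValueError("converged fit must have ic50 > 0")


def _residuals(params: np.ndarray, logc: np.ndarray, resp: np.ndarray) -> np.ndarray:
    top, bottom, log_ic50, hill = params
    expo = np.clip(hill * (logc - log_ic50), -500.0, 500.0)
    pred = bottom + (top - bottom) / (1.0 + np.exp(expo))
    return pred - resp


def fit_4pl(
    concentrations: np.ndarray | list[float],
    responses: np.ndarray | list[float],
) -> FitResult:
    """Fit a 4PL curve to pooled dose-response points.

    Parameters are estimated on natural-log concentration with a
    multi-start over candidate midpoints (every observed concentration)
    and both hill signs; the best least-squares solution wins.  Flat data
    (no detectable dose dependence) returns ``converged=False`` with the
    grand mean as both asymptotes rather than raising.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    logc = np.log(c)
    spread = r.max() - r.min()
    if spread == 0:
        return FitResult(float(np.exp(np.median(logc))), 0.0, float(r[0]), float(r[0]),
                         converged=False, residual_sd=0.0)

    best = None
    order = np.argsort(logc)
    r_lo_end = r[order][: max(1, len(r) // 4)].mean()   # low-concentration side
    r_hi_end = r[order][-max(1, len(r) // 4):].mean()
    for log_mid in np.unique(logc):
        for hill0 in (1.0, -1.0, 2.0, -2.0):
            x0 = np.array([r_lo_end, r_hi_end, log_mid, hill0])
            try:
                sol = least_squares(_residuals, x0, args=(logc, r), method="lm",
                                    max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return FitResult(float(np.exp(np.median(logc))), 0.0, float(r.mean()),
                         float(r.mean()), converged=False, residual_sd=float(r.std()))

    top, bottom, log_ic50, hill = best.x
    n_par = 4
    dof = max(1, r.size - n_par)
    residual_sd = float(np.sqrt(2 * best.cost / dof))

    # orientation normalisation: report top >= bottom with hill flipped
    if top < bottom:
        top, bottom, hill = bottom, top, -hill

    # honesty of the converged flag: the curve must actually separate its
    # asymptotes from the noise and keep its midpoint near the sampled range
    dynamic = abs(top - bottom)
    in_range = logc.min() - np.log(50.0) <= log_ic50 <= logc.max() + np.log(50.0)
    converged = bool(best.success and dynamic > 3.0 * residual_sd and in_range
                     and abs(hill) > 1e-3)
    ic50 = float(np.exp(log_ic50))
    return FitResult(ic50=ic50, hill=float(hill), top=float(top), bottom=float(bottom),
                     converged=converged, residual_sd=residual_sd)


def fit_series(series: pd.DataFrame, response_col: str = "response") -> FitResult:
    """Fit a tidy dose-series table (columns ``concentration_nM``, response)."""
    return fit_4pl(series["concentration_nM"].to_numpy(),
                   series[response_col].to_numpy())


def plot_fit(series: pd.DataFrame, fit: FitResult, path,
             response_col: str = "response") -> None:
    """Save a dose-response plot: observed points and the fitted 4PL curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = series["concentration_nM"].to_numpy()
    r = series[response_col].to_numpy()
    grid = np.geomspace(c.min() / 4, c.max() * 4, 200)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(c, r, "o", alpha=0.7, label="observed")
    ax.semilogx(grid, four_pl(grid, fit.top, fit.bottom, fit.ic50, fit.hill),
                "-", label=f"4PL fit (IC50 = {fit.ic50:.3g} nM)")
    ax.axvline(fit.ic50, ls=":", color="gray")
    ax.set_xlabel("concentration (nM)")
    ax.set_ylabel(response_col)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class ToxicityProfile:
    classification: str                   # 'stable' or 'declining'
    lowest_declining_nM: float | None     # lowest concentration breaching the floor
    per_concentration: pd.DataFrame       # concentration_nM, mean_count, sd_count


def toxicity_profile(
    series: pd.DataFrame,
    vehicle_mean_count: float,
    stable_fraction: float = 0.8,
) -> ToxicityProfile:
    """Classify the vessel nuclei-count dose profile as stable or declining.

    The series is 'stable' when every concentration's mean count stays at
    or above ``stable_fraction`` of the vehicle reference; otherwise it is
    'declining' and the lowest offending concentration is reported.
    """
    if "vessel_nuclei_count" not in series.columns or series["vessel_nuclei_count"].isna().any():
        raise ValueError("vessel nuclei counts missing from the dose series")
    if vehicle_mean_count <= 0:
        raise ValueError("vehicle_mean_count must be > 0")
    per = (
        series.groupby("concentration_nM")["vessel_nuclei_count"]
        .agg(mean_count="mean", sd_count="std")
        .reset_index()
        .sort_values("concentration_nM", ignore_index=True)
    )
    floor = stable_fraction * vehicle_mean_count
    offending = per[per["mean_count"] < floor]
    if offending.empty:
        return ToxicityProfile("stable", None, per)
    return ToxicityProfile("declining", float(offending["concentration_nM"].iloc[0]), per)
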