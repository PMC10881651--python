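"""Screen-level statistics.

Per-chip sprouting is summarised by D10, the mean longitudinal position of
the ten sprout-region nuclei furthest from the micro-vessel.  Chips are
normalised against the vehicle controls of their plate with a robust Z*
score,

    Z* = (D10 - median_vehicle) / MAD_vehicle,

where MAD is the raw median absolute deviation (no normal-consistency
constant by default — the score counts MADs from the vehicle median).
Z* maps onto ordinal inhibition levels, and assay quality is summarised by
the Z' factor, control CVs, duplicate Spearman correlation and duplicate
integrity-score concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .imaging import NucleusRecord

#: Z* boundaries of the ordinal inhibition levels (left-closed severity:
#: a score exactly on a boundary takes the more severe level).
INHIBITION_BOUNDARIES = {"mild": -3.0, "moderate": -9.0, "high": -15.0}
INHIBITION_LEVELS = ("none", "mild", "moderate", "high")

MAD_NORMAL_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class ChipMeasurement:
    """Per-chip measurement with its screening metadata."""

    chip_id: str
    plate_id: str
    role: str                      # vehicle / sunitinib_control / unstimulated / sample
    d10_um: float
    vessel_nuclei_count: int
    qc_score: int
    integrity_score: int
    compound_id: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.d10_um < 0:
            raise ValueError("d10_um must be >= 0")
        for name in ("qc_score", "integrity_score"):
            if getattr(self, name) not in (1, 2, 3, 4):
                raise ValueError(f"{name} must be in 1..4")


@dataclass(frozen=True)
class PlateStats:
    """Vehicle-control location/scale of one plate (or pooled batch)."""

    plate_id: str
    vehicle_median_d10: float
    vehicle_mad_d10: float
    n_vehicle: int
    pooled_fallback: bool = False  # True when batch-pooled vehicles were used

    def __post_init__(self) -> None:
        if self.n_vehicle < 2:
            raise ValueError("plate statistics need >= 2 vehicle chips")
        if self.vehicle_mad_d10 < 0:
            raise ValueError("MAD must be >= 0")

    @property
    def degenerate(self) -> bool:
        return self.vehicle_mad_d10 == 0.0


@dataclass(frozen=True)
class ZScoreResult:
    chip_id: str
    z_star: float
    inhibition_level: str


def d10(sprout_nuclei: Iterable[NucleusRecord] | Sequence[float] | np.ndarray) -> float:
    """Mean longitudinal position (µm) of the ten furthest sprout nuclei.

    Accepts nucleus records or raw y-values.  Fewer than ten nuclei
    average over all present; no nuclei gives 0.
    """
    ys = np.asarray(
        [n.centroid_y if isinstance(n, NucleusRecord) else float(n) for n in sprout_nuclei],
        dtype=float,
    )
    if ys.size == 0:
        return 0.0
    k = min(10, ys.size)
    top = np.partition(ys, ys.size - k)[-k:]
    return float(top.mean())


def plate_stats(
    vehicle_d10: Sequence[float],
    plate_id: str = "",
    pooled_fallback: bool = False,
) -> PlateStats:
    """Median and raw MAD of a plate's vehicle-control D10 values."""
    vals = np.asarray(vehicle_d10, dtype=float)
    if vals.size < 2:
        raise ValueError(f"plate {plate_id!r}: need >= 2 vehicle chips, got {vals.size}")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return PlateStats(plate_id=plate_id, vehicle_median_d10=med,
                      vehicle_mad_d10=mad, n_vehicle=int(vals.size),
                      pooled_fallback=pooled_fallback)


def robust_z(d10_um: float, stats: PlateStats, consistency: bool = False) -> float:
    """Robust Z* of one chip against its plate's vehicle statistics.

    ``consistency=True`` scales the MAD by 1.4826 so Z* is on an
    equivalent-standard-deviation scale.
    """
    mad = stats.vehicle_mad_d10 * (MAD_NORMAL_CONSISTENCY if consistency else 1.0)
    if mad <= 0:
        raise ZeroDivisionError(
            f"plate {stats.plate_id!r}: vehicle MAD is zero, Z* undefined"
        )
    return float((d10_um - stats.vehicle_median_d10) / mad)


def classify_inhibition(z_star: float) -> str:
    """Ordinal inhibition level of a Z* score.

    none: Z* > -3; mild: -9 < Z* <= -3; moderate: -15 < Z* <= -9;
    high: Z* <= -15.  Boundary values take the more severe level.
    """
    if not np.isfinite(z_star):
        raise ValueError(f"z_star must be finite, got {z_star}")
    if z_star <= INHIBITION_BOUNDARIES["high"]:
        return "high"
    if z_star <= INHIBITION_BOUNDARIES["moderate"]:
        return "moderate"
    if z_star <= INHIBITION_BOUNDARIES["mild"]:
        return "mild"
    return "none"


def z_prime(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Z' assay-quality factor between two control groups.

    Z' = 1 - 3 (sigma_a + sigma_b) / |mu_a - mu_b| with sample standard
    deviations (ddof=1); always <= 1, higher is better separation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both control groups need n >= 2")
    sep = abs(a.mean() - b.mean())
    if sep == 0:
        raise ZeroDivisionError("control groups have equal means: Z' undefined")
    return float(1.0 - 3.0 * (a.std(ddof=1) + b.std(ddof=1)) / sep)


def control_cv(group: Sequence[float]) -> float:
    """Coefficient of variation of a control group, in percent."""
    g = np.asarray(group, dtype=float)
    if g.size < 2:
        raise ValueError("CV needs n >= 2")
    mean = g.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * g.std(ddof=1) / mean)


def replicate_spearman(pairs: Sequence[tuple[float, float]]) -> float:
    """Spearman rank correlation between duplicate Z* scores.

    Pairs containing a non-finite value (an excluded replicate) are
    dropped before the correlation; fewer than 3 complete pairs raise.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    keep = np.isfinite(arr).all(axis=1)
    arr = arr[keep]
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 complete pairs, got {arr.shape[0]}")
    rho, _ = sps.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho)


def integrity_concordance(
    pairs: Sequence[tuple[int, int]],
) -> tuple[float, float, float]:
    """Duplicate agreement of ordinal integrity scores.

    Returns percentages of pairs that are identical, adjacent (differ by
    one level) and discordant (differ by two or more); the three sum
    to 100.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if arr.size == 0:
        return (0.0, 0.0, 0.0)
    diff = np.abs(arr[:, 0] - arr[:, 1])
    n = arr.shape[0]
    same = float(100.0 * np.sum(diff == 0) / n)
    adjacent = float(100.0 * np.sum(diff == 1) / n)
    discordant = float(100.0 * np.sum(diff >= 2) / n)
    return (same, adjacent, discordant)
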