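"""Per-chip phenotype sampling.

The biological model behind the generator:

* A chip's sprouting extent ``true_D10`` (mean longitudinal position of the
  ten furthest sprout-region nuclei) is drawn from a log-normal whose median
  and CV are role-specific calibration constants: vehicle controls sprout a
  median 352.1 µm at CV 12.1 %, Sunitinib-like strong-inhibition controls
  62.2 µm, unstimulated controls stay short at CV 14.1 %.  Sample chips
  scale the vehicle median by the compound's planted ``inhibition_effect``.
* The two replicate chips of a compound share a latent standard-normal
  effect draw mixed with independent chip noise at correlation ``rho``,
  reproducing the replicate concordance structure of a duplicate screen.
* Nuclei are placed as a dense band in the vessel channel plus nuclei along
  simulated sprout paths; the ten frontier nuclei are placed so that their
  mean longitudinal position equals the drawn ``true_D10`` exactly.
* Vessel-integrity and QC scores are ordinal 1-4 expert labels: integrity
  is centred on ``5 - toxicity_class`` and jittered by one level with a
  configurable flip probability; QC is drawn from a categorical
  distribution calibrated to a ~96.5 % pass rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .._rng import TAG_CHIP, substream
from ..geometry import ChipGeometry
from .library import CompoundTruth

CONTROL_ROLES = ("vehicle", "sunitinib_control", "unstimulated")


@dataclass(frozen=True)
class NoiseParams:
    """Calibration and noise of the phenotype generator.

    Medians are in µm; CVs are fractional (0.121 = 12.1 %).
    """

    vehicle_median: float = 352.1
    vehicle_cv: float = 0.121
    sunitinib_median: float = 62.2
    sunitinib_cv: float = 0.20
    unstimulated_median: float = 45.0
    unstimulated_cv: float = 0.141
    replicate_rho: float = 0.85          # latent-effect correlation of duplicates
    score_flip_prob: float = 0.2         # P(expert score deviates +-1 level)
    qc_probs: tuple[float, float, float, float] = (0.005, 0.03, 0.165, 0.8)
    vessel_nuclei_base: int = 150        # healthy-vessel nuclei count
    vessel_count_cv: float = 0.10
    toxicity_count_loss: float = 0.12    # count fraction lost per toxicity level
    n_sprouts: int = 10                  # sprout paths per chip
    nucleus_spacing: float = 25.0        # µm between stalk nuclei along a sprout
    frontier_spread: float = 0.05        # relative y-spread of the ten frontier nuclei

    def __post_init__(self) -> None:
        for name in ("vehicle_cv", "sunitinib_cv", "unstimulated_cv", "vessel_count_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.replicate_rho <= 1.0:
            raise ValueError("replicate_rho must be in [0, 1]")
        if not 0.0 <= self.score_flip_prob <= 1.0:
            raise ValueError("score_flip_prob must be in [0, 1]")
        if abs(sum(self.qc_probs) - 1.0) > 1e-9:
            raise ValueError("qc_probs must sum to 1")

    def noiseless_scores(self) -> "NoiseParams":
        """Variant with deterministic expert scores (no measurement noise)."""
        return replace(self, score_flip_prob=0.0, qc_probs=(0.0, 0.0, 0.0, 1.0))


@dataclass(frozen=True)
class ChipPhenotype:
    """Ground truth for one simulated chip."""

    chip_id: str
    role: str
    compound_id: str | None
    true_d10: float                      # µm
    vessel_nuclei: np.ndarray            # (n, 2) array of (x µm, y µm), y <= 0
    sprout_nuclei: np.ndarray            # (n, 2) array of (x µm, y µm), y > 0
    integrity_score: int
    qc_score: int

    def __post_init__(self) -> None:
        if self.true_d10 < 0:
            raise ValueError("true_d10 must be >= 0")
        for name in ("integrity_score", "qc_score"):
            if getattr(self, name) not in (1, 2, 3, 4):
                raise ValueError(f"{name} must be in 1..4")

    @property
    def vessel_nuclei_count(self) -> int:
        return len(self.vessel_nuclei)

    @property
    def n_nuclei(self) -> int:
        return len(self.vessel_nuclei) + len(self.sprout_nuclei)

    def all_nuclei(self) -> np.ndarray:
        """(n, 2) positions of every nucleus, vessel band first."""
        return np.vstack([self.vessel_nuclei.reshape(-1, 2),
                          self.sprout_nuclei.reshape(-1, 2)])


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _role_calibration(role: str, truth: CompoundTruth | None, noise: NoiseParams) -> tuple[float, float]:
    if role == "vehicle":
        return noise.vehicle_median, noise.vehicle_cv
    if role == "sunitinib_control":
        return noise.sunitinib_median, noise.sunitinib_cv
    if role == "unstimulated":
        return noise.unstimulated_median, noise.unstimulated_cv
    if role == "sample":
        if truth is None:
            raise ValueError("sample chips require a CompoundTruth")
        return noise.vehicle_median * truth.inhibition_effect, noise.vehicle_cv
    raise ValueError(f"unknown chip role {role!r}")


def _ordinal_score(center: int, flip_prob: float, rng: np.random.Generator) -> int:
    score = center
    if flip_prob > 0 and rng.random() < flip_prob:
        score += int(rng.choice([-1, 1]))
    return int(np.clip(score, 1, 4))


def _place_vessel_nuclei(
    count: int, geometry: ChipGeometry, rng: np.random.Generator, min_sep: float = 12.0
) -> np.ndarray:
    """Dart-throwing placement of the micro-vessel nuclei band (limited retries)."""
    if count <= 0:
        return np.empty((0, 2))
    margin = 8.0
    y_lo = -geometry.vessel_band_depth + margin
    y_hi = -geometry.phaseguide_width - margin
    pts: list[tuple[float, float]] = []
    for _ in range(count):
        for _ in range(25):
            x = rng.uniform(margin, geometry.image_width - margin)
            y = rng.uniform(y_lo, y_hi)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts[-60:]):
                pts.append((x, y))
                break
        else:
            pts.append((x, y))  # dense band: accept the overlap
    return np.array(pts)


def _place_sprout_nuclei(
    target_d10: float,
    geometry: ChipGeometry,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Place sprout-path nuclei whose ten furthest average exactly the target.

    Returns the (n, 2) positions and the realised true D10 (equal to the
    clipped target up to float rounding).
    """
    max_y = geometry.sprout_region_depth - 8.0
    target = float(np.clip(target_d10, 0.0, max_y))

    n_lanes = noise.n_sprouts
    margin = 15.0
    lane_x = np.linspace(margin, geometry.image_width - margin, n_lanes)
    lane_x = lane_x + rng.uniform(-4, 4, size=n_lanes)

    if target <= 1.0:
        # fully inhibited: a few nuclei hugging the vessel boundary
        n = 10
        x = rng.uniform(margin, geometry.image_width - margin, size=n)
        y = rng.uniform(0.3, 1.5, size=n)
        pts = np.column_stack([x, y])
        top = np.sort(y)[-10:]
        return pts, float(np.mean(top))

    # ten frontier nuclei: zero-mean offsets around the target, scaled so no
    # nucleus is clipped, then distributed over distinct lanes
    spread = noise.frontier_spread * target
    offsets = rng.normal(0.0, spread, size=10)
    offsets -= offsets.mean()
    limit = min(max_y - target, target - 1.0)
    omax = np.max(np.abs(offsets))
    if omax > 0 and omax > limit:
        offsets *= limit / omax
    frontier_y = target + offsets
    reps = -(-10 // n_lanes)  # one frontier tip per lane when n_lanes >= 10
    lanes = np.concatenate([rng.permutation(n_lanes) for _ in range(reps)])[:10]
    frontier_x = lane_x[lanes] + rng.uniform(-5, 5, size=10)
    frontier = np.column_stack([np.clip(frontier_x, 2.0, geometry.image_width - 2.0),
                                frontier_y])

    # stalk nuclei along each sprout path, kept below the frontier so the
    # ten frontier nuclei remain the furthest
    stalk_top = float(frontier_y.min()) - 1.5 * noise.nucleus_spacing
    stalk_pts: list[tuple[float, float]] = []
    if stalk_top > noise.nucleus_spacing:
        for lx in lane_x:
            n_stalk = int(stalk_top // noise.nucleus_spacing)
            ys = (np.arange(1, n_stalk + 1) * noise.nucleus_spacing
                  + rng.uniform(-5, 5, size=n_stalk))
            xs = lx + rng.uniform(-6, 6, size=n_stalk)
            for x, y in zip(xs, ys):
                if 0.5 < y < stalk_top + 8:
                    stalk_pts.append((float(np.clip(x, 2.0, geometry.image_width - 2.0)),
                                      float(y)))
    pts = np.vstack([frontier, np.array(stalk_pts).reshape(-1, 2)])
    top10 = np.sort(pts[:, 1])[-10:]
    return pts, float(np.mean(top10))


def sample_phenotype(
    role: str,
    geometry: ChipGeometry,
    noise: NoiseParams,
    seed: int,
    chip_index: tuple[int, int] = (0, 0),
    truth: CompoundTruth | None = None,
    latent_z: float | None = None,
    chip_id: str = "chip",
) -> ChipPhenotype:
    """Draw one chip's ground-truth phenotype.

    Parameters
    ----------
    role : {'vehicle', 'sunitinib_control', 'unstimulated', 'sample'}
    geometry, noise : calibration of chip and generator.
    seed : top-level seed; the chip substream is derived from
        ``(seed, plate_index, chip_index)`` so layouts can grow without
        perturbing existing chips.
    chip_index : (plate_index, position) pair identifying the substream.
    truth : planted compound effect; required for sample chips.
    latent_z : standard-normal latent effect shared by a compound's two
        replicates (mixed in at correlation ``noise.replicate_rho``);
        ``None`` leaves the chip fully independent.
    """
    rng = substream(seed, TAG_CHIP, *chip_index)
    median, cv = _role_calibration(role, truth, noise)

    sigma = _lognormal_sigma(cv)
    eps = float(rng.standard_normal())
    if latent_z is not None:
        rho = noise.replicate_rho
        z = np.sqrt(rho) * latent_z + np.sqrt(1.0 - rho) * eps
    else:
        z = eps
    target = median * float(np.exp(sigma * z)) if median > 0 else 0.0

    sprout, true_d10 = _place_sprout_nuclei(target, geometry, noise, rng)

    if role == "sample":
        tox = truth.toxicity_class
        integrity_center = 5 - tox
    elif role == "sunitinib_control":
        tox, integrity_center = 2, 3   # strong inhibitor with mild vessel stress
    else:
        tox, integrity_center = 1, 4
    integrity = _ordinal_score(integrity_center, noise.score_flip_prob, rng)
    qc = int(rng.choice([1, 2, 3, 4], p=noise.qc_probs))

    count_scale = max(0.2, 1.0 - noise.toxicity_count_loss * (tox - 1))
    count_noise = (np.exp(_lognormal_sigma(noise.vessel_count_cv) * rng.standard_normal())
                   if noise.vessel_count_cv > 0 else 1.0)
    count = int(round(noise.vessel_nuclei_base * count_scale * count_noise))
    vessel = _place_vessel_nuclei(count, geometry, rng)

    return ChipPhenotype(
        chip_id=chip_id,
        role=role,
        compound_id=truth.compound_id if (role == "sample" and truth) else None,
        true_d10=true_d10,
        vessel_nuclei=vessel,
        sprout_nuclei=sprout,
        integrity_score=integrity,
        qc_score=qc,
    )
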