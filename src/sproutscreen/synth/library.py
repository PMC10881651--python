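"""Compound library with planted ground-truth effects.

Each compound carries an inhibition effect (a multiplier on the mean sprout
extent: 1 leaves sprouting untouched, 0 abolishes it), an ordinal toxicity
class 1-4 governing micro-vessel integrity scores and nuclei counts
(1 = benign, 4 = vessel-destroying), and a set of main-pathway annotations
drawn from a 15-label vocabulary mimicking a vendor kinase-library
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import TAG_LIBRARY, substream

#: Default controlled vocabulary of main pathways (15 labels).
MAIN_PATHWAYS: tuple[str, ...] = (
    "MAPK/ERK",
    "Wnt",
    "PI3K/Akt/mTOR",
    "Cell Cycle/DNA Damage",
    "Apoptosis",
    "Autophagy",
    "JAK/STAT",
    "NF-kB",
    "Hedgehog",
    "Notch",
    "TGF-beta/Smad",
    "Hippo",
    "Protein Tyrosine Kinase/RTK",
    "Cytoskeletal Signaling",
    "Angiogenesis",
)


@dataclass(frozen=True)
class CompoundTruth:
    """Planted ground truth for one library compound."""

    compound_id: str
    inhibition_effect: float  # fraction of vehicle mean sprout extent remaining
    toxicity_class: int       # 1 (benign) .. 4 (vessel-destroying)
    pathway_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.inhibition_effect <= 1.0:
            raise ValueError(f"inhibition_effect must be in [0, 1], got {self.inhibition_effect}")
        if self.toxicity_class not in (1, 2, 3, 4):
            raise ValueError(f"toxicity_class must be in 1..4, got {self.toxicity_class}")
        if not self.pathway_set:
            raise ValueError("pathway_set must be non-empty")

    @property
    def is_planted_hit(self) -> bool:
        """A safe strong inhibitor: the verdict a perfect screen should call 'hit'."""
        return self.inhibition_effect <= 0.2 and self.toxicity_class <= 2

    @property
    def is_planted_toxic(self) -> bool:
        return self.toxicity_class >= 3


@dataclass(frozen=True)
class EffectMixture:
    """Composition of planted effects across the library.

    Fractions of strong safe inhibitors, vessel-toxic compounds, and
    inactive-to-mild compounds; must sum to 1.
    """

    frac_hit: float = 0.10
    frac_toxic: float = 0.45
    frac_inactive: float = 0.45

    def __post_init__(self) -> None:
        total = self.frac_hit + self.frac_toxic + self.frac_inactive
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {total}")


def _draw_pathways(rng: np.random.Generator, vocabulary: tuple[str, ...]) -> frozenset[str]:
    # compounds hit 1-5 main pathways; small sets dominate
    k = int(rng.choice([1, 1, 1, 2, 2, 3, 4, 5]))
    idx = rng.choice(len(vocabulary), size=k, replace=False)
    return frozenset(vocabulary[i] for i in idx)


def generate_library(
    n_compounds: int,
    seed: int,
    mixture: EffectMixture | None = None,
    vocabulary: tuple[str, ...] = MAIN_PATHWAYS,
) -> list[CompoundTruth]:
    """Generate ``n_compounds`` compounds with planted effects, deterministically.

    Compound identities are ``C0001`` ... and their class (hit-like, toxic,
    inactive) is assigned by deterministic proportion of the mixture, with
    per-compound parameters drawn from the library substream of ``seed``.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    mixture = mixture or EffectMixture()
    rng = substream(seed, TAG_LIBRARY)

    n_hit = int(round(mixture.frac_hit * n_compounds))
    n_toxic = int(round(mixture.frac_toxic * n_compounds))
    classes = (["hit"] * n_hit + ["toxic"] * n_toxic
               + ["inactive"] * (n_compounds - n_hit - n_toxic))
    rng.shuffle(classes)

    compounds: list[CompoundTruth] = []
    for i, cls in enumerate(classes, start=1):
        if cls == "hit":
            effect = float(rng.uniform(0.05, 0.2))
            tox = int(rng.integers(1, 3))  # 1 or 2
        elif cls == "toxic":
            # toxic compounds often also suppress sprouting
            effect = float(rng.uniform(0.0, 0.8))
            tox = int(rng.integers(3, 5))  # 3 or 4
        else:
            effect = float(rng.uniform(0.6, 1.0))
            tox = int(rng.integers(1, 3))
        compounds.append(
            CompoundTruth(
                compound_id=f"C{i:04d}",
                inhibition_effect=effect,
                toxicity_class=tox,
                pathway_set=_draw_pathways(rng, vocabulary),
            )
        )
    return compounds
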