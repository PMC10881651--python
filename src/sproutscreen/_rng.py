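"""Deterministic random-stream derivation.

Every stochastic stage draws from a substream derived from the single
top-level seed plus a stable tuple of small integers (a stage tag and
indices such as plate or chip number).  Adding plates or compounds to a
run therefore never changes the draws of existing chips.
"""

from __future__ import annotations

import numpy as np

# stage tags for substream derivation
TAG_LIBRARY = 1
TAG_LAYOUT = 2
TAG_CHIP = 3
TAG_COMPOUND_LATENT = 4
TAG_RENDER = 5
TAG_DOSE = 6


def substream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream identified by ``(seed, *key)``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
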