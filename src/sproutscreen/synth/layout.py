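"""Plate layouts: 64-slot plates with a fixed control composition.

Every plate carries 8 vehicle controls, 4 Sunitinib-like strong-inhibition
controls and 4 unstimulated controls; the remaining 48 slots hold sample
chips.  Each compound is screened in duplicate, with the two replicate
chips placed on different plates whenever more than one plate exists.
When the library does not fill every sample slot, the spare slots stay
empty (no chip record is emitted for them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import TAG_LAYOUT, substream

CHIPS_PER_PLATE = 64
CONTROL_COUNTS = {"vehicle": 8, "sunitinib_control": 4, "unstimulated": 4}
SAMPLES_PER_PLATE = CHIPS_PER_PLATE - sum(CONTROL_COUNTS.values())  # 48

ROLES = ("vehicle", "sunitinib_control", "unstimulated", "sample")


@dataclass(frozen=True)
class ChipSlot:
    chip_id: str
    plate_id: str
    position: int  # 0..63 within the plate
    role: str
    compound_id: str | None = None  # samples only
    replicate: int | None = None    # 1 or 2, samples only

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if (self.role == "sample") != (self.compound_id is not None):
            raise ValueError("compound_id must be set iff role == 'sample'")


@dataclass(frozen=True)
class PlateLayout:
    plate_id: str
    chips: tuple[ChipSlot, ...]

    def __post_init__(self) -> None:
        if len(self.chips) > CHIPS_PER_PLATE:
            raise ValueError(f"plate holds at most {CHIPS_PER_PLATE} chips")
        counts = self.role_counts()
        for role, expected in CONTROL_COUNTS.items():
            if counts.get(role, 0) != expected:
                raise ValueError(
                    f"plate {self.plate_id}: expected {expected} {role} chips, "
                    f"got {counts.get(role, 0)}"
                )
        if counts.get("sample", 0) > SAMPLES_PER_PLATE:
            raise ValueError(f"plate {self.plate_id}: more than {SAMPLES_PER_PLATE} sample chips")

    def role_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.chips:
            out[c.role] = out.get(c.role, 0) + 1
        return out


class LayoutCapacityError(ValueError):
    """Raised when the requested library does not fit on the requested plates."""


def generate_layout(
    n_plates: int,
    compound_ids: list[str] | int,
    seed: int,
) -> list[PlateLayout]:
    """Assign controls and duplicate sample chips to plates, deterministically.

    Parameters
    ----------
    n_plates : int
        Number of 64-slot plates.
    compound_ids : list of str, or int
        Compound identifiers to place (an int generates ``C0001``-style ids).
    seed : int
        Slot shuffling and plate assignment derive from this seed only.

    Each compound occupies exactly two sample chips; the two replicates are
    placed on distinct plates whenever ``n_plates > 1`` and capacity allows.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if isinstance(compound_ids, int):
        compound_ids = [f"C{i:04d}" for i in range(1, compound_ids + 1)]
    n_compounds = len(compound_ids)
    capacity = n_plates * SAMPLES_PER_PLATE
    if 2 * n_compounds > capacity:
        needed = -(-2 * n_compounds // SAMPLES_PER_PLATE)  # ceil
        raise LayoutCapacityError(
            f"{n_compounds} compounds need {2 * n_compounds} sample chips but "
            f"{n_plates} plate(s) provide {capacity}; at least {needed} plates required"
        )

    rng = substream(seed, TAG_LAYOUT)

    free = np.full(n_plates, SAMPLES_PER_PLATE, dtype=int)
    order = list(range(n_compounds))
    rng.shuffle(order)

    # each replicate goes to the emptiest eligible plate, the second
    # avoiding the first's plate whenever another plate has room
    assignments: dict[str, tuple[int, int]] = {}
    for ci in order:
        cid = compound_ids[ci]
        p1 = int(np.argmax(free))
        free[p1] -= 1
        if n_plates > 1:
            masked = free.copy()
            masked[p1] = -1
            p2 = int(np.argmax(masked))
            if masked[p2] <= 0:  # no room elsewhere: fall back to p1's plate
                p2 = int(np.argmax(free))
        else:
            p2 = p1
        free[p2] -= 1
        assignments[cid] = (p1, p2)

    per_plate: list[list[tuple[str, str | None, int | None]]] = [[] for _ in range(n_plates)]
    for p in range(n_plates):
        for role, count in CONTROL_COUNTS.items():
            per_plate[p].extend((role, None, None) for _ in range(count))
    for cid, (p1, p2) in sorted(assignments.items()):
        per_plate[p1].append(("sample", cid, 1))
        per_plate[p2].append(("sample", cid, 2))

    plates: list[PlateLayout] = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        entries = per_plate[p]
        positions = rng.permutation(CHIPS_PER_PLATE)[: len(entries)]
        chips = [
            ChipSlot(
                chip_id=f"{plate_id}-{pos + 1:02d}",
                plate_id=plate_id,
                position=int(pos),
                role=role,
                compound_id=cid,
                replicate=rep,
            )
            for pos, (role, cid, rep) in zip(positions, entries)
        ]
        chips.sort(key=lambda c: c.position)
        plates.append(PlateLayout(plate_id=plate_id, chips=tuple(chips)))
    return plates
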