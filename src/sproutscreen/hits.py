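"""Three-gate, duplicate-agreement hit calling.

A chip contributes to a hit only when it passes all three gates:

* QC gate — micro-vessel formed properly before exposure (QC score >= 3);
  a chip failing QC is excluded from every statistic;
* integrity gate — the micro-vessel F-actin network stayed intact under
  the compound (integrity score >= 3); failing it marks vessel toxicity;
* efficacy gate — sprouting inhibited with Z* strictly below -3.

A compound is a *hit* only when both replicate chips pass all three
gates.  Vessel toxicity in any QC-passing replicate dominates: such a
compound is *toxic_excluded* regardless of efficacy.  A compound whose
two replicates both fail QC is *qc_excluded*; everything else, including
compounds with a single analysable replicate, is a *non_hit*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ChipMeasurement, ZScoreResult

VERDICTS = ("hit", "non_hit", "toxic_excluded", "qc_excluded")


@dataclass(frozen=True)
class HitCriteria:
    min_qc: int = 3
    min_integrity: int = 3
    z_star_cutoff: float = -3.0
    agreement_mode: str = "both_replicates_pass"  # or "mean_z_with_both_gates"

    def __post_init__(self) -> None:
        if self.z_star_cutoff >= 0:
            raise ValueError("z_star_cutoff must be negative")
        if self.min_qc not in (1, 2, 3, 4) or self.min_integrity not in (1, 2, 3, 4):
            raise ValueError("ordinal criteria must be in 1..4")
        if self.agreement_mode not in ("both_replicates_pass", "mean_z_with_both_gates"):
            raise ValueError(f"unknown agreement_mode {self.agreement_mode!r}")


@dataclass(frozen=True)
class ChipFlags:
    """Gate outcomes for one chip."""

    chip_id: str
    qc_pass: bool
    integrity_pass: bool
    efficacy_pass: bool
    z_star: float

    @property
    def all_pass(self) -> bool:
        return self.qc_pass and self.integrity_pass and self.efficacy_pass


@dataclass(frozen=True)
class CompoundCall:
    compound_id: str
    verdict: str
    replicate_flags: tuple[ChipFlags, ...]
    single_replicate: bool = False  # only one QC-passing replicate was available

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def gate_chip(m: ChipMeasurement, z: ZScoreResult, criteria: HitCriteria) -> ChipFlags:
    """Evaluate the three gates for one chip."""
    if m.qc_score is None or m.integrity_score is None:
        raise ValueError(f"chip {m.chip_id}: missing QC or integrity score")
    return ChipFlags(
        chip_id=m.chip_id,
        qc_pass=m.qc_score >= criteria.min_qc,
        integrity_pass=m.integrity_score >= criteria.min_integrity,
        efficacy_pass=bool(np.isfinite(z.z_star) and z.z_star < criteria.z_star_cutoff),
        z_star=z.z_star,
    )


def call_compound(
    compound_id: str,
    flags: tuple[ChipFlags, ...] | list[ChipFlags],
    criteria: HitCriteria,
) -> CompoundCall:
    """Combine duplicate gate outcomes into one compound verdict.

    Precedence: both-QC-fail -> qc_excluded; vessel toxicity in any
    QC-passing replicate -> toxic_excluded; both replicates fully passing
    -> hit; otherwise non_hit.  In ``mean_z_with_both_gates`` mode the
    efficacy gate is applied to the mean replicate Z* instead of to each
    replicate individually (QC and integrity gates unchanged).
    """
    flags = tuple(flags)
    if not 1 <= len(flags) <= 2:
        raise ValueError(f"{compound_id}: expected 1 or 2 replicate chips, got {len(flags)}")

    analysable = [f for f in flags if f.qc_pass]
    if not analysable:
        return CompoundCall(compound_id, "qc_excluded", flags)
    if any(not f.integrity_pass for f in analysable):
        return CompoundCall(compound_id, "toxic_excluded", flags)
    if len(analysable) < 2:
        # no duplicate agreement possible
        return CompoundCall(compound_id, "non_hit", flags, single_replicate=True)

    if criteria.agreement_mode == "mean_z_with_both_gates":
        mean_z = float(np.mean([f.z_star for f in analysable]))
        efficacious = mean_z < criteria.z_star_cutoff
    else:
        efficacious = all(f.efficacy_pass for f in analysable)
    verdict = "hit" if efficacious else "non_hit"
    return CompoundCall(compound_id, verdict, flags)


def call_screen(
    measurements: dict[str, ChipMeasurement],
    z_scores: dict[str, ZScoreResult],
    layout_compounds: dict[str, list[str]],
    criteria: HitCriteria | None = None,
) -> list[CompoundCall]:
    """Call every compound of a screen.

    Parameters
    ----------
    measurements, z_scores : keyed by chip_id.
    layout_compounds : compound_id -> list of its sample chip_ids.
    """
    criteria = criteria or HitCriteria()
    calls = []
    for cid, chip_ids in sorted(layout_compounds.items()):
        flags = tuple(
            gate_chip(measurements[ch], z_scores[ch], criteria) for ch in chip_ids
        )
        calls.append(call_compound(cid, flags, criteria))
    return calls


def summarize_screen(
    calls: list[CompoundCall],
    inhibition_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Verdict counts and percentages; partitions the library exactly.

    Returns a tidy table with one row per verdict (and, when
    ``inhibition_levels`` maps compound_id -> level, one row per level
    among hits).
    """
    n = len(calls)
    rows = []
    for verdict in VERDICTS:
        count = sum(1 for c in calls if c.verdict == verdict)
        rows.append({"category": "verdict", "label": verdict, "count": count,
                     "percent": 100.0 * count / n if n else 0.0})
    if inhibition_levels:
        hits = [c.compound_id for c in calls if c.verdict == "hit"]
        for level in ("none", "mild", "moderate", "high"):
            count = sum(1 for h in hits if inhibition_levels.get(h) == level)
            rows.append({"category": "hit_inhibition_level", "label": level,
                         "count": count,
                         "percent": 100.0 * count / len(hits) if hits else 0.0})
    return pd.DataFrame(rows)
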