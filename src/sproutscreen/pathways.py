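"""Pathway-combination analysis of hit compounds.

Hits are grouped by the canonical (sorted) set of main pathways their
library annotation assigns them; the frequency of each unique combination
is counted and the replicate-averaged Z* of member hits summarised as
mean +- sd.  Per-pathway membership counts overlap (a multi-pathway hit
counts once in each of its pathways).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CombinationSummary:
    pathway_combination: tuple[str, ...]  # canonical: sorted labels
    n_hits: int
    z_star_mean: float
    z_star_sd: float
    compound_ids: tuple[str, ...]


class AnnotationError(KeyError):
    """A hit compound lacks a pathway annotation."""


def _canonical(pathways) -> tuple[str, ...]:
    return tuple(sorted(set(pathways)))


def combination_frequency(
    hits: list[str],
    annotations: dict[str, set[str] | frozenset[str] | list[str]],
    z_star: dict[str, float] | None = None,
) -> list[CombinationSummary]:
    """Unique pathway combinations among hits with frequencies and Z* summaries.

    ``z_star`` maps compound_id to its replicate-averaged Z*; omit it to get
    NaN summaries.  Rows are ordered by descending frequency, then label.
    Frequencies sum to the number of hits.
    """
    missing = [h for h in hits if h not in annotations or not annotations[h]]
    if missing:
        raise AnnotationError(f"hits without pathway annotation: {sorted(missing)}")
    groups: dict[tuple[str, ...], list[str]] = {}
    for h in hits:
        groups.setdefault(_canonical(annotations[h]), []).append(h)

    out = []
    for combo, members in groups.items():
        if z_star is not None:
            zs = np.array([z_star[m] for m in members], dtype=float)
            mean = float(zs.mean())
            sd = float(zs.std(ddof=1)) if zs.size > 1 else 0.0
        else:
            mean = sd = float("nan")
        out.append(CombinationSummary(combo, len(members), mean, sd, tuple(sorted(members))))
    out.sort(key=lambda s: (-s.n_hits, s.pathway_combination))
    return out


def pathway_membership(
    hits: list[str],
    annotations: dict[str, set[str] | frozenset[str] | list[str]],
) -> pd.DataFrame:
    """Per-pathway hit counts (overlapping) with percentages of all hits."""
    counts: dict[str, int] = {}
    for h in hits:
        for p in set(annotations.get(h, ())):
            counts[p] = counts.get(p, 0) + 1
    n = len(hits)
    rows = [
        {"pathway": p, "n_hits": c, "percent_of_hits": 100.0 * c / n if n else 0.0}
        for p, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pathway", "n_hits", "percent_of_hits"])


def multi_hit_combinations(
    summaries: list[CombinationSummary], min_hits: int = 2
) -> list[CombinationSummary]:
    """Combinations shared by at least ``min_hits`` hit compounds."""
    return [s for s in summaries if s.n_hits >= min_hits]


def combinations_to_frame(summaries: list[CombinationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_combination": [" + ".join(s.pathway_combination) for s in summaries],
            "n_hits": [s.n_hits for s in summaries],
            "z_star_mean": [s.z_star_mean for s in summaries],
            "z_star_sd": [s.z_star_sd for s in summaries],
            "compound_ids": [";".join(s.compound_ids) for s in summaries],
        }
    )
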