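"""End-to-end screen execution.

``run_screen`` composes the stages — simulate, (optionally) render and
detect, score, call, pathway-report — into one reproducible run returning
an in-memory :class:`ScreenResult` and, when an output directory is given,
a set of CSV artifacts plus a JSON manifest.  Outputs are a pure function
of the :class:`~sproutscreen.config.RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import TAG_COMPOUND_LATENT, substream
from .config import RunConfig
from .hits import CompoundCall, HitCriteria, call_screen, summarize_screen
from .imaging import detect
from .pathways import combination_frequency, combinations_to_frame, pathway_membership
from .stats import (
    ChipMeasurement,
    PlateStats,
    ZScoreResult,
    classify_inhibition,
    control_cv,
    d10,
    integrity_concordance,
    plate_stats,
    replicate_spearman,
    robust_z,
    z_prime,
)
from .synth.layout import generate_layout
from .synth.library import CompoundTruth, generate_library
from .synth.phenotype import ChipPhenotype, sample_phenotype
from .synth.render import render_image, write_tiff


@dataclass
class ScoredScreen:
    """Scored measurements of one screen, before hit calling."""

    chip_scores: pd.DataFrame      # one row per chip (all chips; excluded flagged)
    plate_stats: dict[str, PlateStats]
    z_results: dict[str, ZScoreResult]
    measurements: dict[str, ChipMeasurement]


@dataclass
class ScreenResult:
    """All artifacts of one end-to-end run."""

    config: RunConfig
    layout: pd.DataFrame
    library: pd.DataFrame
    truth: pd.DataFrame
    nuclei: pd.DataFrame
    chip_scores: pd.DataFrame
    plate_report: pd.DataFrame
    compound_calls: pd.DataFrame
    screen_summary: pd.DataFrame
    assay_quality: pd.DataFrame
    pathway_combinations: pd.DataFrame
    pathway_membership: pd.DataFrame
    calls: list[CompoundCall]
    compound_truths: dict[str, CompoundTruth]


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage and chip/compound context."""


def score_measurements(
    measurements: list[ChipMeasurement],
    criteria: HitCriteria,
    min_plate_vehicle: int = 4,
    min_qc: int | None = None,
    mad_consistency: bool = False,
) -> ScoredScreen:
    """Plate-normalise and Z*-score a set of chip measurements.

    QC-failing chips (score below the criteria's QC gate) contribute to no
    statistic; their Z* is NaN and their exclusion reason is recorded.
    Plates with fewer than ``min_plate_vehicle`` analysable vehicle chips
    fall back to batch-pooled vehicle statistics, with provenance flagged.
    """
    min_qc = criteria.min_qc if min_qc is None else min_qc
    by_plate: dict[str, list[ChipMeasurement]] = {}
    for m in measurements:
        by_plate.setdefault(m.plate_id, []).append(m)

    pooled_vehicle = [m.d10_um for m in measurements
                      if m.role == "vehicle" and m.qc_score >= min_qc]
    if not pooled_vehicle:
        raise StageError("scoring: no QC-passing vehicle chips anywhere in the batch")

    stats_by_plate: dict[str, PlateStats] = {}
    for plate_id, ms in sorted(by_plate.items()):
        veh = [m.d10_um for m in ms if m.role == "vehicle" and m.qc_score >= min_qc]
        if len(veh) >= min_plate_vehicle:
            stats_by_plate[plate_id] = plate_stats(veh, plate_id)
        else:
            stats_by_plate[plate_id] = plate_stats(
                pooled_vehicle, plate_id, pooled_fallback=True
            )

    z_results: dict[str, ZScoreResult] = {}
    rows = []
    meas_by_chip: dict[str, ChipMeasurement] = {}
    for m in measurements:
        meas_by_chip[m.chip_id] = m
        ps = stats_by_plate[m.plate_id]
        excluded = m.qc_score < min_qc
        if excluded:
            z = float("nan")
            level = "excluded"
            reason = "qc_fail"
        else:
            z = robust_z(m.d10_um, ps, consistency=mad_consistency)
            level = classify_inhibition(z)
            reason = ""
        z_results[m.chip_id] = ZScoreResult(m.chip_id, z, level)
        rows.append(
            {
                "chip_id": m.chip_id,
                "plate_id": m.plate_id,
                "role": m.role,
                "compound_id": m.compound_id or "",
                "replicate": m.replicate if m.replicate is not None else "",
                "D10_um": m.d10_um,
                "z_star": z,
                "inhibition_level": level,
                "qc_score": m.qc_score,
                "integrity_score": m.integrity_score,
                "vessel_nuclei_count": m.vessel_nuclei_count,
                "excluded_reason": reason,
            }
        )
    chip_scores = pd.DataFrame(rows).sort_values("chip_id", ignore_index=True)
    return ScoredScreen(chip_scores, stats_by_plate, z_results, meas_by_chip)


def _simulate_chips(
    config: RunConfig,
    out_dir: Path | None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, CompoundTruth],
           list[ChipMeasurement], pd.DataFrame, dict[str, ChipPhenotype]]:
    """Generate library, layout and per-chip phenotypes; measure each chip."""
    library = generate_library(config.n_compounds, config.seed, config.mixture)
    truths = {c.compound_id: c for c in library}
    compound_index = {c.compound_id: i for i, c in enumerate(library)}
    plates = generate_layout(config.n_plates, [c.compound_id for c in library],
                             config.seed)

    latents = {
        cid: float(substream(config.seed, TAG_COMPOUND_LATENT, compound_index[cid])
                   .standard_normal())
        for cid in truths
    }

    layout_rows, truth_rows, nuclei_rows = [], [], []
    measurements: list[ChipMeasurement] = []
    phenotypes: dict[str, ChipPhenotype] = {}
    img_dir = None
    if out_dir is not None and config.write_images:
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)

    for p_idx, plate in enumerate(plates):
        for chip in plate.chips:
            truth = truths.get(chip.compound_id) if chip.compound_id else None
            latent = latents.get(chip.compound_id) if chip.compound_id else None
            try:
                pheno = sample_phenotype(
                    chip.role, config.geometry, config.noise, config.seed,
                    chip_index=(p_idx, chip.position), truth=truth,
                    latent_z=latent, chip_id=chip.chip_id,
                )
            except Exception as e:
                raise StageError(f"simulate: chip {chip.chip_id}: {e}") from e
            phenotypes[chip.chip_id] = pheno

            layout_rows.append(
                {"plate_id": chip.plate_id, "chip_id": chip.chip_id,
                 "position": chip.position, "role": chip.role,
                 "compound_id": chip.compound_id or "",
                 "replicate": chip.replicate if chip.replicate is not None else ""}
            )
            truth_rows.append(
                {"chip_id": chip.chip_id, "true_D10_um": pheno.true_d10,
                 "integrity_score": pheno.integrity_score, "qc_score": pheno.qc_score,
                 "vessel_nuclei_count": pheno.vessel_nuclei_count,
                 "n_sprout_nuclei": len(pheno.sprout_nuclei)}
            )

            if config.use_imaging:
                try:
                    image, _ = render_image(pheno, config.geometry, config.render,
                                            seed=config.seed)
                    if img_dir is not None:
                        write_tiff(img_dir / f"{chip.chip_id}.tiff", image)
                    records = detect(image, config.geometry, config.detection)
                except Exception as e:
                    raise StageError(f"detect: chip {chip.chip_id}: {e}") from e
                sprout = [r for r in records if r.region == "sprout"]
                measured_d10 = d10(sprout)
                vessel_count = sum(1 for r in records if r.region == "vessel")
                for r in records:
                    nuclei_rows.append(
                        {"chip_id": chip.chip_id, "x_um": r.centroid_x,
                         "y_um": r.centroid_y, "area_um2": r.area, "region": r.region}
                    )
            else:
                measured_d10 = pheno.true_d10
                vessel_count = pheno.vessel_nuclei_count
                # ground-truth positions stand in for detections so the CSV
                # interfaces stay complete without the imaging stage
                for x, y in pheno.all_nuclei():
                    nuclei_rows.append(
                        {"chip_id": chip.chip_id, "x_um": float(x), "y_um": float(y),
                         "area_um2": float("nan"),
                         "region": config.geometry.region_of(float(y))}
                    )

            measurements.append(
                ChipMeasurement(
                    chip_id=chip.chip_id, plate_id=chip.plate_id, role=chip.role,
                    d10_um=measured_d10, vessel_nuclei_count=vessel_count,
                    qc_score=pheno.qc_score, integrity_score=pheno.integrity_score,
                    compound_id=chip.compound_id, replicate=chip.replicate,
                )
            )

    layout_df = pd.DataFrame(layout_rows)
    truth_df = pd.DataFrame(truth_rows)
    library_df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in library],
            "inhibition_effect": [c.inhibition_effect for c in library],
            "toxicity_class": [c.toxicity_class for c in library],
            "pathways": [";".join(sorted(c.pathway_set)) for c in library],
        }
    )
    nuclei_df = pd.DataFrame(
        nuclei_rows, columns=["chip_id", "x_um", "y_um", "area_um2", "region"]
    )
    return layout_df, library_df, truths, measurements, nuclei_df, truth_df


def _assay_quality(
    scored: ScoredScreen, layout: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Per-plate report and screen-level quality metrics."""
    cs = scored.chip_scores
    ok = cs[cs["excluded_reason"] == ""]
    plate_rows = []
    for plate_id, ps in sorted(scored.plate_stats.items()):
        sub = ok[ok["plate_id"] == plate_id]
        veh = sub[sub["role"] == "vehicle"]["D10_um"].to_numpy()
        sun = sub[sub["role"] == "sunitinib_control"]["D10_um"].to_numpy()
        uns = sub[sub["role"] == "unstimulated"]["D10_um"].to_numpy()
        def _safe(fn, *groups):
            try:
                return fn(*groups)
            except (ValueError, ZeroDivisionError):
                return float("nan")
        plate_rows.append(
            {
                "plate_id": plate_id,
                "vehicle_median_D10_um": ps.vehicle_median_d10,
                "vehicle_MAD_D10_um": ps.vehicle_mad_d10,
                "n_vehicle": ps.n_vehicle,
                "pooled_fallback": ps.pooled_fallback,
                "z_prime_vehicle_vs_sunitinib": _safe(z_prime, veh, sun),
                "z_prime_vehicle_vs_unstimulated": _safe(z_prime, veh, uns),
                "cv_vehicle_percent": _safe(control_cv, veh),
                "cv_unstimulated_percent": _safe(control_cv, uns),
                "n_excluded": int((cs["plate_id"] == plate_id).sum() - len(sub)),
            }
        )
    plate_report = pd.DataFrame(plate_rows)

    # screen-level: replicate agreement among sample compounds
    samples = ok[ok["role"] == "sample"]
    z_pairs, i_pairs = [], []
    for cid, grp in samples.groupby("compound_id"):
        if len(grp) == 2:
            z_pairs.append(tuple(grp.sort_values("replicate")["z_star"]))
            i_pairs.append(tuple(grp.sort_values("replicate")["integrity_score"]))
    quality: dict[str, float] = {}
    veh_all = ok[ok["role"] == "vehicle"]["D10_um"].to_numpy()
    sun_all = ok[ok["role"] == "sunitinib_control"]["D10_um"].to_numpy()
    uns_all = ok[ok["role"] == "unstimulated"]["D10_um"].to_numpy()
    try:
        quality["z_prime_vehicle_vs_sunitinib"] = z_prime(veh_all, sun_all)
        quality["z_prime_vehicle_vs_unstimulated"] = z_prime(veh_all, uns_all)
    except (ValueError, ZeroDivisionError):
        pass
    try:
        quality["cv_vehicle_percent"] = control_cv(veh_all)
        quality["cv_unstimulated_percent"] = control_cv(uns_all)
    except ValueError:
        pass
    try:
        quality["replicate_spearman"] = replicate_spearman(z_pairs)
    except ValueError:
        quality["replicate_spearman"] = float("nan")
    same, adj, disc = integrity_concordance(i_pairs)
    quality["integrity_same_percent"] = same
    quality["integrity_adjacent_percent"] = adj
    quality["integrity_discordant_percent"] = disc
    quality_df = pd.DataFrame(
        [{"metric": k, "value": v} for k, v in quality.items()]
    )
    return plate_report, quality_df, quality


def run_screen(config: RunConfig, out_dir: str | Path | None = None) -> ScreenResult:
    """Execute a full synthetic screen: simulate -> detect -> score -> call.

    When ``out_dir`` is given, all result tables are written there as CSV
    together with ``manifest.json`` (config and its hash).  Re-running an
    identical config reproduces byte-identical CSVs.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    layout_df, library_df, truths, measurements, nuclei_df, truth_df = _simulate_chips(
        config, out_path
    )
    scored = score_measurements(
        measurements, config.criteria, config.min_plate_vehicle,
        mad_consistency=config.mad_consistency,
    )

    layout_compounds: dict[str, list[str]] = {}
    for row in layout_df.itertuples():
        if row.role == "sample":
            layout_compounds.setdefault(row.compound_id, []).append(row.chip_id)
    calls = call_screen(scored.measurements, scored.z_results, layout_compounds,
                        config.criteria)

    # replicate-mean inhibition level per compound, for the summary
    levels: dict[str, str] = {}
    for call in calls:
        zs = [f.z_star for f in call.replicate_flags
              if f.qc_pass and np.isfinite(f.z_star)]
        if zs:
            levels[call.compound_id] = classify_inhibition(float(np.mean(zs)))
    summary = summarize_screen(calls, levels)

    plate_report, quality_df, _ = _assay_quality(scored, layout_df)

    hits = [c.compound_id for c in calls if c.verdict == "hit"]
    annotations = {c: truths[c].pathway_set for c in truths}
    z_by_compound = {
        c.compound_id: float(np.mean([f.z_star for f in c.replicate_flags
                                      if np.isfinite(f.z_star)]))
        for c in calls
        if any(np.isfinite(f.z_star) for f in c.replicate_flags)
    }
    combos = combination_frequency(hits, annotations, z_by_compound)
    combos_df = combinations_to_frame(combos)
    membership_df = pathway_membership(hits, annotations)

    calls_df = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "verdict": c.verdict,
                "single_replicate": c.single_replicate,
                **{
                    f"{k}_rep{i + 1}": v
                    for i, f in enumerate(c.replicate_flags)
                    for k, v in (
                        ("z_star", f.z_star),
                        ("qc_pass", f.qc_pass),
                        ("integrity_pass", f.integrity_pass),
                        ("efficacy_pass", f.efficacy_pass),
                    )
                },
            }
            for c in calls
        ]
    )

    result = ScreenResult(
        config=config, layout=layout_df, library=library_df, truth=truth_df,
        nuclei=nuclei_df, chip_scores=scored.chip_scores, plate_report=plate_report,
        compound_calls=calls_df, screen_summary=summary, assay_quality=quality_df,
        pathway_combinations=combos_df, pathway_membership=membership_df,
        calls=calls, compound_truths=truths,
    )

    if out_path is not None:
        tables = {
            "layout.csv": result.layout,
            "library.csv": result.library,
            "truth.csv": result.truth,
            "nuclei.csv": result.nuclei,
            "chip_scores.csv": result.chip_scores,
            "plate_report.csv": result.plate_report,
            "compound_calls.csv": result.compound_calls,
            "screen_summary.csv": result.screen_summary,
            "assay_quality.csv": result.assay_quality,
            "pathway_combinations.csv": result.pathway_combinations,
            "pathway_membership.csv": result.pathway_membership,
        }
        for name, df in tables.items():
            df.to_csv(out_path / name, index=False)
        cfg = config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": config.seed,
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                           default=str))
    return result
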