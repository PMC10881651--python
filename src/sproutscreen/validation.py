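"""Self-validation studies: parameter recovery on planted ground truth.

Each study generates a synthetic screen (or dose panel) with known truth,
runs the analysis pipeline on it, and reports how faithfully the pipeline
recovers what was planted.  They exist so the package can demonstrate —
reproducibly, from a single seed — that detection, scoring, hit calling
and curve fitting work end to end at the calibrated noise levels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import RunConfig
from .dose_response import fit_series
from .geometry import ChipGeometry
from .imaging import DetectionParams, detect
from .pipeline import run_screen
from .stats import d10
from .synth import (
    CompoundTruth,
    NoiseParams,
    RenderParams,
    generate_dose_response,
    render_image,
    sample_phenotype,
)


def match_detections(
    detected: np.ndarray, truth: np.ndarray, radius: float
) -> tuple[int, int, int]:
    """Bipartite matching of detections to ground truth within ``radius`` µm.

    Returns (true positives, false positives, false negatives).
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    dist = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(dist)
    tp = int((dist[ri, ci] <= radius).sum())
    return tp, len(detected) - tp, len(truth) - tp


def detection_fidelity_study(
    seed: int,
    n_chips: int = 50,
    geometry: ChipGeometry | None = None,
    match_radius_px: float = 2.0,
) -> dict:
    """Render chips at default imaging noise and score nuclei detection.

    Chips span the full planted-effect range (strong inhibition to
    vehicle-like) with 20-150 nuclei each; reports the mean detection F1
    against ground truth (2-px matching) and the fraction of chips whose
    pipeline D10 lands within 5 µm of the ground-truth D10.
    """
    geometry = geometry or ChipGeometry()
    # modest band density keeps per-chip totals in the 20-150 range
    noise = NoiseParams(vessel_nuclei_base=25, nucleus_spacing=32.0)
    params = DetectionParams.for_scale(geometry.pixel_size)
    render = RenderParams()
    effects = np.linspace(0.05, 1.0, 10)

    f1s, d10_err, n_nuclei = [], [], []
    for i in range(n_chips):
        truth_c = CompoundTruth("C0001", float(effects[i % len(effects)]), 1,
                                frozenset({"MAPK/ERK"}))
        ph = sample_phenotype("sample", geometry, noise, seed=seed,
                              chip_index=(0, i), truth=truth_c, chip_id=f"fid{i}")
        img, truth = render_image(ph, geometry, render, seed=seed)
        recs = detect(img, geometry, params)
        det = np.array([[r.centroid_x, r.centroid_y] for r in recs]).reshape(-1, 2)
        tru = truth[["x_um", "y_um"]].to_numpy()
        tp, fp, fn = match_detections(det, tru, match_radius_px * geometry.pixel_size)
        prec = tp / max(tp + fp, 1)
        rec = tp / max(tp + fn, 1)
        f1s.append(2 * prec * rec / max(prec + rec, 1e-12))
        sprout = [r for r in recs if r.region == "sprout"]
        d10_err.append(abs(d10(sprout) - ph.true_d10))
        n_nuclei.append(len(tru))
    d10_err = np.asarray(d10_err)
    return {
        "n_chips": n_chips,
        "f1_mean": float(np.mean(f1s)),
        "f1_min": float(np.min(f1s)),
        "d10_within_5um_fraction": float(np.mean(d10_err <= 5.0)),
        "d10_error_max_um": float(d10_err.max()),
        "nuclei_min": int(np.min(n_nuclei)),
        "nuclei_max": int(np.max(n_nuclei)),
    }


def zero_noise_screen_study(seed: int, n_compounds: int = 24) -> dict:
    """One-plate screen with zero measurement noise, imaged vs ground truth.

    Rendering and expert-score noise are switched off (the chip-to-chip
    biological spread stays at calibration); the imaged pipeline must
    reproduce every chip's ground-truth D10 within rendering tolerance and
    every compound verdict of the ground-truth analysis.
    """
    cfg = RunConfig(
        seed=seed,
        n_plates=1,
        n_compounds=n_compounds,
        noise=NoiseParams().noiseless_scores(),
        render=RenderParams().noiseless(),
        detection=DetectionParams.for_scale(ChipGeometry().pixel_size),
        use_imaging=True,
    )
    imaged = run_screen(cfg)
    truthed = run_screen(dataclasses.replace(cfg, use_imaging=False))

    merged = imaged.chip_scores.merge(
        imaged.truth[["chip_id", "true_D10_um"]], on="chip_id"
    )
    errors = (merged["D10_um"] - merged["true_D10_um"]).abs()

    va = imaged.compound_calls.set_index("compound_id")["verdict"]
    vb = truthed.compound_calls.set_index("compound_id")["verdict"]
    agree = float((va == vb.loc[va.index]).mean())
    return {
        "n_chips": len(merged),
        "max_d10_error_um": float(errors.max()),
        "verdict_agreement_fraction": agree,
        "n_hits": int((va == "hit").sum()),
    }


def planted_recovery_study(seed: int, n_plates: int = 4, n_compounds: int = 96) -> dict:
    """Hit recovery on a default-noise screen with noiseless expert scores.

    Measures sensitivity for planted safe strong inhibitors
    (effect <= 0.2, toxicity class <= 2) and counts hits among planted
    vessel-toxic compounds (must be zero: the integrity gate is exact when
    scores carry no noise).
    """
    cfg = RunConfig(
        seed=seed,
        n_plates=n_plates,
        n_compounds=n_compounds,
        noise=NoiseParams(vessel_nuclei_base=40).noiseless_scores(),
        use_imaging=False,
    )
    result = run_screen(cfg)
    verdicts = result.compound_calls.set_index("compound_id")["verdict"]
    truths = result.compound_truths

    planted_hits = [c for c, t in truths.items() if t.is_planted_hit]
    planted_toxic = [c for c, t in truths.items() if t.is_planted_toxic]
    sensitivity = float(np.mean([verdicts[c] == "hit" for c in planted_hits]))
    toxic_hits = int(sum(verdicts[c] == "hit" for c in planted_toxic))
    return {
        "n_compounds": n_compounds,
        "n_planted_hits": len(planted_hits),
        "sensitivity": sensitivity,
        "n_planted_toxic": len(planted_toxic),
        "toxic_called_hit": toxic_hits,
    }


def ic50_recovery_study(
    seed: int, n_series: int = 20, true_ic50: float = 100.0, noise_cv: float = 0.10
) -> dict:
    """4PL parameter recovery on duplicate 8-point 4-fold series.

    Reports the noiseless relative IC50 error and, over ``n_series`` noisy
    simulations, the median absolute log2 fold error of the fitted IC50.
    """
    clean = generate_dose_response(ic50=true_ic50, hill=1.0, noise_cv=0.0, seed=seed)
    fit0 = fit_series(clean)
    noiseless_rel_err = abs(fit0.ic50 - true_ic50) / true_ic50

    fold_errors = []
    for i in range(n_series):
        df = generate_dose_response(ic50=true_ic50, hill=1.0, noise_cv=noise_cv,
                                    seed=seed + i + 1)
        fit = fit_series(df)
        fold_errors.append(abs(np.log2(fit.ic50 / true_ic50)))
    return {
        "noiseless_rel_error": float(noiseless_rel_err),
        "noiseless_ic50_nM": float(fit0.ic50),
        "median_abs_log2_fold_error": float(np.median(fold_errors)),
        "n_series": n_series,
    }


def determinism_study(seed: int, out_a, out_b) -> dict:
    """Run the same imaged config twice; compare result CSVs byte-for-byte."""
    geometry = ChipGeometry(pixel_size=1.3)
    cfg = RunConfig(
        seed=seed,
        n_plates=1,
        n_compounds=12,
        geometry=geometry,
        detection=DetectionParams.for_scale(geometry.pixel_size),
        use_imaging=True,
    )
    run_screen(cfg, out_dir=out_a)
    run_screen(cfg, out_dir=out_b)
    from pathlib import Path

    names = ["chip_scores.csv", "compound_calls.csv", "truth.csv", "nuclei.csv",
             "screen_summary.csv", "plate_report.csv"]
    identical = all(
        (Path(out_a) / n).read_bytes() == (Path(out_b) / n).read_bytes() for n in names
    )
    return {"identical": bool(identical), "n_files_compared": len(names)}
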