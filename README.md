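# sproutscreen

Analysis pipeline for phenotypic anti-angiogenesis screens run on 3D
organ-on-a-chip micro-vessel assays, with a synthetic chip-image generator
that makes the whole pipeline testable end to end without any acquired
data.

## The problem

In a microfluidic angiogenesis assay, a perfused endothelial micro-vessel
grows against an ECM gel pinned by two phaseguide ridges; a cocktail of
angiogenic factors drives sprouts from the vessel into the gel. A compound
screen asks two questions per chip: *did the compound block sprouting?*
(efficacy) and *did it leave the micro-vessel itself intact?* (safety).
`sproutscreen` implements the quantitative side of such a screen:

- **Nuclei detection** in the nuclei-channel fluorescence raster:
  rolling-ball background subtraction → Difference-of-Gaussians (DoG)
  enhancement → IsoData automatic threshold → watershed splitting of
  touching nuclei → centroid/area extraction in µm chip coordinates, with
  each nucleus assigned to the vessel or sprouting region.
- **Sprouting statistic**: D10, the mean longitudinal position *Y* of the
  ten sprout-region nuclei furthest from the vessel.
- **Robust scoring**: each chip is normalised to its plate's vehicle
  controls with a robust Z\* score,
  `Z* = (D10 − median_vehicle) / MAD_vehicle`,
  mapped onto ordinal inhibition levels
  (none > −3, mild −3…−9, moderate −9…−15, high ≤ −15).
- **Hit calling**: three gates per chip — QC score ≥ 3 (vessel formed
  properly), integrity score ≥ 3 (vessel survived the compound),
  Z\* < −3 (sprouting inhibited) — and a compound is a hit only when both
  duplicate chips pass all three. Vessel toxicity in either replicate
  excludes the compound.
- **Assay quality**: Z′ factor `1 − 3(σ₁+σ₂)/|μ₁−μ₂|` between control
  groups, control CVs, duplicate Spearman correlation, and duplicate
  integrity-score concordance.
- **Pathway analysis**: frequency of unique main-pathway combinations
  among hits with mean ± sd Z\*.
- **Dose response**: four-parameter logistic fits
  `r(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` on duplicate
  8-point series, plus a vessel nuclei-count toxicity profile.

Because real screen images and compound identities of such assays are
typically proprietary, the package ships a first-class synthetic generator
(`sproutscreen.synth`) producing plate layouts (64 chips: 8 vehicle,
4 Sunitinib-like, 4 unstimulated controls, 48 samples), compound libraries
with planted effects and pathway annotations, per-chip phenotypes with
ground-truth nuclei positions, and rendered TIFF-writable rasters.

## Worked example

```python
from sproutscreen import RunConfig, run_screen

cfg = RunConfig(seed=1, n_plates=1, n_compounds=24, use_imaging=False)
result = run_screen(cfg)
print(result.screen_summary.query("category == 'verdict'"))
```

prints

```
category          label  count   percent
 verdict            hit      7 29.166667
 verdict        non_hit      5 20.833333
 verdict toxic_excluded     12 50.000000
 verdict    qc_excluded      0  0.000000
```

— of the 24 simulated compounds, 7 inhibited sprouting (Z\* < −3 in both
replicates) without harming the vessel, 12 damaged the micro-vessel
(integrity gate) and are excluded from hits regardless of efficacy, and 5
passed all safety gates but did not inhibit sprouting. More narrative
walk-throughs live in `examples/` (simulation + scoring, image rendering +
detection, dose-response fitting, pathway combinations).

A CLI mirrors the library stages over CSV/TIFF interfaces:

```bash
sproutscreen run-all --seed 1 --out results/
sproutscreen dose-response --series dose.csv --out fits.csv
```

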