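# Methods

## The chip model and its coordinate frame

A chip lane is imaged as one raster laid out, top to bottom, as perfusion
channel (default 400 µm), vessel-side phaseguide (100 µm), sprouting
region (gel, default depth 500 µm), far phaseguide (100 µm). The
longitudinal coordinate *y* is measured in µm from the gel-side edge of
the vessel-side phaseguide, increasing into the gel; pixel centres sit at
`(index + 0.5) · pixel_size`. A nucleus belongs to the sprouting region
iff its centroid lies strictly between the two phaseguide inner edges
(`0 < y < depth`); nuclei over a phaseguide or in the channel count as
vessel-side. All statistics are computed in µm, so results are
pixel-size invariant up to discretisation. The default calibration of
0.65 µm/px is typical of a 10× widefield camera and is configurable.

## Synthetic screen generator

The generator is the package's study population: every downstream claim
about the pipeline is a claim about recovery of what the generator plants.

**Sprouting extent.** Each chip's ground-truth D10 is drawn from a
log-normal, parameterised by median and CV (σ = √ln(1+CV²)), because the
distance is positive and only location/spread summaries are available as
calibration anchors. Defaults: vehicle median 352.1 µm at CV 12.1 %;
Sunitinib-like strong-inhibition controls median 62.2 µm at CV 20 % (no
spread is published for this group; 20 % keeps the control bands cleanly
separated and is configurable); unstimulated controls CV 14.1 % with
median 45 µm (no median is published; 45 µm places the unstimulated
baseline below the strong-inhibition reference, as a no-cocktail chip
should sit). Sample chips multiply the vehicle median by the compound's
planted `inhibition_effect ∈ [0,1]` (1 = inert, 0 = complete block).

**Replicate structure.** The two chips of a compound share a latent
standard-normal effect draw mixed with independent chip noise at
correlation ρ = 0.85, so duplicate measurements co-vary the way duplicate
screening data do. ρ is a plausibility default, not a fitted value.

**Nuclei placement.** Ten "frontier" nuclei (sprout tips) are placed with
zero-mean jitter around the drawn extent — rescaled so their mean equals
it exactly, making ground-truth D10 identical to the statistic computed
from planted positions — one per sprout path (10 paths by default) spread
across the lane. Stalk nuclei line each path at ~25 µm spacing below the
frontier; the vessel band is filled by dart-throwing with a 12 µm minimum
separation (overlaps accepted after bounded retries, as in a real dense
band). Fully inhibited chips place a few nuclei hugging the boundary
(y < 2 µm). Extents are clipped 8 µm short of the far phaseguide, and the
ground truth is always recomputed from the placed positions, so truth and
geometry can never disagree.

**Expert scores.** Micro-vessel integrity (1 = destroyed … 4 = intact) is
centred on `5 − toxicity_class` of the compound and deviates by ±1 level
with probability 0.2 (split evenly); this yields duplicate concordance of
roughly 66 % identical / 32 % adjacent, the regime reported for expert
rescoring of such assays. QC scores are categorical with a 96.5 % pass
rate (P(4)=0.80, P(3)=0.165, P(2)=0.03, P(1)=0.005). `noiseless_scores()`
switches both noises off for exact-recovery studies. Scores are generated
as labels and never computed from images — mirroring their origin as
expert annotations.

**Library mixture.** Published screens do not state their effect
distribution, so the planted mixture is a package choice, fixed once:
10 % safe strong inhibitors (effect 0.05–0.2, toxicity class 1–2), 45 %
vessel-toxic compounds (class 3–4, effects spread 0–0.8, since toxic
compounds usually also suppress sprouting), 45 % inactive-to-mild (effect
0.6–1.0, class 1–2). Each compound carries 1–5 main-pathway labels from a
15-label vocabulary.

**Rendering.** Nuclei are isotropic Gaussian blobs (FWHM = 10 µm) with
log-normal per-nucleus brightness (CV 15 %), on a constant background of
100 counts plus a linear illumination ramp (50 counts peak-to-peak), with
Poisson shot noise and additive read noise (σ = 5). `noiseless()` removes
everything but the blobs and flat background. Rasters are float in memory
and written as 16-bit TIFF.

**Dose series.** The default concentration series is an 8-point 4-fold
serial dilution from 10 µM (10000, 2500, 625, 156.25, 39.06, 9.77, 2.44,
0.61 nM): a 4-fold ladder reproduces the commonly quoted 156 nM and 39 nM
interior points exactly, with the bottom point at 0.61 nM (≈ the loosely
rounded "0.7 nM"). Responses follow the 4PL with multiplicative
log-normal noise; vessel nuclei counts decay linearly in
log-concentration by a planted `count_decay` fraction (0 = stable vessel).

**Determinism.** Every stochastic stage draws from a substream derived
from the single top-level seed plus stable small-integer keys (stage tag,
plate index, chip position, compound index). Consequently chips keep
their draws when plates are added, and identical configs reproduce
byte-identical CSVs. Layouts place each compound's two replicates on
distinct plates whenever more than one plate has room; under-subscribed
plates leave spare sample slots empty while keeping the exact
8/4/4-control composition.

## Detection pipeline

1. **Background**: rolling-ball estimation subtracted and clipped at
   zero. The ball radius (default 50 px) must exceed the nucleus radius.
   For speed the background is estimated on a 4× downsampled copy and
   resized back — background varies on scales far above a pixel, and the
   package's tests bound the approximation error; `downsample=1` runs the
   exact estimator.
2. **DoG**: `blur(σ_small) − blur(σ_large)` with
   `σ_small = diameter_px/(2√2)` and `σ_large = 2σ_small`, which peaks
   the band-pass response at the nucleus scale. `DetectionParams.for_scale`
   derives all pixel-unit defaults from the calibration.
3. **IsoData threshold** on a 256-bin histogram, iterating
   `T ← (mean(I≤T) + mean(I>T))/2` until the change is below half a bin.
   The threshold additionally may not fall below `median + 5·1.4826·MAD`
   of the DoG response: on a structureless (pure-noise) image the IsoData
   split of a symmetric histogram would otherwise foreground half the
   pixels; on any image with real nuclei the IsoData threshold dominates
   and the floor is inert. Setting `noise_floor_k = 0` disables the guard.
4. **Watershed** on the negated Euclidean distance transform, seeded at
   its h-maxima (h = 2 px), splitting touching nuclei; components the
   seeding misses keep a single label.
5. **Extraction**: per-label area filter (25–2000 µm²) and
   intensity-weighted centroids (on the background-subtracted image) in
   µm chip coordinates. Weighted centroids reduce the sub-pixel bias of
   binary-mask centroids under an illumination gradient.

## Screen statistics and hit calling

D10 averages the ten largest sprout-region *y* values (all of them when
fewer than ten; 0 when none). Plate normalisation uses the plate's
QC-passing vehicle chips; plates with fewer than 4 fall back to
batch-pooled vehicle statistics with the fallback recorded. The MAD is
raw (no 1.4826 consistency constant) because Z\* counts median absolute
deviations from the vehicle median; the constant is a config switch.
Inhibition-level boundaries are left-closed toward severity: exactly −3
is mild, −9 moderate, −15 high, consistent with the hit gate requiring
Z\* *strictly* below −3.

A chip passes gating when QC ≥ 3, integrity ≥ 3 and Z\* < −3. Verdict
precedence for the duplicate: both replicates QC-failing → `qc_excluded`;
any QC-passing replicate failing integrity → `toxic_excluded` (a
compound that damages the vessel in either replicate cannot be a hit);
both replicates passing all gates → `hit`; everything else → `non_hit`,
including compounds with a single analysable replicate (no duplicate
agreement possible; flagged). An alternative `mean_z_with_both_gates`
mode applies the efficacy cutoff to the mean replicate Z\* and is
non-default. Verdicts always partition the library.

Z′ is reported for vehicle-vs-Sunitinib (default pair) and
vehicle-vs-unstimulated, with sample standard deviations. Duplicate
Spearman correlation is computed on Z\* pairs after dropping pairs with
an excluded replicate.

## Dose-response fitting

The 4PL is fit on natural-log concentration by Levenberg–Marquardt least
squares with a multi-start over every observed concentration as candidate
midpoint and both hill orientations; replicates pool into the residuals.
The reported orientation is normalised to `top ≥ bottom` (hill sign
flipped accordingly); IC50 is the midpoint concentration either way. The
`converged` flag is honest: it requires optimizer success, a fitted
dynamic range above 3 residual standard deviations, a midpoint within
~1.7 decades of the sampled range, and a non-degenerate hill — flat
series return `converged=False` rather than raising. The nuclei-count
toxicity profile classifies a series "stable" when no concentration's
mean count drops below 80 % (configurable) of the vehicle reference.

## Validation studies and their problem sizes

`sproutscreen.validation` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) fixes the study sizes: 1000 random draws per
statistic-vs-oracle comparison; 50 rendered chips spanning effects
0.05–1.0 with 20–150 nuclei each for detection fidelity (F1 with 2-px
bipartite matching); one 64-chip plate for the zero-measurement-noise
round trip (render and score noise off, biological spread at
calibration — with literally zero spread the vehicle MAD would be zero
and Z\* undefined, which the package treats as the degenerate error it
is); 4 plates × 96 compounds for planted-hit recovery and assay-quality
metrics; 20 duplicate series for IC50 recovery; and a 12-compound imaged
plate at 1.3 µm/px run twice for byte-determinism. These sizes keep each
study to seconds-to-minutes on a single core while leaving the Monte
Carlo error well below the thresholds being checked.

## What passing does and does not show

The generator emulates the statistical skeleton of a chip screen —
control calibrations, duplicate correlation, ordinal score noise,
blob-like nuclei over uneven illumination — but not out-of-focus planes,
actin-channel texture, debris, segmentation-hostile nuclear clumping at
vessel density, plate-position effects, or batch drift. Recovery results
therefore validate the correctness of the statistics, gating logic and
the detection pipeline's behaviour on well-formed images; they do not
certify detection parameters for any particular microscope, which should
be re-tuned (all parameters are exposed in `RunConfig`) on real data.

## Known limitations

- Nuclei merging in very dense vessel bands biases the vessel count low;
  D10 is unaffected (it uses only sprout-region nuclei).
- The IsoData noise floor assumes the DoG background response is roughly
  symmetric; exotic structured backgrounds could defeat it.
- The 4PL fit reports a point estimate without confidence intervals;
  series whose IC50 lies far outside the sampled range are flagged
  non-converged rather than extrapolated.
- Integrity/QC scores are consumed as inputs by design; the package never
  attempts to compute them from images.
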