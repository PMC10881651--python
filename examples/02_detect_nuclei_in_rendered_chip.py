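"""Render one synthetic chip image and detect its nuclei.

A vehicle-control chip phenotype is rendered as a nuclei-channel raster
(Gaussian blobs, illumination gradient, shot + read noise), then pushed
through the detection pipeline: rolling-ball background subtraction,
Difference-of-Gaussians enhancement, IsoData thresholding, watershed
splitting, and centroid/area extraction in µm chip coordinates.
"""

from sproutscreen import ChipGeometry, DetectionParams, d10, detect
from sproutscreen.synth import NoiseParams, RenderParams, render_image, sample_phenotype

geometry = ChipGeometry()  # 400 um channel, 100 um phaseguides, 0.65 um/px
phenotype = sample_phenotype("vehicle", geometry, NoiseParams(), seed=7,
                             chip_id="demo")
image, truth = render_image(phenotype, geometry, RenderParams(), seed=7)

records = detect(image, geometry, DetectionParams.for_scale(geometry.pixel_size))
sprout = [r for r in records if r.region == "sprout"]

print(f"planted nuclei: {len(truth)}  detected: {len(records)}")
print(f"sprout-region detections: {len(sprout)}")
print(f"D10 from detections: {d10(sprout):.1f} um")
print(f"D10 ground truth:    {phenotype.true_d10:.1f} um")
print("\nD10 is the mean longitudinal position of the ten sprout nuclei "
      "furthest from the micro-vessel; agreement within a few µm means the "
      "imaging pipeline adds no material measurement error.")
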