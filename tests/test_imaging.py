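import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, strategies as st
from skimage import filters as skfilters
from skimage.morphology import disk

from sproutscreen.geometry import ChipGeometry
from sproutscreen.imaging import (
    DegenerateImageError,
    DetectionParams,
    detect,
    enhance_dog,
    extract_nuclei,
    isodata_threshold,
    separate_watershed,
    subtract_background,
    threshold_isodata_mask,
)
from sproutscreen.synth import NoiseParams, RenderParams, render_image, sample_phenotype


def _blob(shape, center, sigma, amplitude=100.0):
    yy, xx = np.indices(shape, dtype=float)
    return amplitude * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                                / (2 * sigma**2)))


# ---------------------------------------------------------------- background

def test_background_of_constant_image_is_zero():
    img = np.full((120, 120), 37.0)
    out = subtract_background(img, radius=20, downsample=1)
    assert np.allclose(out, 0.0, atol=1e-6)


def test_blob_survives_background_subtraction():
    img = 50.0 + _blob((160, 160), (80, 80), sigma=4.0, amplitude=200.0)
    out = subtract_background(img, radius=30, downsample=1)
    # oracle: grey opening with a matching disk removes small bright blobs
    opened = ndi.grey_opening(img, footprint=disk(30))
    oracle = np.clip(img - opened, 0, None)
    assert out.max() == pytest.approx(200.0, rel=0.05)
    assert abs(out.max() - oracle.max()) / oracle.max() < 0.05


def test_ramp_background_mostly_removed():
    ramp = np.linspace(0, 80, 200)[:, None] * np.ones((1, 200))
    img = ramp + _blob((200, 200), (100, 100), sigma=4.0, amplitude=200.0)
    out = subtract_background(img, radius=30, downsample=1)
    far_corner = out[:40, :40]
    assert far_corner.max() <= 0.10 * 200.0


def test_downsampled_background_close_to_exact():
    rng = np.random.default_rng(0)
    img = np.linspace(0, 50, 200)[:, None] + rng.uniform(0, 2, (200, 200))
    img += _blob((200, 200), (60, 140), sigma=4.0, amplitude=150.0)
    exact = subtract_background(img, radius=30, downsample=1)
    fast = subtract_background(img, radius=30, downsample=4)
    assert np.abs(fast - exact).mean() < 2.0


def test_background_radius_validation():
    with pytest.raises(ValueError):
        subtract_background(np.zeros((10, 10)), radius=0)


# ----------------------------------------------------------------------- DoG

def test_dog_constant_image_is_zero():
    out = enhance_dog(np.full((64, 64), 12.0), 2.0, 4.0)
    assert np.allclose(out, 0.0, atol=1e-9)


def test_dog_is_linear():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 10, (64, 64))
    assert np.allclose(enhance_dog(3 * img, 2.0, 4.0), 3 * enhance_dog(img, 2.0, 4.0))


def test_dog_response_peaks_at_matched_blob_scale():
    # brute force over blob scales: response at centre is maximal near
    # sigma_blob = sqrt(sigma_small * sigma_large)
    s_small, s_large = 3.0, 6.0
    matched = np.sqrt(s_small * s_large)
    scales = np.linspace(1.0, 12.0, 23)
    responses = []
    for s in scales:
        img = _blob((121, 121), (60, 60), sigma=s)
        responses.append(enhance_dog(img, s_small, s_large)[60, 60])
    best = scales[int(np.argmax(responses))]
    assert best == pytest.approx(matched, abs=1.0)


def test_dog_sigma_ordering_validated():
    with pytest.raises(ValueError):
        enhance_dog(np.zeros((8, 8)), 4.0, 2.0)


# ------------------------------------------------------------------- IsoData

def test_isodata_two_level_image():
    img = np.array([10.0] * 70 + [100.0] * 30).reshape(10, 10)
    t = isodata_threshold(img)
    assert 10 < t < 100
    mask = threshold_isodata_mask(img)
    assert mask.sum() == 30


def test_isodata_satisfies_fixed_point():
    rng = np.random.default_rng(2)
    img = np.concatenate([rng.normal(20, 3, 600), rng.normal(90, 8, 400)])
    t = isodata_threshold(img)
    lo, hi = img[img <= t], img[img > t]
    assert t == pytest.approx(0.5 * (lo.mean() + hi.mean()), abs=1.0)


def test_isodata_shift_equivariance():
    rng = np.random.default_rng(3)
    img = np.concatenate([rng.normal(20, 3, 500), rng.normal(90, 8, 500)]).reshape(25, 40)
    t0 = isodata_threshold(img)
    t1 = isodata_threshold(img + 55.0)
    assert t1 - t0 == pytest.approx(55.0, abs=0.5)
    assert np.array_equal(threshold_isodata_mask(img), threshold_isodata_mask(img + 55.0))


def test_isodata_mask_count_matches_brute_force():
    rng = np.random.default_rng(4)
    img = np.concatenate([rng.normal(10, 2, 800), rng.normal(60, 5, 200)]).reshape(40, 25)
    t = isodata_threshold(img)
    assert threshold_isodata_mask(img).sum() == int((img > t).sum())


def test_isodata_agrees_with_reference_implementation():
    rng = np.random.default_rng(5)
    img = np.concatenate([rng.normal(30, 5, 700), rng.normal(120, 15, 300)])
    ours = isodata_threshold(img)
    ref = skfilters.threshold_isodata(img, nbins=256)
    assert ours == pytest.approx(ref, abs=(img.max() - img.min()) / 128)


def test_isodata_constant_image_rejected():
    with pytest.raises(DegenerateImageError):
        isodata_threshold(np.full((10, 10), 5.0))


# ----------------------------------------------------------------- watershed

def _disk_mask(shape, center, r):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def test_disjoint_disks_keep_two_labels():
    mask = _disk_mask((100, 100), (30, 30), 10) | _disk_mask((100, 100), (70, 70), 10)
    labels = separate_watershed(mask)
    assert labels.max() == 2


def test_touching_disks_are_split():
    # centres 1.5 radii apart: a single connected component with two
    # distance-transform maxima (the oracle) must yield two labels
    r = 12
    mask = _disk_mask((100, 100), (50, 40), r) | _disk_mask((100, 100), (50, 58), r)
    _, n_components = ndi.label(mask)
    assert n_components == 1
    labels = separate_watershed(mask)
    assert labels.max() == 2


def test_watershed_preserves_mask_pixels():
    r = 12
    mask = _disk_mask((100, 100), (50, 40), r) | _disk_mask((100, 100), (50, 58), r)
    labels = separate_watershed(mask)
    assert np.array_equal(labels > 0, mask)


def test_empty_mask_gives_empty_labelling():
    labels = separate_watershed(np.zeros((50, 50), dtype=bool))
    assert labels.max() == 0


# ---------------------------------------------------------- record extraction

def test_centroid_and_area_arithmetic():
    g = ChipGeometry(channel_width=10, phaseguide_width=5, sprout_region_depth=40,
                     image_width=60, pixel_size=1.0)
    labels = np.zeros(g.image_shape, dtype=np.int32)
    labels[10:15, 10:15] = 1  # 5x5 square, centroid at pixel index (12, 12)
    params = DetectionParams(min_area=5, max_area=100, dog_sigma_small=1,
                             dog_sigma_large=2, weighted_centroid=False)
    (rec,) = extract_nuclei(labels, g, params)
    assert rec.area == pytest.approx(25.0)
    # pixel centres at index + 0.5: centroid index 12 -> 12.5 um
    assert rec.centroid_x == pytest.approx(12.5)
    assert rec.centroid_y == pytest.approx(12.5 - g.vessel_band_depth)


def test_area_filter_excludes_small_labels():
    g = ChipGeometry(channel_width=10, phaseguide_width=5, sprout_region_depth=40,
                     image_width=60, pixel_size=1.0)
    labels = np.zeros(g.image_shape, dtype=np.int32)
    labels[5:7, 5:7] = 1    # 4 um2, below min
    labels[20:25, 20:25] = 2
    params = DetectionParams(min_area=5, max_area=100, dog_sigma_small=1,
                             dog_sigma_large=2)
    recs = extract_nuclei(labels, g, params)
    assert len(recs) == 1 and recs[0].area == pytest.approx(25.0)


# ------------------------------------------------------------- full pipeline

def _render_chip(small_geometry, seed, render_params=None, median=150.0):
    noise = NoiseParams(vehicle_median=median, vessel_nuclei_base=25)
    ph = sample_phenotype("vehicle", small_geometry, noise, seed=seed, chip_id="t")
    img, truth = render_image(ph, small_geometry,
                              render_params or RenderParams(), seed=seed)
    return ph, img, truth


def test_blank_noisy_image_yields_no_records(small_geometry):
    rng = np.random.default_rng(0)
    img = rng.poisson(100, small_geometry.image_shape).astype(float)
    params = DetectionParams.for_scale(small_geometry.pixel_size)
    assert detect(img, small_geometry, params) == []


def test_zero_noise_well_separated_nuclei_all_found(small_geometry):
    # k well-separated planted nuclei -> exactly k records
    from sproutscreen.synth.phenotype import ChipPhenotype
    xs, ys = np.meshgrid(np.arange(30.0, 230.0, 40.0), np.arange(30.0, 280.0, 40.0))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    ph = ChipPhenotype(chip_id="sep", role="vehicle", compound_id=None,
                       true_d10=float(np.sort(pts[:, 1])[-10:].mean()),
                       vessel_nuclei=np.empty((0, 2)), sprout_nuclei=pts,
                       integrity_score=4, qc_score=4)
    img, truth = render_image(ph, small_geometry, RenderParams().noiseless(), seed=2)
    params = DetectionParams.for_scale(small_geometry.pixel_size)
    recs = detect(img, small_geometry, params)
    assert len(recs) == len(truth)
    # every planted nucleus recovered to sub-pixel accuracy
    det = np.array([[r.centroid_x, r.centroid_y] for r in recs])
    for x, y in pts:
        assert np.min(np.hypot(det[:, 0] - x, det[:, 1] - y)) < 1.0


def test_detection_deterministic(small_geometry):
    _, img, _ = _render_chip(small_geometry, seed=3)
    params = DetectionParams.for_scale(small_geometry.pixel_size)
    assert detect(img, small_geometry, params) == detect(img, small_geometry, params)


def test_intensity_scale_invariance(small_geometry):
    # IsoData scales, DoG is linear, rolling ball scales: detections unchanged
    _, img, _ = _render_chip(small_geometry, seed=4)
    params = DetectionParams.for_scale(small_geometry.pixel_size)
    a = detect(img, small_geometry, params)
    b = detect(img * 3.0, small_geometry, params)
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.centroid_x == pytest.approx(rb.centroid_x, abs=0.2)
        assert ra.centroid_y == pytest.approx(rb.centroid_y, abs=0.2)


def test_translation_equivariance(small_geometry):
    _, img, _ = _render_chip(small_geometry, seed=5,
                             render_params=RenderParams().noiseless())
    shift = 9
    shifted = np.roll(img, shift, axis=1)
    params = DetectionParams.for_scale(small_geometry.pixel_size)
    a = sorted(detect(img, small_geometry, params), key=lambda r: (r.centroid_y, r.centroid_x))
    b = sorted(detect(shifted, small_geometry, params), key=lambda r: (r.centroid_y, r.centroid_x))
    moved = [r for r in a if r.centroid_x + shift * small_geometry.pixel_size
             < small_geometry.image_width - 5]
    assert len(b) >= len(moved)
    xs_a = np.sort([r.centroid_x for r in moved])
    xs_b = np.sort([r.centroid_x - shift * small_geometry.pixel_size for r in b])[: len(xs_a)]
    assert np.allclose(np.sort(xs_b), xs_a, atol=0.5)


def test_mismatched_geometry_rejected(small_geometry):
    with pytest.raises(ValueError, match="shape"):
        detect(np.zeros((10, 10)), small_geometry)


@given(st.floats(min_value=0.5, max_value=5.0))
def test_detection_params_scale_ordering(pixel_size):
    p = DetectionParams.for_scale(pixel_size)
    assert 0 < p.dog_sigma_small < p.dog_sigma_large
    assert p.rolling_ball_radius > p.dog_sigma_large
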