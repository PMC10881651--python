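"""Rendering of synthetic nuclei-channel chip rasters.

Each nucleus is drawn as an isotropic Gaussian blob at its ground-truth
position; a constant offset plus an optional smooth gradient emulate
uneven illumination, and shot (Poisson) plus additive read noise emulate
camera statistics.  The ground-truth table lists every nucleus in both µm
chip coordinates and pixel coordinates together with its region label, so
detection output can be matched against it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .._rng import TAG_RENDER, substream
from ..geometry import ChipGeometry
from .phenotype import ChipPhenotype


@dataclass(frozen=True)
class RenderParams:
    """Optical and camera model of the synthetic raster."""

    nucleus_diameter: float = 10.0   # µm, FWHM of the rendered blob
    intensity: float = 800.0         # peak counts of one nucleus
    intensity_cv: float = 0.15       # per-nucleus brightness variation
    background: float = 100.0        # constant offset, counts
    gradient_amplitude: float = 50.0 # peak-to-peak illumination gradient, counts
    poisson_noise: bool = True
    read_noise_sd: float = 5.0       # counts

    def __post_init__(self) -> None:
        if self.nucleus_diameter <= 0:
            raise ValueError("nucleus_diameter must be > 0")
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")

    def noiseless(self) -> "RenderParams":
        return replace(self, intensity_cv=0.0, gradient_amplitude=0.0,
                       poisson_noise=False, read_noise_sd=0.0)


class RenderGeometryError(ValueError):
    """A nucleus falls outside the imaged field."""


def _stamp_gaussians(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Sum of Gaussian blobs, each stamped on a local +-4 sigma window."""
    img = np.zeros(shape, dtype=np.float64)
    half = max(2, int(np.ceil(4 * sigma_px)))
    for r, c, a in zip(rows, cols, amplitudes):
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, shape[0]), min(c1, shape[1])
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        yy = np.arange(rr0, rr1, dtype=np.float64)[:, None] - r
        xx = np.arange(cc0, cc1, dtype=np.float64)[None, :] - c
        img[rr0:rr1, cc0:cc1] += a * np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    return img


def render_image(
    phenotype: ChipPhenotype,
    geometry: ChipGeometry,
    params: RenderParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one chip raster and its ground-truth nucleus table.

    Returns
    -------
    image : float64 array of shape ``geometry.image_shape``
        Synthetic counts; non-negative.
    truth : DataFrame
        One row per nucleus: ``nucleus_id, x_um, y_um, row_px, col_px, region``.
    """
    params = params or RenderParams()
    rng = substream(seed, TAG_RENDER, *map(ord, phenotype.chip_id))
    shape = geometry.image_shape

    pts = phenotype.all_nuclei()
    if len(pts):
        x, y = pts[:, 0], pts[:, 1]
        if (x.min() < 0 or x.max() > geometry.image_width
                or y.min() < -geometry.vessel_band_depth
                or y.max() > geometry.sprout_region_depth + geometry.phaseguide_width):
            raise RenderGeometryError(
                f"chip {phenotype.chip_id}: nuclei outside the imaged field"
            )
        rows = np.array([geometry.y_to_row(v) for v in y])
        cols = np.array([geometry.x_to_col(v) for v in x])
    else:
        rows = cols = np.empty(0)

    sigma_px = params.nucleus_diameter / 2.355 / geometry.pixel_size  # FWHM -> sigma
    if params.intensity_cv > 0 and len(pts):
        amps = params.intensity * np.exp(
            np.sqrt(np.log1p(params.intensity_cv**2)) * rng.standard_normal(len(pts))
        )
    else:
        amps = np.full(len(pts), params.intensity)

    img = _stamp_gaussians(shape, rows, cols, amps, sigma_px)
    img += params.background
    if params.gradient_amplitude > 0:
        ramp = np.linspace(0.0, 1.0, shape[0])[:, None]
        img += params.gradient_amplitude * ramp

    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if params.read_noise_sd > 0:
        img += rng.normal(0.0, params.read_noise_sd, size=shape)
    img = np.clip(img, 0.0, None)

    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(len(pts)),
            "x_um": pts[:, 0] if len(pts) else np.empty(0),
            "y_um": pts[:, 1] if len(pts) else np.empty(0),
            "row_px": rows,
            "col_px": cols,
            "region": [geometry.region_of(v) for v in (pts[:, 1] if len(pts) else [])],
        }
    )
    return img, truth


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a raster as 16-bit TIFF, clipping to the dtype range."""
    data = np.clip(np.round(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)
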