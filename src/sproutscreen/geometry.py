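"""Chip geometry and the mapping between pixel and physical coordinates.

A chip lane is imaged as a single fluorescence raster.  Along the image
rows (top to bottom) the lane is laid out as::

    perfusion channel (micro-vessel)   channel_width  µm
    phaseguide (vessel side)           phaseguide_width µm
    sprouting region (ECM gel)         sprout_region_depth µm
    phaseguide (far side)              phaseguide_width µm

The longitudinal chip coordinate ``y`` is measured in µm from the inner
(gel-side) edge of the vessel-side phaseguide, increasing into the gel:
``y = 0`` is the boundary sprouts emerge from, ``y = sprout_region_depth``
is the far phaseguide.  ``x`` runs along the vessel (image columns).
Pixel centres sit at ``(index + 0.5) * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChipGeometry:
    """Physical calibration of one chip image.

    Parameters
    ----------
    channel_width : float
        Width of the perfusion channel holding the micro-vessel, µm.
    phaseguide_width : float
        Width of each phaseguide ridge, µm.
    sprout_region_depth : float
        Distance between the inner edges of the two phaseguides, µm; the
        sprouting region.  Must accommodate the longest sprout generated.
    image_width : float
        Lateral extent of the imaged field along the vessel, µm.
    pixel_size : float
        Image calibration, µm per pixel.
    """

    channel_width: float = 400.0
    phaseguide_width: float = 100.0
    sprout_region_depth: float = 500.0
    image_width: float = 400.0
    pixel_size: float = 0.65

    def __post_init__(self) -> None:
        for name in ("channel_width", "phaseguide_width", "sprout_region_depth",
                     "image_width", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def vessel_band_depth(self) -> float:
        """µm from the image top to y = 0 (channel plus vessel-side phaseguide)."""
        return self.channel_width + self.phaseguide_width

    @property
    def image_height(self) -> float:
        """Total imaged depth in µm (channel, both phaseguides, gel)."""
        return self.vessel_band_depth + self.sprout_region_depth + self.phaseguide_width

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster at this calibration."""
        return (
            int(round(self.image_height / self.pixel_size)),
            int(round(self.image_width / self.pixel_size)),
        )

    # -- coordinate transforms -------------------------------------------

    def y_to_row(self, y_um: float) -> float:
        """Chip y (µm) to fractional row index."""
        return (y_um + self.vessel_band_depth) / self.pixel_size - 0.5

    def row_to_y(self, row: float) -> float:
        """Fractional row index to chip y (µm)."""
        return (row + 0.5) * self.pixel_size - self.vessel_band_depth

    def x_to_col(self, x_um: float) -> float:
        return x_um / self.pixel_size - 0.5

    def col_to_x(self, col: float) -> float:
        return (col + 0.5) * self.pixel_size

    def region_of(self, y_um: float) -> str:
        """Region label for a nucleus at longitudinal position ``y_um``.

        A nucleus is in the sprouting region iff it lies strictly between
        the inner edges of the two phaseguides; nuclei over a phaseguide or
        in the channel belong to the vessel side.
        """
        if 0.0 < y_um < self.sprout_region_depth:
            return "sprout"
        return "vessel"
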