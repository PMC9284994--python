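"""Shared image-geometry container.

All image arrays in this package are ordered ``(slice, row, col)`` for a
single frame and ``(frame, slice, row, col)`` for a time series; indices
are 0-based and refer to pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Geometry:
    """Physical pixel geometry of a multislice 2-D acquisition.

    Parameters
    ----------
    pixel_spacing_mm : (row_spacing, col_spacing)
        In-plane pixel size in millimetres.
    slice_thickness_mm : float
        Through-plane voxel extent (contiguous slices assumed).
    """

    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        dy, dx = self.pixel_spacing_mm
        if dy <= 0 or dx <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        dy, dx = self.pixel_spacing_mm
        return dy * dx

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_area_mm2 * self.slice_thickness_mm

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0
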