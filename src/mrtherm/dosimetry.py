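"""Sapareto-Dewey CEM43 thermal dosimetry and isodose volumetry.

The cumulative equivalent minutes at 43 degC convert an arbitrary
temperature history T(t) into the exposure time at 43 degC that would
cause the same thermal damage:

    CEM43 = sum_t R^(43 - T_t) * dt   [minutes]

with R = 0.50 for T_t >= 43 degC and R = 0.25 below, T_t the average
temperature over each interval dt.  Necrotic-zone volume is estimated by
counting pixels whose accumulated dose exceeds a threshold (70 CEM43 by
default) and multiplying by the three pixel dimensions -- no smoothing,
interpolation or connectivity filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .geometry import Geometry
from .thermometry import TemperatureSeries

__all__ = [
    "DoseParams",
    "DoseMap",
    "AblationVolume",
    "accumulate_cem43",
    "dose_volume",
    "isodose_contours",
]


@dataclass(frozen=True)
class DoseParams:
    """CEM43 accumulation constants and necrosis threshold.

    ``baseline_temp_C`` is the assumed absolute tissue temperature at
    zero measured change; absolute temperature is baseline + dT.
    """

    R_below: float = 0.25
    R_at_or_above: float = 0.50
    reference_temp_C: float = 43.0
    threshold_CEM: float = 70.0
    baseline_temp_C: float = 37.0

    def __post_init__(self) -> None:
        if not (0 < self.R_below < 1 and 0 < self.R_at_or_above < 1):
            raise ValueError("R values must lie in (0, 1)")
        if self.threshold_CEM <= 0:
            raise ValueError("threshold_CEM must be positive")


@dataclass(frozen=True)
class DoseMap:
    """Cumulative CEM43 per pixel, ``cem43[slice, row, col]`` (minutes)."""

    cem43: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        cem = np.asarray(self.cem43, dtype=float)
        object.__setattr__(self, "cem43", cem)
        if cem.ndim != 3:
            raise ValueError("cem43 must be (slice, row, col)")
        if np.any(cem < 0):
            raise ValueError("dose must be nonnegative")


@dataclass(frozen=True)
class AblationVolume:
    volume_cm3: float
    pixel_count: int
    threshold_used: float
    voxel_volume_cm3: float


def accumulate_cem43(
    temps: TemperatureSeries, params: DoseParams | None = None
) -> DoseMap:
    """Accumulate the Sapareto-Dewey dose over a temperature series.

    Each interval between adjacent frames contributes
    ``R^(43 - T_avg) * dt_minutes`` where ``T_avg`` is the mean of the
    absolute temperatures at the two endpoints and R is selected by
    comparing ``T_avg`` with the 43 degC reference.
    """
    params = params or DoseParams()
    if temps.n_frames < 2:
        raise ValueError("need at least 2 frames to accumulate dose")
    baseline = (
        params.baseline_temp_C
        if params.baseline_temp_C is not None
        else temps.baseline_temp_C
    )
    T = baseline + temps.delta_T
    T_avg = 0.5 * (T[:-1] + T[1:])
    dt_min = np.diff(temps.timestamps_s) / 60.0
    R = np.where(T_avg >= params.reference_temp_C, params.R_at_or_above, params.R_below)
    contrib = R ** (params.reference_temp_C - T_avg) * dt_min[:, None, None, None]
    return DoseMap(cem43=contrib.sum(axis=0), geometry=temps.geometry)


def dose_volume(dose: DoseMap, params: DoseParams | None = None) -> AblationVolume:
    """Thresholded pixel-count volume of the predicted necrotic zone.

    Pixels strictly above ``threshold_CEM`` are counted; volume is
    count x (pixel area x slice thickness) in cm^3.
    """
    params = params or DoseParams()
    count = int(np.count_nonzero(dose.cem43 > params.threshold_CEM))
    vox = dose.geometry.voxel_volume_cm3
    return AblationVolume(
        volume_cm3=count * vox,
        pixel_count=count,
        threshold_used=params.threshold_CEM,
        voxel_volume_cm3=vox,
    )


def isodose_contours(
    dose: DoseMap, levels
) -> dict[float, list[list[np.ndarray]]]:
    """Marching-squares isodose contours per slice, in millimetres.

    Returns ``{level: [contours_slice0, contours_slice1, ...]}`` where
    each contour is an ``(N, 2)`` array of (row_mm, col_mm) vertices in
    physical coordinates (pixel centers at ``index * spacing``).
    """
    levels = [float(l) for l in np.atleast_1d(levels)]
    if any(l <= 0 for l in levels):
        raise ValueError("contour levels must be positive")
    dy, dx = dose.geometry.pixel_spacing_mm
    out: dict[float, list[list[np.ndarray]]] = {}
    for level in levels:
        per_slice = []
        for s in range(dose.cem43.shape[0]):
            contours = measure.find_contours(dose.cem43[s], level=level)
            per_slice.append([c * np.array([dy, dx]) for c in contours])
        out[level] = per_slice
    return out
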