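"""Lesion volumetry from traced histology sections.

Mirrors the manual procedure used on TTC-stained brain slices: a ruler
in the photograph calibrates pixels to centimetres, the unstained
(necrotic) region of each 5-mm coronal section is traced to an area in
cm^2, and the lesion volume is the sum of area x slice thickness over
sections the ablation passes fully through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import agreement

__all__ = [
    "HistologySection",
    "HistologySectionSet",
    "ObserverComparison",
    "calibrate_scale",
    "pixel_area_to_cm2",
    "histology_volume",
    "observer_compare",
]


@dataclass(frozen=True)
class HistologySection:
    """One traced coronal section.

    ``full_thickness`` records whether the lesion reached the posterior
    face of the slice; only such sections contribute their full
    thickness to the volume.
    """

    slice_index: int
    area_cm2: float
    full_thickness: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.area_cm2) or self.area_cm2 < 0:
            raise ValueError(f"area must be finite and >= 0, got {self.area_cm2}")


@dataclass(frozen=True)
class HistologySectionSet:
    """Traced lesion areas for one specimen, plus scale provenance."""

    sections: tuple[HistologySection, ...]
    slice_thickness_cm: float = 0.5
    scale_px_per_cm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", tuple(self.sections))
        if self.slice_thickness_cm <= 0:
            raise ValueError("slice thickness must be positive")
        idx = [s.slice_index for s in self.sections]
        if len(idx) != len(set(idx)):
            raise ValueError("slice indices must be unique")

    @property
    def areas_cm2(self) -> np.ndarray:
        return np.array([s.area_cm2 for s in self.sections], dtype=float)


def calibrate_scale(ruler_px: float, ruler_cm: float = 1.0) -> float:
    """Pixels-per-centimetre scale from a ruler measurement in the image."""
    if ruler_px <= 0 or ruler_cm <= 0:
        raise ValueError("ruler lengths must be positive")
    return ruler_px / ruler_cm


def pixel_area_to_cm2(area_px: float, scale_px_per_cm: float) -> float:
    """Convert a traced pixel area to cm^2 using a linear scale."""
    if scale_px_per_cm <= 0:
        raise ValueError("scale must be positive")
    return area_px / scale_px_per_cm**2


def histology_volume(
    sections: HistologySectionSet, partial_fraction: float = 0.0
) -> float:
    """Total lesion volume in cm^3 by area x slice-thickness summation.

    Sections flagged ``full_thickness`` contribute
    ``area * slice_thickness``; sections where the ablation did not
    reach the posterior face contribute ``area * slice_thickness *
    partial_fraction`` (0 by default).
    """
    if not sections.sections:
        raise ValueError("section set is empty")
    if not 0.0 <= partial_fraction <= 1.0:
        raise ValueError("partial_fraction must be in [0, 1]")
    t = sections.slice_thickness_cm
    return float(
        sum(
            s.area_cm2 * t * (1.0 if s.full_thickness else partial_fraction)
            for s in sections.sections
        )
    )


@dataclass(frozen=True)
class ObserverComparison:
    """Paired comparison of two observers' volume measurements."""

    differences: np.ndarray = field(repr=False)
    mean_diff: float = 0.0
    sem_diff: float = 0.0
    t_stat: float = 0.0
    p_value: float = 1.0


def observer_compare(volumes_p1, volumes_p2) -> ObserverComparison:
    """Per-pair differences, mean +/- SEM and paired t-test of two raters."""
    a = np.asarray(volumes_p1, dtype=float)
    b = np.asarray(volumes_p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    mean, sem = agreement.summarize_metric(a - b)
    t, p = agreement.paired_t(a, b)
    return ObserverComparison(
        differences=a - b, mean_diff=mean, sem_diff=sem, t_stat=t, p_value=p
    )
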