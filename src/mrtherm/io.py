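"""Readers and writers for the package's on-disk formats.

Image-like quantities (phase series, temperature series, dose maps,
masks) are stored as NIfTI with axes ordered ``(row, col, slice,
frame)`` and an affine carrying the pixel spacing, plus a JSON sidecar
holding timestamps and acquisition parameters.  Tables (histology
sections, ROI curves, the bundled animal-study summary table) are CSV;
results and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Geometry
from .histology import HistologySection, HistologySectionSet
from .dosimetry import DoseMap
from .thermometry import AcquisitionParams, PhaseSeries, RoiCurve, TemperatureSeries

__all__ = [
    "load_table1_fixture",
    "write_phase_series",
    "read_phase_series",
    "write_temperature_series",
    "read_temperature_series",
    "write_dose_map",
    "read_dose_map",
    "write_mask",
    "read_mask",
    "write_sections_csv",
    "read_sections_csv",
    "write_roi_curve_csv",
    "write_json",
]


def load_table1_fixture() -> pd.DataFrame:
    """Bundled summary table of the eight swine ablations.

    Columns include the acoustic power and duration of each sonication,
    the recorded maximal temperature rise and time to return to
    baseline, the paired histology and MRTI ablation volumes, and an
    ``included`` flag (two animals were excluded for suboptimal TTC
    staining, recorded in ``exclusion_reason``).
    """
    with resources.files("mrtherm.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["included"] = df["included"].astype(bool)
    return df


def _affine(geometry: Geometry) -> np.ndarray:
    dy, dx = geometry.pixel_spacing_mm
    return np.diag([dy, dx, geometry.slice_thickness_mm, 1.0])


def _to_nifti_order(arr: np.ndarray) -> np.ndarray:
    """(frame, slice, row, col) -> (row, col, slice, frame)."""
    return np.transpose(arr, (2, 3, 1, 0))


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (3, 2, 0, 1))


def _geometry_from_img(img) -> Geometry:
    zooms = img.header.get_zooms()
    return Geometry((float(zooms[0]), float(zooms[1])), float(zooms[2]))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_phase_series(
    path, series: PhaseSeries, acq: AcquisitionParams | None = None
) -> Path:
    """Write a phase series as 4-D NIfTI plus a JSON parameter sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(_to_nifti_order(series.phase), _affine(series.geometry))
    nib.save(img, path)
    sidecar = {
        "kind": "phase_series",
        "timestamps_s": series.timestamps_s.tolist(),
        "baseline_frames": series.baseline_frames,
        "geometry": dataclasses.asdict(series.geometry),
    }
    if acq is not None:
        sidecar["acquisition"] = dataclasses.asdict(acq)
    write_json(_sidecar_path(path), sidecar)
    return path


def read_phase_series(path) -> tuple[PhaseSeries, AcquisitionParams | None]:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    series = PhaseSeries(
        phase=_from_nifti_order(np.asarray(img.dataobj, dtype=float)),
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
        geometry=_geometry_from_img(img),
        baseline_frames=int(meta["baseline_frames"]),
    )
    acq = None
    if "acquisition" in meta:
        raw = dict(meta["acquisition"])
        for key in ("fov_mm", "matrix"):
            if key in raw:
                raw[key] = tuple(raw[key])
        acq = AcquisitionParams(**raw)
    return series, acq


def write_temperature_series(path, temps: TemperatureSeries) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(_to_nifti_order(temps.delta_T), _affine(temps.geometry))
    nib.save(img, path)
    write_json(
        _sidecar_path(path),
        {
            "kind": "temperature_series",
            "timestamps_s": temps.timestamps_s.tolist(),
            "baseline_temp_C": temps.baseline_temp_C,
            "geometry": dataclasses.asdict(temps.geometry),
        },
    )
    return path


def read_temperature_series(path) -> TemperatureSeries:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return TemperatureSeries(
        delta_T=_from_nifti_order(np.asarray(img.dataobj, dtype=float)),
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
        geometry=_geometry_from_img(img),
        baseline_temp_C=float(meta["baseline_temp_C"]),
    )


def write_dose_map(path, dose: DoseMap) -> Path:
    path = Path(path)
    arr = np.transpose(dose.cem43, (1, 2, 0))  # (row, col, slice)
    nib.save(nib.Nifti1Image(arr, _affine(dose.geometry)), path)
    return path


def read_dose_map(path) -> DoseMap:
    img = nib.load(Path(path))
    arr = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 0, 1))
    return DoseMap(cem43=arr, geometry=_geometry_from_img(img))


def write_mask(path, mask: np.ndarray, geometry: Geometry) -> Path:
    path = Path(path)
    arr = np.transpose(np.asarray(mask, dtype=np.uint8), (1, 2, 0))
    nib.save(nib.Nifti1Image(arr, _affine(geometry)), path)
    return path


def read_mask(path) -> np.ndarray:
    img = nib.load(Path(path))
    return np.transpose(np.asarray(img.dataobj) > 0, (2, 0, 1))


def write_sections_csv(path, sections: HistologySectionSet) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "slice_index": [s.slice_index for s in sections.sections],
            "area_cm2": [s.area_cm2 for s in sections.sections],
            "full_thickness": [s.full_thickness for s in sections.sections],
            "slice_thickness_mm": sections.slice_thickness_cm * 10.0,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_sections_csv(path) -> HistologySectionSet:
    df = pd.read_csv(Path(path))
    thickness_mm = float(df["slice_thickness_mm"].iloc[0]) if len(df) else 5.0
    sections = tuple(
        HistologySection(
            slice_index=int(row.slice_index),
            area_cm2=float(row.area_cm2),
            full_thickness=bool(row.full_thickness),
        )
        for row in df.itertuples()
    )
    return HistologySectionSet(sections=sections, slice_thickness_cm=thickness_mm / 10.0)


def write_roi_curve_csv(path, curve: RoiCurve) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": curve.times_s, "mean_dT_C": curve.mean_dT}).to_csv(
        path, index=False
    )
    return path


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
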