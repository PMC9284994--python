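"""Proton-resonance-frequency-shift (PRFS) MR thermometry.

The water proton resonance frequency decreases approximately linearly
with temperature, so the phase of a gradient-echo image acquired at echo
time TE shifts by ``gamma * alpha * B0 * TE * dT`` radians for a
temperature change ``dT``.  With the nominal aqueous-tissue coefficient
alpha = -0.01 ppm/degC, heating produces a *negative* phase shift.

Two reconstruction routes are provided:

* **Referenced** (:func:`phase_difference` -> :func:`fit_drift_polynomial`
  -> :func:`prfs_temperature`): subtract a pre-heating baseline phase,
  then remove the slow spatial phase drift of the static field by
  fitting a 2nd-order 2-D polynomial to the phase difference in a
  non-heated reference region (a thin ring at the outer edge of the
  brain) and subtracting the fitted surface evaluated everywhere.
* **Referenceless** (:func:`referenceless_temperature`): unwrap the
  phase difference with the Goldstein branch-cut algorithm, fit a
  4th-order polynomial background on the same edge region, and subtract
  it.  Intended as a fallback when the baseline is invalidated (e.g. by
  subject motion).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Geometry

__all__ = [
    "AcquisitionParams",
    "PhaseSeries",
    "ReferenceRegion",
    "TemperatureSeries",
    "RoiCurve",
    "UnwrapResult",
    "wrap_phase",
    "phase_difference",
    "make_edge_reference",
    "fit_drift_polynomial",
    "prfs_temperature",
    "goldstein_unwrap",
    "referenceless_temperature",
    "reconstruct_temperature_series",
    "roi_mean_curve",
]

GAMMA_H_RAD_PER_S_T = 2.0 * np.pi * 42.576e6
"""Proton gyromagnetic ratio, rad/s/T."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Scan parameters entering the PRFS temperature conversion.

    alpha is the PRFS thermal coefficient in ppm/degC (nominal -0.01
    for aqueous tissue); gamma is the gyromagnetic ratio in rad/s/T.
    """

    B0: float = 3.0
    TE: float = 13.2e-3
    alpha: float = -0.01
    gamma: float = GAMMA_H_RAD_PER_S_T
    fov_mm: tuple[float, float] = (150.0, 150.0)
    matrix: tuple[int, int] = (256, 256)
    slice_thickness_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.B0 <= 0 or self.TE <= 0:
            raise ValueError("B0 and TE must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def rad_per_degC(self) -> float:
        """Phase shift per degC: gamma * alpha(dimensionless) * B0 * TE."""
        return self.gamma * self.alpha * 1e-6 * self.B0 * self.TE

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.pixel_spacing_mm, self.slice_thickness_mm)


def wrap_phase(phi):
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped-phase image time series, ``phase[frame, slice, row, col]``.

    ``baseline_frames`` leading frames are pre-heating references.
    """

    phase: np.ndarray
    timestamps_s: np.ndarray
    geometry: Geometry
    baseline_frames: int = 1

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        ts = np.asarray(self.timestamps_s, dtype=float)
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "timestamps_s", ts)
        if phase.ndim != 4:
            raise ValueError(f"phase must be (frame, slice, row, col), got {phase.shape}")
        if ts.shape != (phase.shape[0],):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 1 <= self.baseline_frames <= phase.shape[0]:
            raise ValueError("baseline_frames must be >= 1 and <= number of frames")
        if np.any(np.abs(phase) > np.pi + 1e-9):
            raise ValueError("phase values must lie in (-pi, pi]")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def n_slices(self) -> int:
        return self.phase.shape[1]


@dataclass(frozen=True)
class ReferenceRegion:
    """Non-heated reference mask (one boolean map per slice)."""

    mask: np.ndarray
    width_px: int = 3

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3:
            raise ValueError("mask must be (slice, row, col)")
        empties = [s for s in range(mask.shape[0]) if not mask[s].any()]
        if empties:
            raise ValueError(f"reference region empty on slice(s) {empties}")


@dataclass(frozen=True)
class TemperatureSeries:
    """Temperature-change maps, ``delta_T[frame, slice, row, col]`` in degC.

    Frames correspond one-to-one to the post-baseline frames of the
    source :class:`PhaseSeries`; absolute temperature is
    ``baseline_temp_C + delta_T``.
    """

    delta_T: np.ndarray
    timestamps_s: np.ndarray
    geometry: Geometry
    baseline_temp_C: float = 37.0

    def __post_init__(self) -> None:
        dT = np.asarray(self.delta_T, dtype=float)
        ts = np.asarray(self.timestamps_s, dtype=float)
        object.__setattr__(self, "delta_T", dT)
        object.__setattr__(self, "timestamps_s", ts)
        if dT.ndim != 4:
            raise ValueError(f"delta_T must be (frame, slice, row, col), got {dT.shape}")
        if ts.shape != (dT.shape[0],):
            raise ValueError("one timestamp per frame required")
        if not np.all(np.isfinite(dT)):
            raise ValueError("delta_T must be finite")

    @property
    def n_frames(self) -> int:
        return self.delta_T.shape[0]


def phase_difference(series: PhaseSeries, frame: int) -> np.ndarray:
    """Wrapped phase difference of ``frame`` against the baseline.

    The baseline phase is the circular mean of the ``baseline_frames``
    leading frames; the difference is taken on the unit circle
    (``angle(e^{i phi_f} * conj(z_baseline))``) so it is correctly
    wrapped even across the +/-pi seam.
    """
    if not series.baseline_frames <= frame < series.n_frames:
        raise IndexError(
            f"frame {frame} out of range [{series.baseline_frames}, {series.n_frames})"
        )
    z_base = np.exp(1j * series.phase[: series.baseline_frames]).mean(axis=0)
    return np.angle(np.exp(1j * series.phase[frame]) * np.conj(z_base))


def make_edge_reference(brain_mask: np.ndarray, width_px: int = 3) -> ReferenceRegion:
    """Ring of the outer ``width_px`` morphological shells of a brain mask.

    The ring is ``mask & ~erode(mask, width_px)`` per slice with
    4-connected erosion, mirroring a contour drawn around the outer
    edge of the visible brain.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.ndim == 2:
        mask = mask[None]
    if width_px < 1:
        raise ValueError(f"width_px must be >= 1, got {width_px}")
    rings = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        if not mask[s].any():
            raise ValueError(f"brain mask empty on slice {s}")
        eroded = ndimage.binary_erosion(mask[s], iterations=width_px)
        if not eroded.any():
            raise ValueError(
                f"slice {s}: mask erodes to empty before width {width_px} reached"
            )
        rings[s] = mask[s] & ~eroded
    return ReferenceRegion(mask=rings, width_px=width_px)


def _poly_terms(order: int):
    return [(i, j) for i in range(order + 1) for j in range(order + 1 - i)]


def _design_matrix(rows, cols, shape, order):
    ny, nx = shape
    # normalized coordinates in [-1, 1] for numerical conditioning
    y = 2.0 * rows / max(ny - 1, 1) - 1.0
    x = 2.0 * cols / max(nx - 1, 1) - 1.0
    return np.column_stack([x**i * y**j for i, j in _poly_terms(order)])


def fit_drift_polynomial(
    phase_diff: np.ndarray, region: ReferenceRegion, order: int = 2
) -> np.ndarray:
    """Least-squares 2-D polynomial drift surface, evaluated everywhere.

    Fits, per slice, a polynomial of total degree <= ``order`` in
    normalized pixel coordinates to ``phase_diff`` restricted to the
    reference region, and returns the surface over the full slice.
    This is the background phase attributed to B0 drift.
    """
    pd = np.asarray(phase_diff, dtype=float)
    squeeze = pd.ndim == 2
    if squeeze:
        pd = pd[None]
    mask = region.mask
    if mask.shape != pd.shape:
        raise ValueError(f"region mask shape {mask.shape} != phase_diff shape {pd.shape}")
    n_terms = len(_poly_terms(order))
    surface = np.empty_like(pd)
    ny, nx = pd.shape[1:]
    gy, gx = np.mgrid[0:ny, 0:nx]
    A_full = _design_matrix(gy.ravel(), gx.ravel(), (ny, nx), order)
    for s in range(pd.shape[0]):
        rows, cols = np.nonzero(mask[s])
        if rows.size < n_terms:
            raise ValueError(
                f"slice {s}: region has {rows.size} pixels, "
                f"fewer than the {n_terms} polynomial coefficients"
            )
        A = _design_matrix(rows, cols, (ny, nx), order)
        coef, _, rank, _ = np.linalg.lstsq(A, pd[s][rows, cols], rcond=None)
        if rank < n_terms:
            raise ValueError(
                f"slice {s}: degenerate reference geometry, design matrix rank "
                f"{rank} < {n_terms} coefficients"
            )
        surface[s] = (A_full @ coef).reshape(ny, nx)
    return surface[0] if squeeze else surface


def prfs_temperature(
    phase_diff: np.ndarray, drift_surface, acq: AcquisitionParams
) -> np.ndarray:
    """Convert drift-corrected phase difference to temperature change.

    ``dT = (dphi_w - dphi_cor) / (gamma * alpha * B0 * TE)`` with alpha
    converted from ppm/degC to dimensionless.  With alpha < 0, heating
    corresponds to negative corrected phase.
    """
    pd = np.asarray(phase_diff, dtype=float)
    if drift_surface is None:
        drift = np.zeros_like(pd)
    else:
        drift = np.asarray(drift_surface, dtype=float)
        if drift.shape != pd.shape:
            raise ValueError(f"shape mismatch: {pd.shape} vs {drift.shape}")
    denom = acq.rad_per_degC
    if denom == 0:
        raise ValueError("gamma*alpha*B0*TE is zero; temperature undefined")
    return (pd - drift) / denom


@dataclass(frozen=True)
class UnwrapResult:
    """Unwrapped phase plus a flag map of pixels cut off by branch cuts."""

    phase: np.ndarray
    flagged: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def _residue_map(phase: np.ndarray) -> np.ndarray:
    """Integer residue charge on each 2x2 loop (top-left corner indexed)."""
    d1 = wrap_phase(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = wrap_phase(phase[1:, 1:] - phase[:-1, 1:])
    d3 = wrap_phase(phase[1:, :-1] - phase[1:, 1:])
    d4 = wrap_phase(phase[:-1, :-1] - phase[1:, :-1])
    return np.rint((d1 + d2 + d3 + d4) / (2.0 * np.pi)).astype(int)


def _draw_cut(barrier: np.ndarray, p0, p1) -> None:
    """Mark barrier pixels on the straight segment from p0 to p1."""
    r0, c0 = p0
    r1, c1 = p1
    n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    barrier[rr, cc] = True


def goldstein_unwrap(phase: np.ndarray) -> UnwrapResult:
    """Goldstein branch-cut unwrapping of a 2-D wrapped phase map.

    Residues are detected on 2x2 loops; opposite-sign residues are
    paired greedily by nearest-neighbor distance (row-major tie-break)
    and joined by branch cuts, with unpaired residues cut to the nearest
    border.  A flood fill integrates wrapped phase gradients without
    crossing cuts; pixels only reachable across a cut are flagged.  The
    result is unique up to a global multiple of 2*pi.
    """
    p = np.asarray(phase, dtype=float)
    if p.ndim != 2:
        raise ValueError("goldstein_unwrap expects a 2-D map")
    ny, nx = p.shape
    barrier = np.zeros((ny, nx), dtype=bool)

    charges = _residue_map(p)
    pos = [tuple(rc) for rc in np.argwhere(charges > 0)]
    neg = [tuple(rc) for rc in np.argwhere(charges < 0)]
    # greedy nearest-neighbor pairing, scan order row-major over positives
    unpaired_neg = list(neg)
    for pr in pos:
        if unpaired_neg:
            d2 = [(pr[0] - q[0]) ** 2 + (pr[1] - q[1]) ** 2 for q in unpaired_neg]
            k = int(np.argmin(d2))  # argmin keeps row-major tie-break
            _draw_cut(barrier, pr, unpaired_neg.pop(k))
        else:
            _cut_to_border(barrier, pr, ny, nx)
    for q in unpaired_neg:
        _cut_to_border(barrier, q, ny, nx)

    unwrapped = p.copy()
    visited = barrier.copy()
    two_pi = 2.0 * np.pi
    seeds = np.argwhere(~visited)
    if seeds.size:
        queue: deque = deque()
        r0, c0 = seeds[0]
        visited[r0, c0] = True
        queue.append((int(r0), int(c0)))
        while queue:
            r, c = queue.popleft()
            here = unwrapped[r, c]
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < ny and 0 <= nc < nx and not visited[nr, nc]:
                    # integer wrap count keeps wrap(unwrapped) == input exactly
                    k = np.rint((here + wrap_phase(p[nr, nc] - here) - p[nr, nc]) / two_pi)
                    unwrapped[nr, nc] = p[nr, nc] + two_pi * k
                    visited[nr, nc] = True
                    queue.append((nr, nc))
    return UnwrapResult(phase=unwrapped, flagged=~visited | barrier)


def _cut_to_border(barrier: np.ndarray, p, ny: int, nx: int) -> None:
    r, c = p
    dists = [(r, (0, c)), (ny - 1 - r, (ny - 1, c)), (c, (r, 0)), (nx - 1 - c, (r, nx - 1))]
    _, target = min(dists, key=lambda t: t[0])
    _draw_cut(barrier, p, target)


def referenceless_temperature(
    phase_diff: np.ndarray,
    edge: ReferenceRegion,
    acq: AcquisitionParams,
    order: int = 4,
) -> np.ndarray:
    """Referenceless PRFS reconstruction via Goldstein unwrapping.

    Unwraps the (possibly wrapped) phase difference per slice, fits an
    ``order``-degree polynomial background on the non-heated edge
    region, subtracts it everywhere, and converts to degC.
    """
    pd = np.asarray(phase_diff, dtype=float)
    squeeze = pd.ndim == 2
    if squeeze:
        pd = pd[None]
    unwrapped = np.empty_like(pd)
    flags = np.zeros(pd.shape, dtype=bool)
    for s in range(pd.shape[0]):
        res = goldstein_unwrap(pd[s])
        unwrapped[s] = res.phase
        flags[s] = res.flagged
    fit_region = ReferenceRegion(mask=edge.mask & ~flags, width_px=edge.width_px)
    background = fit_drift_polynomial(unwrapped, fit_region, order=order)
    dT = prfs_temperature(unwrapped, background, acq)
    return dT[0] if squeeze else dT


def reconstruct_temperature_series(
    series: PhaseSeries,
    brain_mask: np.ndarray,
    acq: AcquisitionParams | None = None,
    method: str = "referenced",
    order: int | None = None,
    edge_width_px: int = 3,
    baseline_temp_C: float = 37.0,
) -> TemperatureSeries:
    """Full thermometry reconstruction of a phase series.

    Runs baseline phase differencing, background removal on the
    brain-edge reference ring, and PRFS conversion for every
    post-baseline frame.  ``method`` selects the referenced route
    (2nd-order drift polynomial by default) or the referenceless route
    (Goldstein unwrap + 4th-order background by default).
    """
    acq = acq or AcquisitionParams()
    if method not in ("referenced", "referenceless"):
        raise ValueError(f"unknown method {method!r}")
    if order is None:
        order = 2 if method == "referenced" else 4
    edge = make_edge_reference(brain_mask, width_px=edge_width_px)
    frames = []
    for f in range(series.baseline_frames, series.n_frames):
        pd = phase_difference(series, f)
        if method == "referenced":
            drift = fit_drift_polynomial(pd, edge, order=order)
            frames.append(prfs_temperature(pd, drift, acq))
        else:
            frames.append(referenceless_temperature(pd, edge, acq, order=order))
    return TemperatureSeries(
        delta_T=np.stack(frames),
        timestamps_s=series.timestamps_s[series.baseline_frames :],
        geometry=series.geometry,
        baseline_temp_C=baseline_temp_C,
    )


@dataclass(frozen=True)
class RoiCurve:
    """ROI mean temperature-change curve with summary metrics.

    ``time_to_baseline_s`` is measured from ``sonication_end_s`` to the
    first later frame whose ROI mean dT is <= ``epsilon_C``; it is NaN
    (and ``returned_to_baseline`` False) if the curve never returns.
    """

    times_s: np.ndarray
    mean_dT: np.ndarray
    max_dT: float
    time_of_max_s: float
    time_to_baseline_s: float
    returned_to_baseline: bool
    epsilon_C: float = 1.0


def roi_mean_curve(
    temps: TemperatureSeries,
    roi: np.ndarray,
    epsilon_C: float = 1.0,
    sonication_end_s: float | None = None,
) -> RoiCurve:
    """Mean temperature change over an ROI, per frame.

    Parameters
    ----------
    roi : boolean map, shape (slice, row, col) or (row, col) broadcast
        over slices.  Must be nonempty.
    epsilon_C : float
        Return-to-baseline tolerance (degC).
    sonication_end_s : float, optional
        Heating shutoff time; defaults to the time of the curve maximum.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.ndim == 2:
        roi = np.broadcast_to(roi[None], temps.delta_T.shape[1:])
    if roi.shape != temps.delta_T.shape[1:]:
        raise ValueError(f"roi shape {roi.shape} != map shape {temps.delta_T.shape[1:]}")
    if not roi.any():
        raise ValueError("ROI is empty")
    curve = temps.delta_T[:, roi].mean(axis=1)
    times = temps.timestamps_s
    i_max = int(np.argmax(curve))
    end = float(times[i_max]) if sonication_end_s is None else float(sonication_end_s)
    after = (times > end) & (curve <= epsilon_C)
    if after.any():
        t_back = float(times[np.argmax(after)] - end)
        returned = True
    else:
        t_back = float("nan")
        returned = False
    return RoiCurve(
        times_s=times.copy(),
        mean_dT=curve,
        max_dT=float(curve[i_max]),
        time_of_max_s=float(times[i_max]),
        time_to_baseline_s=t_back,
        returned_to_baseline=returned,
        epsilon_C=epsilon_C,
    )
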