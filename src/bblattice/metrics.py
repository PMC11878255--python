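"""Beam metrology: FWHMs, beamlet detection, lattice extent, axial range.

All widths are full widths at half maximum (FWHM) of intensity profiles,
located by linear interpolation between the samples bracketing each
half-maximum crossing. Transverse metrology is read off the plane of maximal
on-axis (beam-row) intensity; longitudinal metrology is read off the on-axis
intensity versus z. The diffraction-free range of a sheet is the maximal
contiguous z-interval around focus over which the mean beamlet y-FWHM stays
at or below a thickness threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield

import numpy as np

from .field import IntensityStack, OpticalField

__all__ = [
    "AxialReport",
    "LatticeReport",
    "fwhm_1d",
    "find_peaks_1d",
    "lattice_report",
    "axial_report",
    "transmittance_efficiency",
]


class UnboundedProfileError(ValueError):
    """The profile never falls below half maximum on one side of the peak."""


@dataclass
class LatticeReport:
    """Focal-plane metrology of a beam array."""

    z_focus: float
    beamlet_centers: list[float]
    fwhm_x: list[float]
    fwhm_y: list[float]
    extent_x: float
    rel_thresh: float
    min_sep: float

    @property
    def count(self) -> int:
        return len(self.beamlet_centers)

    @property
    def max_fwhm_y(self) -> float:
        return max(self.fwhm_y) if self.fwhm_y else float("nan")

    def to_dict(self) -> dict:
        return {
            "z_focus": self.z_focus,
            "count": self.count,
            "beamlet_centers": list(self.beamlet_centers),
            "fwhm_x": list(self.fwhm_x),
            "fwhm_y": list(self.fwhm_y),
            "extent_x": self.extent_x,
            "max_fwhm_y": self.max_fwhm_y,
            "rel_thresh": self.rel_thresh,
            "min_sep": self.min_sep,
        }


@dataclass
class AxialReport:
    """Longitudinal metrology of a beam or sheet."""

    z_peak: float
    fwhm_z: float
    df_range: tuple[float, float, float] | None
    threshold: float = _dfield(default=float("nan"))
    z_unbounded: bool = False  # scan did not bracket the axial half maximum

    def to_dict(self) -> dict:
        return {
            "z_peak": self.z_peak,
            "fwhm_z": self.fwhm_z if not self.z_unbounded else None,
            "z_unbounded": self.z_unbounded,
            "df_range": list(self.df_range) if self.df_range else None,
            "fwhm_y_threshold": self.threshold,
        }


def _cross(coords: np.ndarray, values: np.ndarray, i0: int, i1: int, level: float) -> float:
    """Linear interpolation of the coordinate where values crosses level."""
    v0, v1 = values[i0], values[i1]
    if v1 == v0:
        return float(coords[i0])
    return float(coords[i0] + (level - v0) * (coords[i1] - coords[i0]) / (v1 - v0))


def fwhm_1d(values: np.ndarray, coords: np.ndarray, peak_index: int | None = None) -> float:
    """FWHM around the (global or given) peak of a sampled profile.

    The crossings are the first samples below half maximum on each side of
    the peak, refined by linear interpolation. Raises
    :class:`UnboundedProfileError` if the profile never drops below half
    maximum on either side.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if values.ndim != 1 or values.size < 5:
        raise ValueError("need a 1D profile with at least 5 samples")
    if values.size != coords.size:
        raise ValueError("values and coords must have equal length")
    if np.any(values < 0):
        raise ValueError("intensity profile must be non-negative")
    ipk = int(np.argmax(values)) if peak_index is None else int(peak_index)
    half = values[ipk] / 2.0
    i = ipk
    while i > 0 and values[i - 1] >= half:
        i -= 1
    if i == 0 and values[0] >= half:
        raise UnboundedProfileError("profile does not fall below half maximum on the left")
    left = _cross(coords, values, i - 1, i, half)
    j = ipk
    n = values.size
    while j < n - 1 and values[j + 1] >= half:
        j += 1
    if j == n - 1 and values[-1] >= half:
        raise UnboundedProfileError("profile does not fall below half maximum on the right")
    right = _cross(coords, values, j, j + 1, half)
    return right - left


def find_peaks_1d(
    values: np.ndarray,
    coords: np.ndarray,
    min_sep: float,
    rel_thresh: float,
) -> list[float]:
    """Sub-sample positions of local maxima above ``rel_thresh``·max.

    Peaks closer than ``min_sep`` to a stronger one are suppressed; centers
    are refined by a parabolic fit through the three samples around each
    maximum.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    level = rel_thresh * values.max()
    cand = [
        i
        for i in range(1, values.size - 1)
        if values[i] >= level and values[i] >= values[i - 1] and values[i] > values[i + 1]
    ]
    cand.sort(key=lambda i: -values[i])
    kept: list[int] = []
    for i in cand:
        if all(abs(coords[i] - coords[j]) >= min_sep for j in kept):
            kept.append(i)
    centers = []
    for i in sorted(kept):
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
        centers.append(float(coords[i] + shift * (coords[min(i + 1, values.size - 1)] - coords[i])))
    return centers


def _beam_row(frame: np.ndarray) -> int:
    return int(np.unravel_index(np.argmax(frame), frame.shape)[0])


def _frame_lattice(
    frame: np.ndarray,
    grid,
    min_sep: float,
    rel_thresh: float,
) -> tuple[list[float], list[float], list[float], float | None, int]:
    """Detect beamlets on one frame; returns (centers, fwhm_x, fwhm_y, extent, row)."""
    row = _beam_row(frame)
    xprof = np.asarray(frame[row], dtype=float)
    x = grid.x
    centers = find_peaks_1d(xprof, x, min_sep=min_sep, rel_thresh=rel_thresh)
    fx, fy = [], []
    for c in centers:
        icol = int(np.argmin(np.abs(x - c)))
        fx.append(fwhm_1d(xprof, x, peak_index=icol))
        fy.append(fwhm_1d(np.asarray(frame[:, icol], dtype=float), grid.y, peak_index=row))
    extent = None
    if centers:
        # outermost crossings at each edge beamlet's *own* half maximum, so the
        # measure is meaningful also for inhomogeneous (overwrite-multiplexed)
        # arrays; for homogeneous arrays this coincides with the half-maximum
        # crossings of the global profile.
        il = int(np.argmin(np.abs(x - centers[0])))
        ir = int(np.argmin(np.abs(x - centers[-1])))
        half_l = xprof[il] / 2.0
        i = il
        while i > 0 and xprof[i - 1] >= half_l:
            i -= 1
        left = _cross(x, xprof, max(i - 1, 0), i, half_l) if i > 0 else float(x[0])
        half_r = xprof[ir] / 2.0
        j = ir
        while j < xprof.size - 1 and xprof[j + 1] >= half_r:
            j += 1
        right = (
            _cross(x, xprof, j, j + 1, half_r) if j < xprof.size - 1 else float(x[-1])
        )
        extent = right - left
    return centers, fx, fy, extent, row


def lattice_report(
    stack: IntensityStack,
    min_sep: float = 10.0,
    rel_thresh: float = 0.15,
) -> LatticeReport:
    """Focal-plane beamlet metrology of an intensity z-stack.

    The focal plane is the frame holding the global intensity maximum; the
    beam row is the y-row through that maximum. Beamlets are local maxima of
    the row's x-profile above ``rel_thresh`` of its maximum, separated by at
    least ``min_sep`` µm; per-beamlet FWHMs come from x- and y-cuts through
    each (parabolically refined) center, and the lattice extent is the
    distance between the outermost half-maximum crossings of the x-profile.
    """
    iz = int(np.argmax([f.max() for f in stack.frames]))
    frame = np.asarray(stack.frames[iz], dtype=float)
    centers, fx, fy, extent, _ = _frame_lattice(frame, stack.grid, min_sep, rel_thresh)
    if not centers:
        import warnings

        warnings.warn("no beamlets found above threshold; empty report", stacklevel=2)
        return LatticeReport(float(stack.z_list[iz]), [], [], [], float("nan"), rel_thresh, min_sep)
    return LatticeReport(
        z_focus=float(stack.z_list[iz]),
        beamlet_centers=centers,
        fwhm_x=fx,
        fwhm_y=fy,
        extent_x=float(extent),
        rel_thresh=rel_thresh,
        min_sep=min_sep,
    )


def axial_report(
    stack: IntensityStack,
    at: tuple[float, float] = (0.0, 0.0),
    fwhm_y_threshold: float = 7.0,
    min_sep: float = 10.0,
    rel_thresh: float = 0.15,
) -> AxialReport:
    """Longitudinal metrology: on-axis FWHM_z and diffraction-free range.

    ``fwhm_z`` is the FWHM of the intensity versus z at the lateral point
    ``at``. The diffraction-free range is the maximal contiguous z-interval
    containing the axial peak over which the mean beamlet y-FWHM stays at or
    below ``fwhm_y_threshold`` (µm); ``None`` when the threshold is never met
    at the peak. Beamlet lateral positions are detected once, on the focal
    plane, and the y-widths are then tracked at those fixed positions through
    the scan — mirroring a z-scan characterization, and immune to spurious
    defocus structure that per-plane re-detection would pick up.
    """
    grid = stack.grid
    icol = int(np.argmin(np.abs(grid.x - at[0])))
    irow = int(np.argmin(np.abs(grid.y - at[1])))
    onaxis = np.asarray(stack.frames[:, irow, icol], dtype=float)
    z = stack.z_list
    z_peak = float(z[int(np.argmax(onaxis))])
    z_unbounded = False
    try:
        fwhm_z = fwhm_1d(onaxis, z)
    except UnboundedProfileError:
        fwhm_z = float("nan")
        z_unbounded = True

    iz_focus = int(np.argmax([f.max() for f in stack.frames]))
    focal = np.asarray(stack.frames[iz_focus], dtype=float)
    centers, _, _, _, _ = _frame_lattice(focal, grid, min_sep, rel_thresh)
    cols = [int(np.argmin(np.abs(grid.x - c))) for c in centers]
    ok = np.zeros(len(stack), dtype=bool)
    for i in range(len(stack)):
        frame = np.asarray(stack.frames[i], dtype=float)
        widths = []
        try:
            for c in cols:
                cut = np.asarray(frame[:, c], dtype=float)
                widths.append(fwhm_1d(cut, grid.y))
        except UnboundedProfileError:
            continue
        if widths:
            ok[i] = float(np.mean(widths)) <= fwhm_y_threshold
    ipk = int(np.argmax(onaxis))
    df = None
    if ok[ipk]:
        i0 = ipk
        while i0 > 0 and ok[i0 - 1]:
            i0 -= 1
        i1 = ipk
        while i1 < len(stack) - 1 and ok[i1 + 1]:
            i1 += 1
        df = (float(z[i0]), float(z[i1]), float(z[i1] - z[i0]))
    return AxialReport(
        z_peak=z_peak,
        fwhm_z=fwhm_z,
        df_range=df,
        threshold=fwhm_y_threshold,
        z_unbounded=z_unbounded,
    )


def transmittance_efficiency(
    input_field: OpticalField | None,
    stack: IntensityStack,
    aperture_radius: float,
    z_ref: float,
    z_focal: float,
    center: tuple[float, float] | None = None,
) -> float:
    """Power within a circular aperture at the focal plane over the power
    within the same aperture at the reference plane.

    The aperture is centered on the focal-plane intensity maximum unless
    ``center`` is given. Planes are taken from the nearest stack frames; if
    ``z_ref`` lies outside the stack but matches ``input_field.z``, the
    reference intensity is read from ``input_field`` directly (the usual case
    z_ref = 0, the modulation plane).
    """
    grid = stack.grid
    if aperture_radius > min(grid.window) / 2:
        raise ValueError("aperture exceeds the simulation window")
    focal = np.asarray(stack.frame_at(z_focal), dtype=float)
    if (z_ref < stack.z_list[0] or z_ref > stack.z_list[-1]) and input_field is not None:
        if abs(input_field.z - z_ref) > 1e-9:
            raise ValueError(
                f"z_ref={z_ref} is outside the stack and input_field sits at z={input_field.z}"
            )
        ref = input_field.intensity()
    else:
        ref = np.asarray(stack.frame_at(z_ref), dtype=float)
    if center is None:
        irow, icol = np.unravel_index(np.argmax(focal), focal.shape)
        center = (float(grid.x[icol]), float(grid.y[irow]))
    xx, yy = grid.mesh()
    ap = np.hypot(xx - center[0], yy - center[1]) <= aperture_radius
    p_ref = float(np.sum(ref[ap]))
    if p_ref == 0:
        raise ValueError("no power inside the aperture at the reference plane")
    return float(np.sum(focal[ap]) / p_ref)
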