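"""Sampled scalar fields on centered Cartesian grids.

All lengths are in micrometres (µm). A :class:`GridSpec` fixes the sampling
lattice; :class:`OpticalField` carries a complex scalar field at one axial
position; :class:`IntensityStack` holds |E|² frames over an ordered list of
axial positions and is what all metrology consumes.

The grid is centered so that sample index ``(ny//2, nx//2)`` lies exactly at
the physical origin, i.e. ``x_i = (i - nx//2) * dx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield

import numpy as np

__all__ = [
    "GridSpec",
    "InputBeamSpec",
    "OpticalField",
    "IntensityStack",
    "make_grid",
    "make_input_beam",
    "field_power",
]


@dataclass(frozen=True)
class GridSpec:
    """Sampling lattice of a simulation window.

    Attributes
    ----------
    nx, ny : int
        Sample counts along x (columns) and y (rows); at least 16.
    dx, dy : float
        Sample pitch in µm; strictly positive.
    """

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        for name, n in (("nx", self.nx), ("ny", self.ny)):
            if int(n) != n or n < 16:
                raise ValueError(f"{name} must be an integer >= 16, got {n!r}")
        for name, d in (("dx", self.dx), ("dy", self.dy)):
            if not (d > 0):
                raise ValueError(f"{name} must be positive, got {d!r}")

    @property
    def x(self) -> np.ndarray:
        """1D x-coordinates (µm), zero at index ``nx//2``."""
        return (np.arange(self.nx) - self.nx // 2) * self.dx

    @property
    def y(self) -> np.ndarray:
        """1D y-coordinates (µm), zero at index ``ny//2``."""
        return (np.arange(self.ny) - self.ny // 2) * self.dy

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (X, Y) coordinate rasters with shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    @property
    def window(self) -> tuple[float, float]:
        """Physical window size (x, y) in µm."""
        return (self.nx * self.dx, self.ny * self.dy)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def fx(self) -> np.ndarray:
        """Spatial frequencies along x (cycles/µm, FFT order)."""
        return np.fft.fftfreq(self.nx, self.dx)

    def fy(self) -> np.ndarray:
        return np.fft.fftfreq(self.ny, self.dy)


@dataclass(frozen=True)
class InputBeamSpec:
    """Illumination incident on the modulation plane.

    ``kind`` is ``"uniform"`` (flat unit-phase plane wave) or ``"gaussian"``
    (amplitude ∝ exp(−(x²+y²)/w0²), i.e. 1/e amplitude radius ``w0``).
    """

    kind: str = "uniform"
    w0: float | None = None
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ValueError(f"kind must be 'uniform' or 'gaussian', got {self.kind!r}")
        if self.kind == "gaussian" and not (self.w0 is not None and self.w0 > 0):
            raise ValueError("gaussian beam requires w0 > 0")


@dataclass
class OpticalField:
    """A sampled 2D complex scalar field at axial position ``z``.

    ``data`` has shape ``grid.shape`` and dimensionless amplitude;
    ``wavelength`` and ``z`` are in µm.
    """

    grid: GridSpec
    wavelength: float
    z: float
    data: np.ndarray = _dfield(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength!r}")
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field data contains non-finite values")

    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def power(self) -> float:
        return field_power(self)

    def copy(self) -> "OpticalField":
        return OpticalField(self.grid, self.wavelength, self.z, self.data.copy())


@dataclass
class IntensityStack:
    """|E|² frames over strictly increasing axial positions.

    Frames are stored as float32: metrology works on half-maximum crossings
    and is insensitive to single-precision rounding, while a full z-scan at
    1024² would be needlessly heavy in float64.
    """

    grid: GridSpec
    z_list: np.ndarray
    frames: np.ndarray = _dfield(repr=False, default=None)

    def __post_init__(self) -> None:
        self.z_list = np.asarray(self.z_list, dtype=float)
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.z_list.ndim != 1 or self.z_list.size == 0:
            raise ValueError("z_list must be a non-empty 1D sequence")
        if np.any(np.diff(self.z_list) <= 0):
            raise ValueError("z_list must be strictly increasing")
        if self.frames.shape != (self.z_list.size, *self.grid.shape):
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with "
                f"{self.z_list.size} planes on grid {self.grid.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensity frames must be non-negative")

    def __len__(self) -> int:
        return int(self.z_list.size)

    def frame_at(self, z: float) -> np.ndarray:
        """Frame at the z position nearest to ``z``."""
        return self.frames[int(np.argmin(np.abs(self.z_list - z)))]


def make_grid(nx: int, ny: int, dx: float, dy: float) -> GridSpec:
    """Build a centered sampling grid (validates counts and pitches)."""
    return GridSpec(nx=nx, ny=ny, dx=dx, dy=dy)


def make_input_beam(grid: GridSpec, spec: InputBeamSpec, wavelength: float) -> OpticalField:
    """Construct the input illumination at the modulation plane (z = 0).

    Uniform beams are flat in amplitude and phase; Gaussian beams have
    amplitude ``amplitude * exp(-(x²+y²)/w0²)`` and flat phase.
    """
    if not (wavelength > 0):
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    if spec.kind == "uniform":
        data = np.full(grid.shape, spec.amplitude, dtype=np.complex128)
    else:
        xx, yy = grid.mesh()
        data = (spec.amplitude * np.exp(-(xx**2 + yy**2) / spec.w0**2)).astype(
            np.complex128
        )
    return OpticalField(grid=grid, wavelength=wavelength, z=0.0, data=data)


def field_power(field: OpticalField) -> float:
    """Total power Σ|E|²·dx·dy of a field (µm²-scaled, dimensionless E)."""
    return float(np.sum(np.abs(field.data) ** 2) * field.grid.dx * field.grid.dy)
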