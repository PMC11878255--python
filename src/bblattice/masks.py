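"""Single-plane complex transmission masks for Bessel-beam lattices.

One beamlet is encoded by an annular amplitude mask combined with the exact
(non-paraxial) phase of a converging lens,

    phi_ring(x, y) = -(2*pi/lambda) * (sqrt(r^2 + f^2) - f),    r about the
    beamlet center,

restricted to the ring support R - Delta <= r <= R (both bounds inclusive).
The annulus selects a thin cone of wavevectors (the quasi-delta-ring spectrum
of a Bessel beam) and the lens phase conjugates it to the image space, so a
single surface acts as apodization mask plus Fourier transformer at once.

A lattice is a list of beamlets multiplexed onto the same plane by one of two
rules: ``sum`` takes the argument of the coherent sum of the beamlet fields;
``overwrite`` lets each consecutive beamlet replace earlier ones on its own
support. Both produce a unit-modulus (phase-only) transmission on the union
of ring supports and zero outside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .field import GridSpec

__all__ = [
    "BeamletSpec",
    "LatticeSpec",
    "DitherSpec",
    "annulus_mask",
    "ring_lens_phase",
    "beamlet_transmission",
    "compose_sum",
    "compose_overwrite",
    "compose",
    "tilt_phase",
    "linear_lattice",
]


@dataclass(frozen=True)
class BeamletSpec:
    """Design parameters of one annulus+lens beamlet.

    R : outer ring radius (µm); delta : ring thickness (µm), 0 < delta < R;
    f : focal length of the encoded lens (µm); center : lateral offset (µm).
    """

    R: float
    delta: float
    f: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.R):
            raise ValueError(
                f"ring thickness must satisfy 0 < delta < R, got delta={self.delta}, R={self.R}"
            )
        if not (self.f > 0):
            raise ValueError(f"focal length must be positive, got {self.f!r}")


@dataclass(frozen=True)
class LatticeSpec:
    """An ordered list of beamlets plus the multiplexing method.

    ``method`` is ``"sum"`` (argument of the coherent field sum) or
    ``"overwrite"`` (later beamlets replace earlier ones on their support).
    ``period`` is a convenience record of the linear-lattice period P.
    """

    beamlets: tuple[BeamletSpec, ...]
    method: str = "overwrite"
    period: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beamlets", tuple(self.beamlets))
        if len(self.beamlets) < 1:
            raise ValueError("a lattice needs at least one beamlet")
        if self.method not in ("sum", "overwrite"):
            raise ValueError(f"method must be 'sum' or 'overwrite', got {self.method!r}")

    @property
    def n(self) -> int:
        return len(self.beamlets)


@dataclass(frozen=True)
class DitherSpec:
    """Weighted input-wavefront tilts used to time-average a virtual sheet."""

    tilts: tuple[tuple[float, float], ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tilts", tuple((float(a), float(b)) for a, b in self.tilts))
        if not self.tilts:
            raise ValueError("at least one tilt required")
        if any(abs(t) >= 0.2 for pair in self.tilts for t in pair):
            raise ValueError("tilt angles must stay paraxial (|theta| < 0.2 rad)")
        w = self.weights
        if w is None:
            w = tuple(1.0 / len(self.tilts) for _ in self.tilts)
        else:
            w = tuple(float(v) for v in w)
            if len(w) != len(self.tilts):
                raise ValueError("weights must match tilts in length")
            if any(v < 0 for v in w):
                raise ValueError("weights must be non-negative")
            s = sum(w)
            if s <= 0:
                raise ValueError("weights must not all be zero")
            w = tuple(v / s for v in w)
        object.__setattr__(self, "weights", w)


def _radius(grid: GridSpec, center: tuple[float, float]) -> np.ndarray:
    xx, yy = grid.mesh()
    return np.hypot(xx - center[0], yy - center[1])


def annulus_mask(grid: GridSpec, spec: BeamletSpec) -> np.ndarray:
    """Binary ring support: 1 where R-delta <= r <= R (inclusive), else 0."""
    r = _radius(grid, spec.center)
    return ((r >= spec.R - spec.delta) & (r <= spec.R)).astype(np.float64)


def ring_lens_phase(grid: GridSpec, spec: BeamletSpec, wavelength: float) -> np.ndarray:
    """Exact converging-lens phase about the beamlet center, in rad (unwrapped).

    Zero at the center, monotonically decreasing with radius. Wrapping to
    (-pi, pi] happens only when the phase is loaded into a complex
    transmission.
    """
    if not (wavelength > 0):
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    r = _radius(grid, spec.center)
    return -(2.0 * np.pi / wavelength) * (np.sqrt(r**2 + spec.f**2) - spec.f)


def beamlet_transmission(grid: GridSpec, spec: BeamletSpec, wavelength: float) -> np.ndarray:
    """Complex transmission of one beamlet: annulus × exp(i·lens phase)."""
    mask = annulus_mask(grid, spec)
    phase = ring_lens_phase(grid, spec, wavelength)
    t = np.zeros(grid.shape, dtype=np.complex128)
    on = mask > 0
    t[on] = np.exp(1j * phase[on])
    return t


def compose_sum(grid: GridSpec, lattice: LatticeSpec, wavelength: float) -> np.ndarray:
    """Method-1 multiplexing: phase = arg of the coherent sum of beamlet fields.

    The amplitude is clamped to 1 on the union of ring supports (a phase-only
    surface cannot exceed unit transmission); where the sum cancels exactly
    the phase is undefined and the transmission is set to 0.
    """
    total = np.zeros(grid.shape, dtype=np.complex128)
    union = np.zeros(grid.shape, dtype=bool)
    for b in lattice.beamlets:
        t = beamlet_transmission(grid, b, wavelength)
        total += t
        union |= t != 0
    out = np.zeros(grid.shape, dtype=np.complex128)
    ok = union & (total != 0)
    out[ok] = np.exp(1j * np.angle(total[ok]))
    return out


def compose_overwrite(grid: GridSpec, lattice: LatticeSpec, wavelength: float) -> np.ndarray:
    """Method-2 multiplexing: each consecutive beamlet overwrites its support.

    Beamlets are applied in list order; where supports overlap the later
    beamlet wins. With one beamlet this is bit-identical to
    :func:`beamlet_transmission`.
    """
    out = np.zeros(grid.shape, dtype=np.complex128)
    for b in lattice.beamlets:
        t = beamlet_transmission(grid, b, wavelength)
        on = t != 0
        out[on] = t[on]
    return out


def compose(grid: GridSpec, lattice: LatticeSpec, wavelength: float) -> np.ndarray:
    """Dispatch to the lattice's multiplexing method."""
    if lattice.method == "sum":
        return compose_sum(grid, lattice, wavelength)
    return compose_overwrite(grid, lattice, wavelength)


def tilt_phase(grid: GridSpec, theta_x: float, theta_y: float, wavelength: float) -> np.ndarray:
    """Linear phase of a tilted input wavefront: (2π/λ)(sinθx·x + sinθy·y)."""
    if abs(theta_x) >= 0.2 or abs(theta_y) >= 0.2:
        raise ValueError("tilt angles must stay paraxial (|theta| < 0.2 rad)")
    xx, yy = grid.mesh()
    k = 2.0 * np.pi / wavelength
    return k * (np.sin(theta_x) * xx + np.sin(theta_y) * yy)


def linear_lattice(
    base: BeamletSpec,
    n: int,
    period: float,
    method: str = "overwrite",
    x0: float = 0.0,
) -> LatticeSpec:
    """Linear array of ``n`` copies of ``base`` shifted along x by j·P.

    Beamlet j is centered at ``(x0 + j*period, base.center[1])``; ``x0``
    defaults to 0 and can be used to center the array support inside the
    simulation window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (period > 0):
        raise ValueError("period must be positive")
    beamlets = tuple(
        replace(base, center=(x0 + j * period, base.center[1])) for j in range(n)
    )
    return LatticeSpec(beamlets=beamlets, method=method, period=period)
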