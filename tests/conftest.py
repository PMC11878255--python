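import numpy as np
import pytest
from hypothesis import settings

import bblattice as bl

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_512():
    """Coarse 512-µm window (1-µm pitch) for fast propagation checks."""
    return bl.make_grid(512, 512, 1.0, 1.0)


@pytest.fixture(scope="session")
def grid_1024():
    """The default high-resolution design grid: 1024², 0.5-µm pitch."""
    return bl.make_grid(1024, 1024, 0.5, 0.5)


@pytest.fixture(scope="session")
def default_beamlet():
    return bl.BeamletSpec(R=100.0, delta=17.0, f=2000.0)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (radial Fresnel-Hankel quadrature). These
# never touch the FFT propagation path they are used to check.
# ---------------------------------------------------------------------------

def hankel_field(rho, z, R=100.0, delta=17.0, f=2000.0, wavelength=0.488, nr=4000):
    """Field of a uniformly lit annulus+lens at radius rho, plane z.

    1D radial quadrature of the Fresnel diffraction integral with the exact
    lens phase: E(rho, z) = (k/z) ∫ r exp(i[phi_ring(r) + k r²/(2z)]) J0(k r rho/z) dr.
    """
    from scipy.special import j0

    k = 2 * np.pi / wavelength
    r = np.linspace(R - delta, R, nr)
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    phase = -k * (np.sqrt(r**2 + f**2) - f) + k * r**2 / (2 * z)
    integrand = r * np.exp(1j * phase)[None, :] * j0(k * np.outer(rho, r) / z)
    return (k / z) * np.trapezoid(integrand, r, axis=1)


def hankel_onaxis_intensity(z, R=100.0, delta=17.0, f=2000.0, wavelength=0.488):
    """Closed-form on-axis intensity: (k/z)²·(Δu/2)²·sinc²(αΔu/2π), α=(k/2)(1/z−1/f)."""
    z = np.asarray(z, dtype=float)
    k = 2 * np.pi / wavelength
    u1, u2 = (R - delta) ** 2, R**2
    du = u2 - u1
    alpha = 0.5 * k * (1.0 / z - 1.0 / f)
    return (k / z) ** 2 * (du / 2.0) ** 2 * np.sinc(alpha * du / (2 * np.pi)) ** 2


def profile_fwhm(coords, values):
    """FWHM by linear interpolation, independent of the package implementation."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    half = values.max() / 2.0
    above = np.where(values >= half)[0]
    i0, i1 = above[0], above[-1]
    left = coords[i0 - 1] + (half - values[i0 - 1]) * (coords[i0] - coords[i0 - 1]) / (
        values[i0] - values[i0 - 1]
    )
    right = coords[i1] + (half - values[i1]) * (coords[i1 + 1] - coords[i1]) / (
        values[i1 + 1] - values[i1]
    )
    return right - left
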