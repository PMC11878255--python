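"""High-level runs: config → mask → propagated stack → reports.

Thin glue shared by the command-line interface, the test-suite and the
reproduction script; all physics lives in the dedicated modules.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .field import IntensityStack, OpticalField, make_input_beam
from .masks import compose
from .metrics import (
    AxialReport,
    LatticeReport,
    axial_report,
    lattice_report,
    transmittance_efficiency,
)
from .propagate import apply_transmission, dithered_stack, propagate_stack

__all__ = [
    "build_mask",
    "masked_field",
    "run_stack",
    "run_reports",
]


def build_mask(cfg: RunConfig) -> np.ndarray:
    """Complex transmission of the configured lattice."""
    return compose(cfg.grid, cfg.lattice, cfg.wavelength)


def masked_field(cfg: RunConfig) -> OpticalField:
    """Input beam modulated by the lattice transmission at z = 0."""
    beam = make_input_beam(cfg.grid, cfg.beam, cfg.wavelength)
    return apply_transmission(beam, build_mask(cfg))


def run_stack(cfg: RunConfig, z_list: np.ndarray | None = None) -> IntensityStack:
    """Propagate the masked field over the configured (or given) z schedule."""
    field = masked_field(cfg)
    z = np.asarray(z_list, float) if z_list is not None else cfg.z.positions()
    if cfg.dither is not None:
        return dithered_stack(field, z, cfg.dither, cfg.propagator)
    return propagate_stack(field, z, cfg.propagator)


def run_reports(
    cfg: RunConfig, stack: IntensityStack
) -> tuple[LatticeReport, AxialReport, float]:
    """Lattice + axial reports and transmittance efficiency for one stack."""
    m = cfg.metrics
    lat = lattice_report(stack, min_sep=m.min_sep, rel_thresh=m.rel_thresh)
    center_x = lat.beamlet_centers[lat.count // 2] if lat.count else 0.0
    ax = axial_report(
        stack,
        at=(center_x, 0.0),
        fwhm_y_threshold=m.fwhm_y_threshold,
        min_sep=m.min_sep,
        rel_thresh=m.rel_thresh,
    )
    z_focal = m.z_focal if m.z_focal is not None else lat.z_focus
    eff = transmittance_efficiency(
        masked_field(cfg), stack, m.aperture_radius, m.z_ref, z_focal
    )
    return lat, ax, eff
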