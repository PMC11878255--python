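"""Discretization of a continuous transmission onto a nanopillar metasurface.

A metasurface realizes a phase map with square dielectric nanopillars on a
fixed sub-wavelength pitch; each pillar side length D yields a known phase
delay and transmittance at the design wavelength. Here the pillar response
is *data*: a :class:`PillarLibrary` is either a user-supplied CSV (measured
or electromagnetically simulated elsewhere) or the built-in synthetic
uniform-phase fixture. Discretization resamples the continuous transmission
onto the pillar pitch (nearest sample — interpolating a wrapped phase across
2π discontinuities would corrupt zone boundaries) and assigns to each
occupied site the library entry nearest in circular phase distance.

Defaults mirror a SiNx design: pitch 400 nm, pillar height 520 nm, sides
60–340 nm, 28 entries covering [0, 2π), design wavelength 478 nm.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field as _dfield
from pathlib import Path

import numpy as np

from .field import GridSpec

__all__ = [
    "PillarEntry",
    "PillarLibrary",
    "LayoutGrid",
    "default_library",
    "load_library",
    "discretize",
    "layout_to_transmission",
    "export_layout",
    "load_layout_csv",
]

EMPTY = -1


@dataclass(frozen=True)
class PillarEntry:
    """One nanopillar: side (nm), phase delay (rad in [0, 2π)), transmittance."""

    side_nm: float
    phase: float
    transmittance: float

    def __post_init__(self) -> None:
        if not (60.0 <= self.side_nm <= 340.0):
            raise ValueError(f"pillar side must lie in [60, 340] nm, got {self.side_nm}")
        if not (0.0 <= self.phase < 2.0 * np.pi):
            raise ValueError(f"pillar phase must lie in [0, 2π), got {self.phase}")
        if not (0.5 < self.transmittance <= 1.0):
            raise ValueError(
                f"library admits only transmittance in (0.5, 1], got {self.transmittance}"
            )


@dataclass(frozen=True)
class PillarLibrary:
    """A discrete set of pillars plus the fixed geometry they share."""

    entries: tuple[PillarEntry, ...]
    height_nm: float = 520.0
    pitch_nm: float = 400.0
    design_wavelength_um: float = 0.478

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        n = len(self.entries)
        if n < 4:
            raise ValueError(f"library needs at least 4 entries, got {n}")
        phases = np.sort([e.phase for e in self.entries])
        gaps = np.diff(np.concatenate([phases, [phases[0] + 2 * np.pi]]))
        max_gap = float(gaps.max())
        if max_gap > 1.5 * 2 * np.pi / n:
            raise ValueError(
                f"phase coverage gap {max_gap:.4f} rad exceeds 1.5·2π/{n} "
                f"= {1.5 * 2 * np.pi / n:.4f} rad"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def phases(self) -> np.ndarray:
        return np.array([e.phase for e in self.entries])

    @property
    def max_quantization_error(self) -> float:
        """Worst-case circular distance to the nearest entry (half max gap)."""
        phases = np.sort(self.phases)
        gaps = np.diff(np.concatenate([phases, [phases[0] + 2 * np.pi]]))
        return float(gaps.max() / 2.0)


@dataclass
class LayoutGrid:
    """Pitch-sampled pillar assignment: entry index per site, EMPTY = -1.

    Site (row, col) sits at physical position
    ``(origin[0] + col·pitch, origin[1] + row·pitch)`` in µm.
    """

    pitch_nm: float
    indices: np.ndarray = _dfield(repr=False, default=None)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int32)
        if self.indices.ndim != 2:
            raise ValueError("indices must be a 2D raster")

    @property
    def pitch_um(self) -> float:
        return self.pitch_nm * 1e-3

    @property
    def occupied(self) -> int:
        return int(np.sum(self.indices != EMPTY))

    def site_positions_um(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.indices.shape
        x = self.origin[0] + np.arange(cols) * self.pitch_um
        y = self.origin[1] + np.arange(rows) * self.pitch_um
        return x, y


def default_library(n: int = 28) -> PillarLibrary:
    """Synthetic fixture library: n uniform phases, monotone sides, T = 0.8.

    Stands in for a measured/simulated pillar response when none is supplied;
    sides span 60–340 nm monotonically so the layout is geometrically
    plausible, and the flat 0.8 transmittance satisfies the >50% admission
    rule.
    """
    if n < 4:
        raise ValueError(f"library needs at least 4 entries, got {n}")
    phases = 2 * np.pi * np.arange(n) / n
    sides = np.linspace(60.0, 340.0, n)
    entries = tuple(
        PillarEntry(side_nm=float(s), phase=float(p), transmittance=0.8)
        for s, p in zip(sides, phases)
    )
    return PillarLibrary(entries=entries)


def load_library(path: str | Path, **geometry) -> PillarLibrary:
    """Load a pillar library from CSV with columns side_nm, phase_rad, transmittance."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                PillarEntry(
                    side_nm=float(row["side_nm"]),
                    phase=float(row["phase_rad"]),
                    transmittance=float(row["transmittance"]),
                )
            )
    return PillarLibrary(entries=tuple(entries), **geometry)


def _nearest_entry(phases: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Index of the library phase with minimal circular distance (ties → lower index)."""
    d = np.abs(target[..., None] - phases[None, None, :])
    d = np.minimum(d, 2 * np.pi - d)
    return np.argmin(d, axis=-1).astype(np.int32)


def discretize(
    t: np.ndarray,
    grid: GridSpec,
    lib: PillarLibrary,
    active_radius: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> LayoutGrid:
    """Assign library pillars to pitch-spaced sites reproducing arg(t).

    Sites cover the support bounding box of ``t`` (or the circular active
    area of radius ``active_radius`` around ``center``); each site reads the
    nearest simulation sample, maps |t| = 0 to EMPTY, and otherwise picks the
    entry minimizing circular distance to arg(t) wrapped to [0, 2π).
    """
    t = np.asarray(t)
    if t.shape != grid.shape:
        raise ValueError(f"transmission shape {t.shape} does not match grid {grid.shape}")
    p = lib.pitch_nm * 1e-3
    on = np.abs(t) > 0
    if active_radius is not None:
        x_lo, x_hi = center[0] - active_radius, center[0] + active_radius
        y_lo, y_hi = center[1] - active_radius, center[1] + active_radius
    elif on.any():
        xx, yy = grid.mesh()
        x_lo, x_hi = float(xx[on].min()), float(xx[on].max())
        y_lo, y_hi = float(yy[on].min()), float(yy[on].max())
    else:
        return LayoutGrid(pitch_nm=lib.pitch_nm, indices=np.full((0, 0), EMPTY), origin=(0.0, 0.0))
    cols = int(np.floor((x_hi - x_lo) / p)) + 1
    rows = int(np.floor((y_hi - y_lo) / p)) + 1
    sx = x_lo + np.arange(cols) * p
    sy = y_lo + np.arange(rows) * p
    # nearest simulation sample for each site
    ix = np.clip(np.rint(sx / grid.dx).astype(int) + grid.nx // 2, 0, grid.nx - 1)
    iy = np.clip(np.rint(sy / grid.dy).astype(int) + grid.ny // 2, 0, grid.ny - 1)
    sub = t[np.ix_(iy, ix)]
    phase = np.mod(np.angle(sub), 2 * np.pi)
    indices = _nearest_entry(lib.phases, phase)
    indices[np.abs(sub) == 0] = EMPTY
    if active_radius is not None:
        gx, gy = np.meshgrid(sx, sy)
        indices[np.hypot(gx - center[0], gy - center[1]) > active_radius] = EMPTY
    return LayoutGrid(pitch_nm=lib.pitch_nm, indices=indices, origin=(float(x_lo), float(y_lo)))


def layout_to_transmission(
    layout: LayoutGrid,
    lib: PillarLibrary,
    grid: GridSpec,
    unpatterned_transmits: bool = False,
) -> np.ndarray:
    """Complex transmission realized by a pillar layout, sampled on ``grid``.

    Each grid sample reads its nearest layout site: occupied sites transmit
    √T·exp(i·phase); EMPTY sites (and samples outside the layout) transmit 0,
    or 1 when ``unpatterned_transmits`` models an unmasked surround.
    """
    bg = 1.0 + 0.0j if unpatterned_transmits else 0.0j
    out = np.full(grid.shape, bg, dtype=np.complex128)
    if layout.indices.size == 0:
        return out
    p = layout.pitch_um
    rows, cols = layout.indices.shape
    jc = np.rint((grid.x - layout.origin[0]) / p).astype(int)
    jr = np.rint((grid.y - layout.origin[1]) / p).astype(int)
    okx = (jc >= 0) & (jc < cols)
    oky = (jr >= 0) & (jr < rows)
    amp = np.sqrt([e.transmittance for e in lib.entries])
    ph = lib.phases
    vals = np.concatenate([amp * np.exp(1j * ph), [bg]])  # index EMPTY → last
    sub = layout.indices[np.ix_(jr[oky], jc[okx])]
    out[np.ix_(oky, okx)] = vals[sub]
    return out


def export_layout(layout: LayoutGrid, lib: PillarLibrary, path: str | Path, format: str = "csv") -> Path:
    """Write a fabrication layout as CSV (row, col, x_nm, y_nm, side_nm) or GDSII.

    CSV rows are emitted row-major over occupied sites, so repeated export of
    the same layout is byte-identical. The GDSII file holds one square per
    site on layer 1 of a single cell, with a 1 nm database unit.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "x_nm", "y_nm", "side_nm"])
            rows, cols = layout.indices.shape
            for r in range(rows):
                for c in range(cols):
                    idx = layout.indices[r, c]
                    if idx == EMPTY:
                        continue
                    x_nm = layout.origin[0] * 1e3 + c * layout.pitch_nm
                    y_nm = layout.origin[1] * 1e3 + r * layout.pitch_nm
                    w.writerow([r, c, f"{x_nm:.1f}", f"{y_nm:.1f}", f"{lib.entries[idx].side_nm:.1f}"])
        return path
    if format == "gdsii":
        _write_gdsii(layout, lib, path)
        return path
    raise ValueError(f"unknown layout format {format!r} (expected 'csv' or 'gdsii')")


def load_layout_csv(path: str | Path, lib: PillarLibrary, shape: tuple[int, int] | None = None) -> LayoutGrid:
    """Rebuild a LayoutGrid from an exported CSV (sides matched to entries)."""
    side_to_idx = {round(e.side_nm, 1): i for i, e in enumerate(lib.entries)}
    recs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            recs.append((int(row["row"]), int(row["col"]), float(row["x_nm"]), float(row["y_nm"]), float(row["side_nm"])))
    if not recs:
        return LayoutGrid(pitch_nm=lib.pitch_nm, indices=np.full(shape or (0, 0), EMPTY))
    rmax = max(r for r, *_ in recs)
    cmax = max(c for _, c, *_ in recs)
    if shape is None:
        shape = (rmax + 1, cmax + 1)
    indices = np.full(shape, EMPTY, dtype=np.int32)
    x0 = min(x - c * lib.pitch_nm for _, c, x, _, _ in recs) * 1e-3
    y0 = min(y - r * lib.pitch_nm for r, _, _, y, _ in recs) * 1e-3
    for r, c, _, _, side in recs:
        indices[r, c] = side_to_idx[round(side, 1)]
    return LayoutGrid(pitch_nm=lib.pitch_nm, indices=indices, origin=(x0, y0))


# --- minimal GDSII writer -------------------------------------------------
# The stream format is a flat sequence of (length, record-type, data) records;
# only the handful of record kinds needed for "squares in one cell on one
# layer" are emitted. Database unit: 1 nm.

def _rec(tag: int, data: bytes = b"") -> bytes:
    return struct.pack(">HH", 4 + len(data), tag) + data


def _rec_i16(tag: int, *vals: int) -> bytes:
    return _rec(tag, struct.pack(f">{len(vals)}h", *vals))


def _rec_i32(tag: int, *vals: int) -> bytes:
    return _rec(tag, struct.pack(f">{len(vals)}i", *vals))


def _gds_real8(value: float) -> bytes:
    """IEEE-754-unlike GDSII 8-byte real (excess-64 base-16 exponent)."""
    if value == 0:
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0
    value = abs(value)
    exponent = 0
    while value >= 1:
        value /= 16.0
        exponent += 1
    while value < 1 / 16.0:
        value *= 16.0
        exponent -= 1
    mantissa = int(value * (1 << 56))
    return struct.pack(">B", sign | (exponent + 64)) + mantissa.to_bytes(7, "big")


def _write_gdsii(layout: LayoutGrid, lib: PillarLibrary, path: Path) -> None:
    ts = (2000, 1, 1, 0, 0, 0)  # fixed timestamp: export is reproducible
    name = b"BBLATTICE\x00"[: 10]
    out = [
        _rec_i16(0x0002, 600),                      # HEADER, version 6
        _rec_i16(0x0102, *ts, *ts),                 # BGNLIB
        _rec(0x0206, name),                         # LIBNAME
        _rec(0x0305, _gds_real8(1e-3) + _gds_real8(1e-9)),  # UNITS: 1 nm db unit
        _rec_i16(0x0502, *ts, *ts),                 # BGNSTR
        _rec(0x0606, b"TOP\x00"),                   # STRNAME
    ]
    rows, cols = layout.indices.shape
    for r in range(rows):
        for c in range(cols):
            idx = layout.indices[r, c]
            if idx == EMPTY:
                continue
            half = int(round(lib.entries[idx].side_nm / 2.0))
            cx = int(round(layout.origin[0] * 1e3 + c * layout.pitch_nm))
            cy = int(round(layout.origin[1] * 1e3 + r * layout.pitch_nm))
            xy = [
                cx - half, cy - half,
                cx + half, cy - half,
                cx + half, cy + half,
                cx - half, cy + half,
                cx - half, cy - half,
            ]
            out += [
                _rec(0x0800),                      # BOUNDARY
                _rec_i16(0x0D02, 1),               # LAYER 1
                _rec_i16(0x0E02, 0),               # DATATYPE 0
                _rec_i32(0x1003, *xy),             # XY
                _rec(0x1100),                      # ENDEL
            ]
    out += [_rec(0x0700), _rec(0x0400)]            # ENDSTR, ENDLIB
    with open(path, "wb") as fh:
        fh.write(b"".join(out))
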