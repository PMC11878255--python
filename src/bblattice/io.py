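"""File products: TIFF intensity stacks, complex-field arrays, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .field import GridSpec, IntensityStack, OpticalField

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_field_npy",
    "read_field_npy",
    "write_json",
]


def write_stack_tiff(stack: IntensityStack, path: str | Path) -> Path:
    """Multi-page 32-bit-float TIFF plus a JSON sidecar index of z positions."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    write_json(
        {
            "z_um": [float(z) for z in stack.z_list],
            "grid": {"nx": stack.grid.nx, "ny": stack.grid.ny,
                     "dx": stack.grid.dx, "dy": stack.grid.dy},
        },
        sidecar,
    )
    return path


def read_stack_tiff(path: str | Path) -> IntensityStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    g = meta["grid"]
    grid = GridSpec(nx=g["nx"], ny=g["ny"], dx=g["dx"], dy=g["dy"])
    return IntensityStack(grid=grid, z_list=np.asarray(meta["z_um"]), frames=frames)


def write_field_npy(field: OpticalField, path: str | Path) -> Path:
    """Lossless complex raster (.npz with grid/wavelength/z metadata)."""
    path = Path(path)
    np.savez(
        path,
        data=field.data,
        wavelength=field.wavelength,
        z=field.z,
        grid=np.array([field.grid.nx, field.grid.ny, field.grid.dx, field.grid.dy]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_field_npy(path: str | Path) -> OpticalField:
    with np.load(path) as payload:
        nx, ny, dx, dy = payload["grid"]
        return OpticalField(
            grid=GridSpec(nx=int(nx), ny=int(ny), dx=float(dx), dy=float(dy)),
            wavelength=float(payload["wavelength"]),
            z=float(payload["z"]),
            data=payload["data"],
        )


def write_json(obj, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
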