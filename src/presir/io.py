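"""File interchange: HDF5 image stacks, CSV scatterer fields, YAML systems.

Complex data is stored as paired real/imaginary float64 datasets for
portability across HDF5 readers; system metadata travels as root
attributes (center wavenumber, k spacing, pixel pitches and grid sizes) so
a stack file is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .forward_model import ImageStack, OCTSystem, ScattererField

__all__ = [
    "write_stack",
    "read_stack",
    "field_to_csv",
    "field_from_csv",
    "system_to_yaml",
    "system_from_yaml",
]

_SYSTEM_FIELDS = ("lambda0_um", "axial_fwhm_um", "lateral_fwhm_um", "n_k",
                  "m_x", "lateral_pitch_um", "span_sigmas", "guard_fraction")

_REQUIRED_ATTRS = ("k0", "dk", "dx_um", "dz_um")


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a complex B-scan stack with full system metadata."""
    system = stack.system
    with h5py.File(path, "w") as f:
        f.create_dataset("image_real", data=stack.data.real)
        f.create_dataset("image_imag", data=stack.data.imag)
        f.create_dataset("timestamps", data=stack.timestamps)
        f.create_dataset("valid_columns", data=stack.valid_columns)
        f.attrs["k0"] = system.k0
        f.attrs["dk"] = system.dk
        f.attrs["dx_um"] = system.lateral_pitch_um
        f.attrs["dz_um"] = system.axial_pitch_um
        for name in _SYSTEM_FIELDS:
            f.attrs[name] = getattr(system, name)


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`; validates the schema."""
    with h5py.File(path, "r") as f:
        missing = [a for a in _REQUIRED_ATTRS if a not in f.attrs]
        if missing:
            raise KeyError(f"stack file missing required attrs: {missing}")
        kwargs = {name: f.attrs[name] for name in _SYSTEM_FIELDS if name in f.attrs}
        kwargs["n_k"] = int(kwargs["n_k"])
        kwargs["m_x"] = int(kwargs["m_x"])
        system = OCTSystem(**kwargs)
        data = np.asarray(f["image_real"], dtype=float) + \
            1j * np.asarray(f["image_imag"], dtype=float)
        timestamps = np.asarray(f["timestamps"]) if "timestamps" in f else None
        valid = np.asarray(f["valid_columns"], dtype=bool) \
            if "valid_columns" in f else None
    return ImageStack(data, system, timestamps=timestamps, valid_columns=valid)


def field_to_csv(path: str | Path, field: ScattererField) -> None:
    pd.DataFrame({"x_um": field.x_um, "z_um": field.z_um, "r": field.r}) \
        .to_csv(path, index=False)


def field_from_csv(path: str | Path,
                   x_extent: tuple[float, float] | None = None,
                   z_extent: tuple[float, float] | None = None) -> ScattererField:
    df = pd.read_csv(path)
    x, z, r = df["x_um"].to_numpy(), df["z_um"].to_numpy(), df["r"].to_numpy()
    if x_extent is None:
        x_extent = (float(x.min()), float(x.max()))
    if z_extent is None:
        z_extent = (float(z.min()), float(z.max()))
    return ScattererField(x, z, r, x_extent, z_extent)


def system_to_yaml(path: str | Path, system: OCTSystem) -> None:
    payload = {name: getattr(system, name) for name in _SYSTEM_FIELDS}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def system_from_yaml(path: str | Path) -> OCTSystem:
    payload = yaml.safe_load(Path(path).read_text())
    return OCTSystem(**payload)
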