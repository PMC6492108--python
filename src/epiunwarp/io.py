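"""File formats: HDF5 k-space container and NIfTI maps.

The k-space container stores both blip polarities with their sampling masks
and the acquisition timing attributes.  NIfTI files carry images, field
maps, coil maps and masks; complex arrays are stored with real and
imaginary parts stacked along a trailing axis, flagged in the header
description field (which also records Hz units for field maps).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .grids import GridGeometry, MultiCoilKSpace, Polarity

__all__ = ["save_kspace", "load_kspace", "save_nifti", "load_nifti", "write_run_log"]


def save_kspace(
    path: str | Path,
    y_up: MultiCoilKSpace,
    y_down: MultiCoilKSpace,
    geometry: GridGeometry,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace_up", data=y_up.data.astype(np.complex64))
        f.create_dataset("kspace_down", data=y_down.data.astype(np.complex64))
        f.create_dataset("sample_mask", data=y_up.sample_mask)
        f.create_dataset("sample_mask_down", data=y_down.sample_mask)
        f.attrs["echo_spacing_s"] = geometry.echo_spacing_s
        f.attrs["bw_per_pixel_hz"] = geometry.bw_per_pixel_hz
        f.attrs["pe_axis"] = geometry.pe_axis
        f.attrs["partial_fourier"] = geometry.partial_fourier
        f.attrs["pixel_mm"] = list(geometry.pixel_mm)


def load_kspace(path: str | Path) -> tuple[MultiCoilKSpace, MultiCoilKSpace, GridGeometry]:
    with h5py.File(path, "r") as f:
        up = np.asarray(f["kspace_up"], dtype=complex)
        down = np.asarray(f["kspace_down"], dtype=complex)
        mask_up = np.asarray(f["sample_mask"], bool)
        mask_down = np.asarray(
            f["sample_mask_down"] if "sample_mask_down" in f else f["sample_mask"], bool
        )
        geometry = GridGeometry(
            n_pe=up.shape[1],
            n_ro=up.shape[2],
            pixel_mm=tuple(f.attrs["pixel_mm"]),
            echo_spacing_s=float(f.attrs["echo_spacing_s"]),
            pe_axis=str(f.attrs["pe_axis"]),
            partial_fourier=float(f.attrs["partial_fourier"]),
        )
    y_up = MultiCoilKSpace(data=up, polarity=Polarity.BLIP_UP, sample_mask=mask_up)
    y_down = MultiCoilKSpace(data=down, polarity=Polarity.BLIP_DOWN, sample_mask=mask_down)
    return y_up, y_down, geometry


def save_nifti(
    path: str | Path,
    array: np.ndarray,
    pixel_mm: tuple[float, float] = (1.0, 1.0),
    descrip: str = "",
) -> None:
    """Write a 2-D or (J, P, R) array; complex data splits into real/imag."""
    arr = np.asarray(array)
    if np.iscomplexobj(arr):
        arr = np.stack([arr.real, arr.imag], axis=-1)
        descrip = (descrip + ";complex=1").lstrip(";")
    affine = np.diag([pixel_mm[0], pixel_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine)
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    if "complex=1" in descrip:
        arr = arr[..., 0] + 1j * arr[..., 1]
    return arr


def write_run_log(path: str | Path, command: str, params: dict) -> None:
    """Structured run log beside a CLI output: command, parameters, version."""
    from . import __version__

    record = {"command": command, "version": __version__, "params": params}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
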