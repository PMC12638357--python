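"""NIfTI-1 I/O with BIDS-style JSON sidecars.

Volumes are written with a diagonal affine from the voxel size; the unit
tag, mask and acquisition metadata (echo times, field strength/frequency,
B0 direction) travel in a sidecar JSON next to the image, so a round trip
preserves everything the in-memory containers carry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionParams, ComplexEchoSeries, ValidationError, VolumeGrid

__all__ = ["save_volume", "load_volume", "save_echo_series", "load_echo_series"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise ValidationError(f"expected a .nii or .nii.gz path, got {path}")


def _affine(voxel_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def save_volume(grid: VolumeGrid, path, extra: dict | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid.voxel_mm)), path)
    meta = {"Units": grid.unit, "VoxelSizeMm": grid.voxel_mm.tolist()}
    if not grid.mask.all():
        meta["MaskRLE"] = _rle_encode(grid.mask)
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_volume(path) -> VolumeGrid:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    voxel = np.asarray(meta.get("VoxelSizeMm", img.header.get_zooms()[:3]), dtype=float)
    values = np.asarray(img.dataobj, dtype=float)
    mask = None
    if "MaskRLE" in meta:
        mask = _rle_decode(meta["MaskRLE"], values.shape)
    return VolumeGrid(values, voxel, meta.get("Units", "dimensionless"), mask)


def save_echo_series(series: ComplexEchoSeries, path) -> None:
    """Write a complex multi-echo series as a 5D NIfTI (x, y, z, echo,
    real/imag) plus a sidecar with the acquisition parameters."""
    path = Path(path)
    stacked = np.stack([series.data.real, series.data.imag], axis=-1)  # e,x,y,z,2
    arr = np.moveaxis(stacked, 0, 3)  # x,y,z,e,2
    nib.save(nib.Nifti1Image(arr.astype(np.float64), _affine(series.acq.voxel_mm)), path)
    meta = {
        "EchoTime": series.acq.te_s.tolist(),
        "ImagingFrequencyHz": series.acq.f0_hz,
        "MagneticFieldStrength": series.acq.f0_hz / 42.577478518e6,
        "B0Direction": series.acq.b0_dir.tolist(),
        "VoxelSizeMm": series.acq.voxel_mm.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_echo_series(path) -> ComplexEchoSeries:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim != 5 or arr.shape[-1] != 2:
        raise ValidationError("echo series NIfTI must be 5D with a real/imag axis")
    data = np.moveaxis(arr[..., 0] + 1j * arr[..., 1], 3, 0)
    acq = AcquisitionParams(
        te_s=np.asarray(meta["EchoTime"], dtype=float),
        f0_hz=float(meta["ImagingFrequencyHz"]),
        b0_dir=np.asarray(meta["B0Direction"], dtype=float),
        voxel_mm=np.asarray(meta["VoxelSizeMm"], dtype=float),
    )
    return ComplexEchoSeries(data, acq)


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    out = runs.tolist()
    return ([0] + out) if flat[0] else out  # counts alternate False/True, start False


def _rle_decode(runs: list[int], shape) -> np.ndarray:
    vals = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    current = False
    for r in runs:
        if current:
            vals[pos : pos + r] = True
        pos += r
        current = not current
    return vals.reshape(shape)
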