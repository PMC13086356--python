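"""NIfTI readers and writers for volumes and displacement fields.

Displacement fields are stored in **voxel units** (not millimetres) with a
trailing vector dimension of size 3.  The writer emits the X×Y×Z×1×3
layout with the NIfTI vector intent; the reader also accepts the plain
X×Y×Z×3 dialect.  Grid spacing is read from the header zooms.
"""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np

from .fields import DisplacementField, Grid, ScalarMap

FIELD_DESCRIP = b"displacement field, voxel units, trailing vector dim"


class FieldFormatError(ValueError):
    pass


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    return aff


def read_volume(path) -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FieldFormatError(f"expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarMap(Grid(data.shape, spacing), data.astype(float))


def write_volume(volume: ScalarMap, path, dtype=None) -> None:
    data = volume.values if dtype is None else volume.values.astype(dtype)
    img = nib.Nifti1Image(data, _affine(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_labels(path) -> ScalarMap:
    """Like :func:`read_volume` but keeps integer label semantics."""
    vol = read_volume(path)
    vol.values = np.round(vol.values)
    return vol


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        data = data[:, :, :, 0, :]
    elif data.ndim == 4 and data.shape[3] == 3:
        pass
    else:
        raise FieldFormatError(
            f"expected X×Y×Z×3 or X×Y×Z×1×3 displacement layout, got {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = Grid(data.shape[:3], spacing)
    return DisplacementField(grid, np.moveaxis(data, -1, 0))


def write_field(field: DisplacementField, path) -> None:
    data = np.moveaxis(field.d, 0, -1)[:, :, :, None, :]  # X,Y,Z,1,3
    img = nib.Nifti1Image(data, _affine(field.grid))
    img.header.set_intent("vector")
    img.header["descrip"] = FIELD_DESCRIP
    nib.save(img, str(path))


def write_report(report: dict, path, schema_version: str = "1") -> None:
    payload = {"schema_version": schema_version, **report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
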