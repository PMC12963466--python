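"""File I/O: NIfTI volumes, CSV tables, JSON manifests.

NIfTI is the interchange format for volumes: HU-valued floats with mm
voxel spacing in the header and the origin in the affine translation.
Round-tripping a volume preserves voxels and spacing exactly.  CSV files
use comma separators, UTF-8, '.' decimal, and a mandatory header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError
from .phantom import CTVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "write_json",
    "sha256_file",
]


def write_volume(path, vol: CTVolume) -> None:
    """Write a CTVolume as NIfTI (float64 HU, spacing in header+affine)."""
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    """Read an HU-valued NIfTI volume.

    Raises ``DimensionalityError`` for non-3D images and ``ValueError``
    for missing/invalid spacing.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3D volume, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"invalid voxel spacing in header: {zooms}")
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return CTVolume(data, zooms, origin)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
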