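"""NIfTI / JSON / CSV input-output helpers.

Volumes are written as NIfTI-1 with an RAS affine carrying the isotropic
voxel size; the package's own readers re-load everything it writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(volume: np.ndarray, voxel_size: float, path) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms((voxel_size,) * 3)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Return (volume, voxel size in mm); assumes isotropic voxels."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return data, float(img.header.get_zooms()[0])


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())
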