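"""NIfTI-1 volume I/O on the pipeline's canonical grid.

Volumes are written with a diagonal affine built from the voxel spacing;
masks go out as uint8, scalar maps as float32.  Reading returns the data
array and the per-axis spacing recovered from the affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["write_volume", "read_volume"]


def write_volume(path, values: np.ndarray, spacing_mm, dtype=None) -> None:
    values = np.asarray(values)
    if dtype is None:
        dtype = np.uint8 if values.dtype == bool else np.float32
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(values.astype(dtype), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing
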