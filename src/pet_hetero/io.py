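"""NIfTI volume I/O and the delimited-table conventions of the pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .voi import SUVolume

__all__ = ["load_suv_nifti", "save_suv_nifti"]


def save_suv_nifti(volume: SUVolume, path: str | Path) -> None:
    """Write an SUV volume as NIfTI-1 with voxel spacing in the header."""
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def load_suv_nifti(path: str | Path) -> SUVolume:
    """Read a NIfTI-1 SUV volume, taking spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return SUVolume(data, tuple(float(z) for z in zooms))
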