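"""NIfTI volume I/O helpers (thin wrappers over nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError

__all__ = ["load_volume", "save_volume", "save_mask"]


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    return data, img.affine


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Save a scalar volume as 32-bit float NIfTI."""
    affine = np.eye(4) if affine is None else affine
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Save a binary mask as unsigned 8-bit {0,1} NIfTI."""
    affine = np.eye(4) if affine is None else affine
    m = (np.asarray(mask) != 0).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(m, affine), str(path))
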