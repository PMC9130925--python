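"""Volume and manifest I/O.

Volumes are stored either as NIfTI (identity orientation, voxel size carried in
the header zooms) or as raw little-endian binary with a mandatory JSON sidecar
``{"shape": [...], "dtype": "float32", "voxel_size_mm": v, "order": "C"}``.
Voxel indices are 0-based; physical positions are in mm at voxel centers,
center of voxel ``i`` at ``(i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "save_volume",
    "load_volume",
    "save_json",
    "load_json",
]


def save_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_volume(values: np.ndarray, voxel_size: float, path) -> None:
    """Save a 3D array as NIfTI (``.nii``) or raw binary + JSON sidecar.

    The format is chosen from the file suffix: ``.nii``/``.nii.gz`` for NIfTI,
    anything else is written raw with a ``<path>.json`` sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {values.shape}")
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        img = nib.Nifti1Image(values, affine)
        img.header.set_zooms((voxel_size,) * 3)
        nib.save(img, str(path))
    else:
        arr = np.ascontiguousarray(values)
        arr.tofile(path)
        save_json(
            {
                "shape": list(arr.shape),
                "dtype": arr.dtype.name,
                "voxel_size_mm": float(voxel_size),
                "order": "C",
            },
            path.with_name(path.name + ".json"),
        )


def load_volume(path) -> tuple[np.ndarray, float]:
    """Load a volume saved by :func:`save_volume`; returns (array, voxel_size)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        return np.asarray(img.dataobj), float(img.header.get_zooms()[0])
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for raw volume: {sidecar}")
    meta = load_json(sidecar)
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return arr, float(meta["voxel_size_mm"])
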