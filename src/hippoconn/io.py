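"""NIfTI-1, FSL gradient-table and cohort-manifest readers and writers.

All volumes in this package live on a single common grid (no registration
stage); the affine is diagonal with the voxel size on the diagonal.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "dwi_path",
    "bval_path",
    "bvec_path",
    "avlt_score",
]


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.broadcast_to(voxel_size, (3,))
    return aff


def save_volume(data: np.ndarray, voxel_size, path: str) -> str:
    """Write a 3-D or 4-D array as NIfTI-1. uint8 for boolean masks."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, affine_from_voxel_size(voxel_size))
    nib.save(img, path)
    return path


def load_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, voxel_size) from a NIfTI file."""
    img = nib.load(path)
    return np.asarray(img.get_fdata()), np.asarray(img.header.get_zooms()[:3])


def save_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, prefix: str) -> tuple[str, str]:
    """Write FSL-dialect gradient tables.

    ``<prefix>.bval``: one whitespace-separated row of b-values.
    ``<prefix>.bvec``: three rows (x, y, z) of N columns.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    bval_path, bvec_path = prefix + ".bval", prefix + ".bvec"
    np.savetxt(bval_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, bvecs.T, fmt="%.8f")
    return bval_path, bvec_path


def load_bvals_bvecs(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.ndim == 2:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"gradient table mismatch: {bvals.shape[0]} b-values, {bvecs.shape[0]} directions"
        )
    return bvals, bvecs


def save_manifest(rows: list[dict], path: str) -> str:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
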