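"""NIfTI-1 volume and manifest I/O (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["subject_id", "group", "path"]


def save_nifti(data: np.ndarray, path, voxel_size=(3.0, 3.0, 3.0)) -> Path:
    """Write a 3D or 4D array as NIfTI-1 with a diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed to write NIfTI volume {path}: {exc}") from exc
    return path


def load_nifti(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI volume not found: {path}")
    return np.asarray(nib.load(str(path)).get_fdata(dtype=np.float32))


def write_manifest(rows, path) -> Path:
    """rows: iterable of (subject_id, group, path) triples."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return df
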