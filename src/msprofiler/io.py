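"""Readers and writers for the pipeline's file formats.

Tables are CSV with a mandatory ``subject_id`` column; matrices are CSV
with row/column labels; parcellations and lesion masks are NIfTI sharing
grid and affine; tractograms are JSON (a metadata block plus a list of
streamlines, each a list of [i, j, k] voxel triplets, 0-based in array
order). All round-trips are value-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dconn import Tractogram
from .synth import LabelVolume

__all__ = [
    "read_table",
    "write_table",
    "read_matrix",
    "write_matrix",
    "read_label_volume",
    "write_label_volume",
    "read_lesion_mask",
    "write_lesion_mask",
    "read_tractogram",
    "write_tractogram",
]


def write_table(df: pd.DataFrame, path) -> None:
    if "subject_id" not in df.columns:
        raise ValueError("table must carry a subject_id column")
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"malformed table {path}: no subject_id column")
    return df


def write_matrix(M: np.ndarray, path, labels: list[str] | None = None) -> None:
    M = np.asarray(M)
    if labels is None:
        labels = [f"region_{i + 1}" for i in range(M.shape[0])]
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy()


def write_label_volume(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int32), affine=np.eye(4))
    nib.save(img, str(path))


def read_label_volume(path, n_regions: int | None = None) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    if n_regions is None:
        n_regions = int(data.max())
    return LabelVolume(data=data, n_regions=n_regions)


def write_lesion_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("lesion mask must be strictly binary")
    img = nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_lesion_mask(path, expected_shape=None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.isin(data, (0, 1)).all():
        raise ValueError(f"lesion mask {path} has non-binary values")
    if expected_shape is not None and data.shape != tuple(expected_shape):
        raise ValueError(
            f"lesion mask {path} grid {data.shape} does not match expected {tuple(expected_shape)}"
        )
    return data.astype(np.uint8)


def write_tractogram(trk: Tractogram, path) -> None:
    payload = {
        "metadata": {
            "grid_shape": list(trk.grid_shape),
            "n_regions": trk.n_regions,
        },
        "endpoints": trk.endpoints.tolist(),
        "streamlines": [sl.tolist() for sl in trk.streamlines],
    }
    Path(path).write_text(json.dumps(payload))


def read_tractogram(path) -> Tractogram:
    payload = json.loads(Path(path).read_text())
    meta = payload["metadata"]
    shape = tuple(int(s) for s in meta["grid_shape"])
    streamlines = []
    for idx, sl in enumerate(payload["streamlines"]):
        arr = np.asarray(sl, dtype=int)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.min(initial=0) < 0 or np.any(
            arr >= np.array(shape)
        ):
            raise ValueError(f"tractogram {path}: streamline {idx} has out-of-grid voxels")
        streamlines.append(arr)
    return Tractogram(
        streamlines=streamlines,
        endpoints=np.asarray(payload["endpoints"], dtype=int).reshape(-1, 2),
        n_regions=int(meta["n_regions"]),
        grid_shape=shape,
    )
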