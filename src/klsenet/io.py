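"""File I/O and run configuration.

Volumes travel as NIfTI; parcel/network maps as TSV; samples, PDFs,
matrices, metric tables and reports as plain CSV (diffable at the
100-node scale); configuration and provenance sidecars as JSON.  Every
output artifact carries the hash of the run configuration so downstream
stages can refuse mixed-config inputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas
from .density import StandardGrid
from .exceptions import FormatError, InputError
from .network import ConnectivityMatrix

__all__ = [
    "RunConfig",
    "read_label_volume",
    "read_intensity_volume",
    "write_volume",
    "read_parcel_table",
    "write_parcel_table",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_sidecar",
    "read_sidecar",
]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; serialized into every sidecar."""

    grid_min: float = 0.0
    grid_max: float = 3.0
    grid_bins: int = 256
    min_voxels: int = 800
    epsilon: float = 1e-12
    bandwidth: str = "botev"  # botev | silverman
    top_fraction: float = 0.20
    alpha: float = 0.05
    viz_threshold: float = 0.80
    n_subjects: int = 67
    age_min: float = 20.0
    age_max: float = 82.0
    effects: str = "aging-linear"  # aging-linear | aging-quadratic | null
    seed: int = 0

    def grid(self) -> StandardGrid:
        return StandardGrid(self.grid_min, self.grid_max, self.grid_bins)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_label_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI parcel label volume; labels must be integer-valued."""
    img = nib.load(str(path))
    if not np.issubdtype(img.get_data_dtype(), np.integer):
        raise FormatError(f"{path}: label volume must have an integer dtype")
    data = np.asarray(img.dataobj).astype(np.int32)
    if data.min() < 0:
        raise FormatError(f"{path}: negative labels")
    return data, img.affine


def read_intensity_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None, dtype=None) -> None:
    affine = np.eye(4) if affine is None else affine
    arr = np.asarray(data, dtype=dtype) if dtype is not None else np.asarray(data)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_parcel_table(path: str | Path, atlas: ParcellationAtlas) -> None:
    atlas.parcels.to_csv(path, sep="\t", index=False)


def read_parcel_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"parcel/network table not found: {path}")
    t = pd.read_csv(path, sep="\t")
    for col in ("parcel_id", "parcel_name", "network"):
        if col not in t.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return t


def write_matrix_csv(path: str | Path, matrix: ConnectivityMatrix) -> None:
    matrix.to_dataframe().to_csv(path, index_label="parcel_id")


def read_matrix_csv(path: str | Path, meta: dict | None = None) -> ConnectivityMatrix:
    # round_trip parsing: shortest-repr CSV floats reload bit-exactly
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = df.index.to_numpy(dtype=int)
    return ConnectivityMatrix(ids, df.to_numpy(dtype=float), meta or {})


def write_sidecar(path: str | Path, config: RunConfig, **extra) -> None:
    payload = {"config": config.to_dict(), "config_hash": config.config_hash(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_sidecar(path: str | Path, expect_hash: str | None = None) -> dict:
    payload = json.loads(Path(path).read_text())
    if expect_hash is not None and payload.get("config_hash") != expect_hash:
        raise InputError(
            f"{path}: produced under config {payload.get('config_hash')}, "
            f"expected {expect_hash} (mixed-config inputs are refused)"
        )
    return payload
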