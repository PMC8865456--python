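"""Brain parcellation atlas: an integer label volume plus a parcel table.

The atlas defines the nodes of every metabolic network built downstream.
Parcels are identified by contiguous positive integer labels; label 0 is
background.  The parcel table maps each parcel to a human-readable name and
to the intrinsic functional network it belongs to (visual, somatomotor,
dorsal attention, ventral attention, limbic, control, default mode,
frontoparietal).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

PARCEL_COLUMNS = ("parcel_id", "parcel_name", "network")


@dataclass
class ParcellationAtlas:
    """Label volume + parcel -> functional-network map.

    Parameters
    ----------
    labels
        Integer voxel volume; 0 is background, positive values are parcel ids.
    parcels
        DataFrame with at least columns ``parcel_id``, ``parcel_name``,
        ``network``.  Phantom atlases additionally carry the generative
        per-parcel columns ``base_mean`` (offset of the parcel mean uptake
        from the global mean) and ``base_sd`` (within-parcel voxel sd).
    affine
        Voxel-to-world affine, carried through NIfTI round-trips.
    """

    labels: np.ndarray
    parcels: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputError("atlas labels must be an integer volume")
        if self.labels.min() < 0:
            raise InputError("atlas labels must be nonnegative")
        missing = [c for c in PARCEL_COLUMNS if c not in self.parcels.columns]
        if missing:
            raise InputError(f"parcel table missing columns {missing}")
        present = np.unique(self.labels)
        present = set(present[present > 0].tolist())
        known = set(int(p) for p in self.parcels["parcel_id"])
        orphan = present - known
        if orphan:
            raise InputError(f"labels {sorted(orphan)[:5]} not in parcel table")

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.parcels["parcel_id"].to_numpy(dtype=int)

    @property
    def networks(self) -> list[str]:
        """Network names in first-appearance order of the parcel table."""
        return list(dict.fromkeys(self.parcels["network"]))

    def network_of(self) -> dict[int, str]:
        return dict(zip(self.parcels["parcel_id"].astype(int), self.parcels["network"]))

    def members(self, network: str) -> np.ndarray:
        """Parcel ids belonging to one functional network."""
        sel = self.parcels["network"] == network
        return self.parcels.loc[sel, "parcel_id"].to_numpy(dtype=int)

    def voxel_counts(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel())
        ids = self.parcel_ids
        vals = [counts[i] if i < len(counts) else 0 for i in ids]
        return pd.Series(vals, index=ids, name="n_voxels")
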