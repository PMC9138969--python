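"""Canonical resting-state-network ROI table and network-pair enumeration.

Twenty-one cortical seeds from the fMRI/hdEEG resting-state literature define
six networks: default mode (DMN), dorsal attention (DAN), ventral attention
(VAN), language (LANG), somatomotor (MOT) and visual (VIS).  Seed coordinates
are given in MNI millimetres; a minimum pairwise distance of 15 mm between
seeds limits zero-lag leakage between neighbouring ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd

NETWORKS = ("DMN", "DAN", "VAN", "LANG", "MOT", "VIS")

#: Approximate centre of the best-fit scalp sphere in MNI coordinates (mm).
#: The spherical head frame is the MNI frame translated so this point is the
#: origin; all 21 seeds then fall well inside an 80 mm brain shell.
HEAD_CENTER_MNI = np.array([0.0, -25.0, 8.0])


@dataclass(frozen=True)
class NetworkTable:
    """The ROI records (name, network, MNI xyz) defining the six networks."""

    names: tuple[str, ...]
    networks: tuple[str, ...]
    coords_mni: np.ndarray  # (n_roi, 3) mm

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("ROI names must be unique")
        if self.coords_mni.shape != (len(self.names), 3):
            raise ValueError("coordinate array must be (n_roi, 3)")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def coords_head(self) -> np.ndarray:
        """Seed coordinates in the sphere-centred head frame (mm)."""
        return self.coords_mni - HEAD_CENTER_MNI

    def members(self, network: str) -> list[int]:
        return [i for i, n in enumerate(self.networks) if n == network]

    def roi_index(self, name: str) -> int:
        return self.names.index(name)

    def min_pairwise_distance(self) -> float:
        d = np.linalg.norm(
            self.coords_mni[:, None, :] - self.coords_mni[None, :, :], axis=-1
        )
        return float(d[np.triu_indices(len(self), k=1)].min())


def load_network_table() -> NetworkTable:
    """Load the packaged 21-ROI / 6-network table."""
    with resources.files("envconn.data").joinpath("networks.csv").open() as fh:
        df = pd.read_csv(fh)
    return NetworkTable(
        names=tuple(df["seed"]),
        networks=tuple(df["network"]),
        coords_mni=df[["x", "y", "z"]].to_numpy(float),
    )


def all_network_pairs() -> list[tuple[str, str]]:
    """All 21 unordered network pairs (6 within + 15 between)."""
    return list(combinations_with_replacement(NETWORKS, 2))


def pairs_of_interest() -> list[tuple[str, str]]:
    """The six a-priori pairs: within-MOT plus MOT with each other network."""
    return [("MOT", "MOT")] + [("MOT", n) for n in NETWORKS if n != "MOT"]


def roi_pairs_for(table: NetworkTable, net_a: str, net_b: str) -> list[tuple[int, int]]:
    """ROI index pairs entering a within- (a == b) or between-network average."""
    if net_a == net_b:
        return list(combinations(table.members(net_a), 2))
    return [(i, j) for i in table.members(net_a) for j in table.members(net_b)]
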