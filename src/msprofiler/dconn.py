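"""Lesion disconnectomes from tractogram–mask intersection.

A reference ("healthy control") tractogram is a set of streamlines, each
an ordered path of voxels whose endpoints lie in labelled grey-matter
regions. Counting streamlines by endpoint pair gives the healthy
connectome HC (an N x N adjacency matrix). Intersecting every streamline
with a subject's binary lesion mask — a streamline is affected iff at
least one voxel on its path is lesioned — gives the affected connectome
AC. The disconnectome is

    D = 1 - (HC - AC) / HC  =  AC / HC        (where HC > 0)

ranging from 0 (connectivity preserved) to 1 (complete disconnection).
Regional disconnection r_i is the proportion of streamlines from/to
region i that intersect the lesion mask; the whole-brain value is the
proportion over all streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tractogram",
    "DisconnectomeMatrix",
    "RegionalDisconnection",
    "healthy_connectome",
    "affected_connectome",
    "disconnectome",
    "regional_disconnection",
]


@dataclass
class Tractogram:
    """Streamlines over a labelled voxel grid.

    streamlines : list of (L, 3) integer arrays of voxel indices (i, j, k)
    endpoints : (S, 2) integer array of region labels (1..n_regions) for
        the first and last voxel of each streamline
    n_regions : number of atlas regions N
    grid_shape : shape of the label/lesion grid
    """

    streamlines: list[np.ndarray]
    endpoints: np.ndarray
    n_regions: int
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        self.endpoints = np.asarray(self.endpoints, dtype=int).reshape(-1, 2)
        if len(self.streamlines) != len(self.endpoints):
            raise ValueError("streamlines and endpoints length mismatch")
        if len(self.endpoints) and (
            self.endpoints.min() < 1 or self.endpoints.max() > self.n_regions
        ):
            raise ValueError("endpoint labels must lie in 1..n_regions")
        shape = np.asarray(self.grid_shape, dtype=int)
        for idx, sl in enumerate(self.streamlines):
            sl = np.asarray(sl, dtype=int)
            if sl.ndim != 2 or sl.shape[1] != 3:
                raise ValueError(f"streamline {idx} is not an (L, 3) voxel path")
            if sl.min(initial=0) < 0 or np.any(sl >= shape):
                raise ValueError(f"streamline {idx} leaves the grid bounds")
            self.streamlines[idx] = sl

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class DisconnectomeMatrix:
    """Pairwise disconnection proportions and the defined-entry mask."""

    values: np.ndarray  # (N, N) in [0, 1]
    defined: np.ndarray  # (N, N) bool, True where HC > 0


@dataclass
class RegionalDisconnection:
    """Per-region and whole-brain disconnection proportions."""

    regional: np.ndarray  # (N,) in [0, 1]
    whole_brain: float


def _pair_counts(endpoints: np.ndarray, n_regions: int, which: np.ndarray | None = None) -> np.ndarray:
    """Symmetric endpoint-pair count matrix (0-based indexing internally)."""
    M = np.zeros((n_regions, n_regions), dtype=int)
    ep = endpoints if which is None else endpoints[which]
    for a, b in ep:
        i, j = a - 1, b - 1
        M[i, j] += 1
        if i != j:
            M[j, i] += 1
    return M


def healthy_connectome(tractogram: Tractogram) -> np.ndarray:
    """Count all streamlines by endpoint region pair (symmetric N x N)."""
    return _pair_counts(tractogram.endpoints, tractogram.n_regions)


def streamline_hits_mask(tractogram: Tractogram, lesion_mask: np.ndarray) -> np.ndarray:
    """Boolean vector: does each streamline's voxel path touch the mask."""
    mask = np.asarray(lesion_mask)
    if mask.shape != tuple(tractogram.grid_shape):
        raise ValueError(
            f"lesion grid {mask.shape} does not match tractogram grid "
            f"{tuple(tractogram.grid_shape)}"
        )
    mask = mask.astype(bool)
    hits = np.empty(len(tractogram), dtype=bool)
    for s, sl in enumerate(tractogram.streamlines):
        hits[s] = mask[sl[:, 0], sl[:, 1], sl[:, 2]].any()
    return hits


def affected_connectome(tractogram: Tractogram, lesion_mask: np.ndarray) -> np.ndarray:
    """Count lesion-affected streamlines by endpoint region pair."""
    hits = streamline_hits_mask(tractogram, lesion_mask)
    return _pair_counts(tractogram.endpoints, tractogram.n_regions, hits)


def disconnectome(HC: np.ndarray, AC: np.ndarray) -> DisconnectomeMatrix:
    """D = 1 - (HC - AC)/HC where HC > 0; 0 (undefined) where HC = 0."""
    HC = np.asarray(HC, dtype=float)
    AC = np.asarray(AC, dtype=float)
    if HC.shape != AC.shape:
        raise ValueError("HC and AC shapes differ")
    if np.any(AC > HC):
        raise ValueError("AC exceeds HC: affected counts cannot outnumber healthy counts")
    if np.any(AC < 0) or np.any(HC < 0):
        raise ValueError("connectome counts must be nonnegative")
    defined = HC > 0
    D = np.zeros_like(HC)
    np.divide(AC, HC, out=D, where=defined)
    return DisconnectomeMatrix(values=D, defined=defined)


def regional_disconnection(HC: np.ndarray, AC: np.ndarray) -> RegionalDisconnection:
    """Proportion of streamlines from/to each region that are affected.

    Row sums count self-connections once (they sit on the diagonal and
    appear in exactly one row). Regions with no streamlines get r_i = 0.
    The whole-brain value is total affected / total streamlines, with
    each streamline counted once (upper triangle + diagonal).
    """
    disconnectome(HC, AC)  # validates shapes, AC <= HC, nonnegativity
    HC = np.asarray(HC, dtype=float)
    AC = np.asarray(AC, dtype=float)
    hc_rows = HC.sum(axis=1)  # diagonal (self-connections) contributes once per row
    ac_rows = AC.sum(axis=1)
    regional = np.zeros(HC.shape[0])
    nz = hc_rows > 0
    regional[nz] = ac_rows[nz] / hc_rows[nz]
    iu = np.triu_indices(HC.shape[0])
    total_hc = HC[iu].sum()
    total_ac = AC[iu].sum()
    whole = float(total_ac / total_hc) if total_hc > 0 else 0.0
    return RegionalDisconnection(regional=regional, whole_brain=whole)
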