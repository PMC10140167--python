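"""Greedy neighbor-count (GROMOS-style) conformational clustering.

Frames are compared by backbone RMSD after per-pair optimal superposition.
The frame with the most neighbors under the cutoff becomes a cluster center,
the cluster is removed, and the procedure repeats until no frames remain.
Ties are broken by the lowest frame index; the neighbor test is strict (<).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .model_io import StructureFrame, Trajectory

__all__ = [
    "Cluster",
    "ClusterResult",
    "backbone_indices",
    "rmsd_matrix",
    "gromos_cluster",
    "cluster_mid_structure",
    "cluster_report",
]

_BACKBONE = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    center: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cutoff: float
    atom_selection: str = ""

    def sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]


def backbone_indices(traj: Trajectory | StructureFrame,
                     chains: list[str] | None = None) -> list[int]:
    """Indices of polymer backbone atoms (N, CA, C, O), optionally
    restricted to a chain set."""
    frame = traj.frames[0] if isinstance(traj, Trajectory) else traj
    out = [i for i, a in enumerate(frame.atoms)
           if not a.is_hetero and a.atom_name in _BACKBONE
           and (chains is None or a.chain_id in chains)]
    return out


def rmsd_matrix(traj: Trajectory, selection: list[int] | None = None,
                chains: list[str] | None = None) -> np.ndarray:
    """Pairwise backbone RMSD matrix with per-pair Kabsch superposition."""
    if selection is None:
        selection = backbone_indices(traj, chains)
    if not selection:
        raise ValueError("empty atom selection")
    coords = traj.coords_array(selection)
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_superpose(coords[j], coords[i])[2]
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Cluster a symmetric distance matrix by greedy neighbor counting."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = len(mat)
    remaining = list(range(n))
    neighbor = mat < cutoff
    clusters: list[Cluster] = []
    while remaining:
        idx = np.array(remaining)
        counts = neighbor[np.ix_(idx, idx)].sum(axis=1)  # includes self
        center = idx[int(np.argmax(counts))]             # argmax -> lowest idx
        members = tuple(i for i in remaining if neighbor[center, i])
        clusters.append(Cluster(members, int(center)))
        taken = set(members)
        remaining = [i for i in remaining if i not in taken]
    return ClusterResult(clusters, float(cutoff))


def cluster_mid_structure(traj: Trajectory, result: ClusterResult,
                          cluster_index: int) -> StructureFrame:
    """The center ('mid') frame of one cluster."""
    if not 0 <= cluster_index < len(result.clusters):
        raise IndexError(f"cluster index {cluster_index} out of range "
                         f"(0..{len(result.clusters) - 1})")
    return traj.frames[result.clusters[cluster_index].center]


def cluster_report(result: ClusterResult) -> pd.DataFrame:
    rows = [{"cluster": i, "size": len(c.members), "center_frame": c.center,
             "members": ",".join(map(str, c.members))}
            for i, c in enumerate(result.clusters)]
    return pd.DataFrame(rows, columns=["cluster", "size", "center_frame",
                                       "members"])
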