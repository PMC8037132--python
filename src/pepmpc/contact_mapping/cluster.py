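"""GROMOS-style conformational clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import PepmpcError
from .superpose import rmsd


@dataclass
class ClusterAssignment:
    """Result of greedy neighbour-count clustering.

    ``sizes`` are descending by extraction order; ``membership[f]`` is
    the 0-based cluster id of frame ``f``; ``representatives[c]`` the
    frame index of cluster ``c``'s representative.
    """

    cutoff: float
    sizes: list
    representatives: list
    membership: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def pairwise_rmsd_matrix(frames: np.ndarray,
                         superpose: bool = True) -> np.ndarray:
    frames = np.asarray(frames, float)
    n = frames.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd(frames[i], frames[j],
                                         superpose=superpose)
    return mat


def gromos_cluster(frames, cutoff: float, superpose: bool = True,
                   stride: int = 1,
                   max_frames: int = 20000) -> ClusterAssignment:
    """Greedy neighbour-count clustering of conformations.

    The frame with the most neighbours within ``cutoff`` (superposed
    RMSD, same unit as the coordinates) becomes the representative of
    the first cluster; it and its members are removed and the procedure
    repeats.  Ties break toward the lowest frame index.
    """
    if cutoff <= 0:
        raise PepmpcError("cutoff must be positive")
    frames = np.asarray(frames, float)[::max(1, int(stride))]
    n = frames.shape[0]
    if n < 1:
        raise PepmpcError("need at least one frame")
    if n > max_frames:
        raise PepmpcError(
            f"{n} frames exceed the memory guard ({max_frames}); "
            "increase stride or max_frames")
    mat = pairwise_rmsd_matrix(frames, superpose=superpose)
    neighbours = mat <= cutoff
    membership = np.full(n, -1, dtype=int)
    sizes, representatives = [], []
    remaining = np.ones(n, dtype=bool)
    cluster_id = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))           # first max -> lowest index
        members = np.nonzero(neighbours[rep] & remaining)[0]
        membership[members] = cluster_id
        sizes.append(int(members.size))
        representatives.append(rep)
        remaining[members] = False
        cluster_id += 1
    return ClusterAssignment(cutoff=cutoff, sizes=sizes,
                             representatives=representatives,
                             membership=membership)
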