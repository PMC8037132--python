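"""Pose clustering into population tables and contact-residue lookup."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import PepmpcError
from ..units import A_PER_NM
from ..structure_model.beads import NanoclusterModel, PeptideModel
from .energy import EnergyBreakdown
from .simulate import DockedPose, _SoluteArrays, _pose_coords_nm


@dataclass
class DockingClusterRow:
    """One row of a docking population table."""

    conf_index: int
    clust_index: str
    rel_pop: float                       # percent of all poses
    representative_energy: EnergyBreakdown | None
    spread: float                        # mean member RMSD to rep, A
    size: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rel_pop <= 100.0:
            raise PepmpcError("rel_pop must lie in [0, 100]")
        if np.isfinite(self.spread) and self.spread < 0:
            raise PepmpcError("spread must be non-negative")


def _pose_coord_matrix(poses: Sequence[DockedPose]) -> np.ndarray:
    coords = []
    for p in poses:
        if p.coords is None:
            raise PepmpcError("pose lacks cached coordinates; record poses "
                              "through run_docking or attach coords")
        coords.append(p.coords)
    return np.asarray(coords)


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Raw (no superposition) pairwise RMSD matrix over pose coordinates."""
    n, m, _ = coords.shape
    flat = coords.reshape(n, -1)
    d2 = cdist(flat, flat, metric="sqeuclidean")
    return np.sqrt(d2 / m)


def cluster_poses(poses: Sequence[DockedPose], n_clusters: int = 5,
                  cutoff: float = 2.0) -> list[DockingClusterRow]:
    """Greedy neighbour-count (GROMOS) clustering of docked poses.

    The pose with the most neighbours within ``cutoff`` (A, raw RMSD in
    the shared cluster frame) becomes the representative of the first
    cluster; it and its members are removed and the procedure repeats.
    The top ``n_clusters`` clusters are emitted; any remaining poses are
    aggregated into a trailing ``rest`` row so that populations total
    100%.
    """
    if n_clusters < 1:
        raise PepmpcError("n_clusters must be >= 1")
    if not poses:
        raise PepmpcError("no poses to cluster")
    coords = _pose_coord_matrix(poses)
    rmsd = _pairwise_rmsd(coords)
    n = len(poses)
    remaining = np.ones(n, dtype=bool)
    rows: list[DockingClusterRow] = []
    emitted = 0
    label = 0
    while remaining.any():
        idx = np.nonzero(remaining)[0]
        neigh = (rmsd[np.ix_(idx, idx)] <= cutoff)
        counts = neigh.sum(axis=1)
        best = int(np.argmax(counts))  # ties -> lowest index (argmax rule)
        rep = idx[best]
        members = idx[neigh[best]]
        label += 1
        if emitted < n_clusters:
            others = members[members != rep]
            spread = float(rmsd[rep, others].mean()) if others.size else 0.0
            rows.append(DockingClusterRow(
                conf_index=poses[rep].conformer_index,
                clust_index=str(label),
                rel_pop=100.0 * members.size / n,
                representative_energy=poses[rep].energy,
                spread=spread,
                size=int(members.size),
            ))
            emitted += 1
        else:
            if rows and rows[-1].clust_index == "rest":
                rows[-1].rel_pop += 100.0 * members.size / n
                rows[-1].size += int(members.size)
            else:
                rows.append(DockingClusterRow(
                    conf_index=-1, clust_index="rest",
                    rel_pop=100.0 * members.size / n,
                    representative_energy=None, spread=float("nan"),
                    size=int(members.size),
                ))
        remaining[members] = False
    return rows


def contacting_residues(pose: DockedPose, peptide: PeptideModel,
                        cluster: NanoclusterModel,
                        cutoff: float = 3.5) -> list[int]:
    """Peptide residues with any bead strictly closer than ``cutoff`` (A)
    to any cluster bead, ordered by residue index."""
    pep = _SoluteArrays.from_peptide(peptide, pose.conformer_index)
    coords_A = _pose_coords_nm(pose, pep) * A_PER_NM
    cl_coords_A = (cluster.coords() - cluster.center()) * A_PER_NM
    d = cdist(coords_A, cl_coords_A)
    close = d.min(axis=1) < cutoff
    res = peptide.residue_indices()
    return sorted(set(int(r) for r in res[close]))
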