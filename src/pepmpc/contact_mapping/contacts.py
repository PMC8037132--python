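"""Ligand-peptide contact statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import PepmpcError
from ..units import A_PER_NM, NM_PER_A
from ..structure_model.beads import Trajectory
from ..association_metrics.profile import minimum_image


@dataclass
class ContactTable:
    """Per-ligand contact probabilities and per-frame contact sets.

    ``probability[lig]`` is the fraction of frames in which that ligand's
    terminal N is within ``cutoff`` (A, inclusive) of any peptide site.
    ``records`` holds (frame, ligand_id, peptide_site, distance_A).
    """

    cutoff: float
    ligand_ids: np.ndarray
    probability: dict
    frame_sets: list
    records: list = field(default_factory=list)

    def high_probability_ligands(self, threshold: float = 0.5) -> list:
        return sorted(lig for lig, p in self.probability.items()
                      if p >= threshold)


def ligand_contacts(traj: Trajectory, terminal_n_indices,
                    cutoff: float = 3.0, peptide_id: str = "peptide",
                    ligand_ids=None) -> ContactTable:
    """Contacts between ligand terminal N sites and any peptide bead.

    The cutoff is inclusive (<=, in Angstrom) and distances observe the
    minimum-image convention.  ``terminal_n_indices`` are global atom
    indices of the tagged terminal N sites; ``ligand_ids`` default to
    1..n in the same order.
    """
    terminal_n_indices = np.asarray(terminal_n_indices, dtype=int)
    if terminal_n_indices.size == 0:
        raise PepmpcError("no ligand terminal N sites tagged")
    if ligand_ids is None:
        ligand_ids = np.arange(1, terminal_n_indices.size + 1)
    ligand_ids = np.asarray(ligand_ids)
    pep = traj.molecule(peptide_id)                  # (F, P, 3) nm
    lig = traj.coords[:, terminal_n_indices, :]      # (F, L, 3) nm
    cutoff_nm = cutoff * NM_PER_A

    diff = pep[:, :, None, :] - lig[:, None, :, :]
    diff = minimum_image(diff, traj.box_length)
    dist = np.sqrt(np.einsum("fplk,fplk->fpl", diff, diff))
    min_dist = dist.min(axis=1)                      # (F, L)
    argmin_site = dist.argmin(axis=1)
    in_contact = min_dist <= cutoff_nm

    id_list = [x.item() if hasattr(x, "item") else x for x in ligand_ids]
    probability = {
        lig_id: float(in_contact[:, j].mean())
        for j, lig_id in enumerate(id_list)
    }
    frame_sets = [
        frozenset(id_list[j] for j in np.nonzero(in_contact[f])[0])
        for f in range(traj.n_frames)
    ]
    records = [
        (int(f), id_list[j], int(argmin_site[f, j]),
         float(min_dist[f, j] * A_PER_NM))
        for f, j in zip(*np.nonzero(in_contact))
    ]
    return ContactTable(cutoff=cutoff, ligand_ids=ligand_ids,
                        probability=probability, frame_sets=frame_sets,
                        records=records)


def simultaneous_contact_matrix(table: ContactTable):
    """Ligand x ligand co-occurrence counts.

    Entry (a, b) counts frames in which both ligands contact the
    peptide; the diagonal holds per-ligand contact frame counts.
    Returns (ligand_ids, matrix).
    """
    if not table.frame_sets:
        raise PepmpcError("empty contact table")
    ids = table.ligand_ids
    index = {lig: i for i, lig in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=int)
    for frame_set in table.frame_sets:
        present = [index[lig] for lig in frame_set]
        for a in present:
            counts[a, present] += 1
    return ids, counts


def inter_ligand_distances(traj: Trajectory, ligand_ids,
                           terminal_n_indices,
                           all_ligand_ids=None) -> dict:
    """Pairwise terminal-N distance time series (A) for chosen ligands.

    Returns ``{"pairs": [(a, b), ...], "series": (n_pairs, n_frames)
    array, "mean": per-pair means, "sd": per-pair SDs, "pooled_mean":
    scalar}``.
    """
    ligand_ids = list(ligand_ids)
    if len(ligand_ids) < 2:
        raise PepmpcError("need at least two ligand ids")
    terminal_n_indices = np.asarray(terminal_n_indices, dtype=int)
    if all_ligand_ids is None:
        all_ligand_ids = np.arange(1, terminal_n_indices.size + 1)
    index = {lig: j for j, lig in enumerate(all_ligand_ids)}
    missing = [lig for lig in ligand_ids if lig not in index]
    if missing:
        raise PepmpcError(f"unknown ligand id(s): {missing}")
    pairs = [(a, b) for i, a in enumerate(ligand_ids)
             for b in ligand_ids[i + 1:]]
    series = []
    for a, b in pairs:
        pa = traj.coords[:, terminal_n_indices[index[a]], :]
        pb = traj.coords[:, terminal_n_indices[index[b]], :]
        diff = minimum_image(pa - pb, traj.box_length)
        series.append(np.linalg.norm(diff, axis=1) * A_PER_NM)
    series = np.asarray(series)
    return {
        "pairs": pairs,
        "series": series,
        "mean": series.mean(axis=1),
        "sd": series.std(axis=1),
        "pooled_mean": float(series.mean()),
    }
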