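"""Centers of mass, gyration radii, end-to-end distances and dihedrals.

Coordinate inputs are in nm unless stated otherwise; scalar shape
observables (Rg, end-to-end) are returned in the same unit as the input
coordinates, so callers feeding nm get nm.  Angles are radians.
"""

from __future__ import annotations

import numpy as np

from ..errors import PepmpcError
from ..structure_model.beads import PeptideModel


def com(coords, masses=None) -> np.ndarray:
    """Mass-weighted mean position; equal masses give the centroid."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise PepmpcError("need at least one bead")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, float)
    if np.any(masses < 0):
        raise PepmpcError("masses must be non-negative")
    total = masses.sum()
    if total <= 0:
        raise PepmpcError("total mass must be positive")
    return (coords * masses[:, None]).sum(axis=0) / total


def radius_of_gyration(coords, masses=None) -> float:
    """sqrt(sum m_i |r_i - r_COM|^2 / sum m_i)."""
    coords = np.asarray(coords, float)
    center = com(coords, masses)
    d2 = np.sum((coords - center) ** 2, axis=1)
    if masses is None:
        return float(np.sqrt(d2.mean()))
    masses = np.asarray(masses, float)
    return float(np.sqrt(np.dot(masses, d2) / masses.sum()))


def end_to_end(peptide: PeptideModel, frame_coords=None,
               conformer: int = 0) -> float:
    """Distance between the N-terminal N site and the C-terminal C site.

    ``frame_coords`` optionally overrides the conformer coordinates
    (same bead ordering).
    """
    i_n = peptide.bead_index("NT")
    i_c = peptide.bead_index("CT")
    coords = peptide.coords(conformer) if frame_coords is None \
        else np.asarray(frame_coords, float)
    return float(np.linalg.norm(coords[i_c] - coords[i_n]))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (rad) of four points, IUPAC convention.

    trans corresponds to +-pi, cis to 0; mirror images negate the angle.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise PepmpcError("dihedral undefined for collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.arctan2(y, x))
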