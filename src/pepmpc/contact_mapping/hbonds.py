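"""Geometric hydrogen-bond counting."""

from __future__ import annotations

import math

import numpy as np

from ..errors import PepmpcError
from ..units import NM_PER_A


def hbond_count(frame_coords, donors, acceptors, d_cut: float = 3.5,
                angle_cut: float = 120.0) -> int:
    """Count donor-acceptor pairs satisfying the geometric criterion.

    Parameters
    ----------
    frame_coords
        (n_atoms, 3) coordinates in nm.
    donors
        Sequence of (donor_index, hydrogen_index) pairs.
    acceptors
        Sequence of acceptor atom indices.
    d_cut
        Donor...acceptor distance cutoff in Angstrom (inclusive).
    angle_cut
        Minimum D-H...A angle at the hydrogen, degrees.
    """
    coords = np.asarray(frame_coords, float)
    acceptors = list(acceptors)
    count = 0
    for pair in donors:
        if pair is None or len(pair) != 2 or pair[1] is None:
            raise PepmpcError("each donor needs an attached hydrogen")
        d_idx, h_idx = pair
        d_pos = coords[d_idx]
        h_pos = coords[h_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            a_pos = coords[a_idx]
            if np.linalg.norm(a_pos - d_pos) > d_cut * NM_PER_A:
                continue
            v1 = d_pos - h_pos
            v2 = a_pos - h_pos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            cosang = float(np.dot(v1, v2) / (n1 * n2))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle >= angle_cut:
                count += 1
    return count
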