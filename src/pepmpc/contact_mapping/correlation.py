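"""Site-site pair correlation function under periodic boundaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import PepmpcError
from ..units import A_PER_NM
from ..structure_model.beads import Trajectory
from ..association_metrics.profile import minimum_image


@dataclass
class RadialDistribution:
    """g(r) between two site selections.

    ``r_centers`` in Angstrom; ``g`` approaches 1 at large r for
    uncorrelated homogeneous systems.
    """

    r_centers: np.ndarray
    g: np.ndarray
    shell_width: float
    reference_pair: tuple


def pair_correlation(traj: Trajectory, selector_A, selector_B,
                     r_max: float, shell_width: float,
                     labels: tuple = ("A", "B")) -> RadialDistribution:
    """Radial distribution function between atom selections A and B.

    ``selector_A``/``selector_B`` are global atom index arrays; ``r_max``
    and ``shell_width`` are in Angstrom.  Each A site's neighbour count
    in a shell is normalized by the ideal-gas expectation
    ``rho_B * 4 pi r^2 dr`` with ``rho_B`` the mean density of B sites in
    the periodic box; identical atom indices are excluded.
    """
    sel_a = np.asarray(selector_A, dtype=int)
    sel_b = np.asarray(selector_B, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise PepmpcError("empty selector")
    if traj.box_length is None:
        raise PepmpcError("pair correlation requires a periodic box")
    box_A = traj.box_length * A_PER_NM
    if r_max >= box_A / 2:
        raise PepmpcError("r_max must be below half the box length")
    edges = np.arange(0.0, r_max + shell_width, shell_width)
    edges = edges[edges <= r_max + 1e-9]
    counts = np.zeros(len(edges) - 1)

    a = traj.coords[:, sel_a, :]
    b = traj.coords[:, sel_b, :]
    same = sel_a[:, None] == sel_b[None, :]
    n_excluded = int(same.sum())
    for f in range(traj.n_frames):
        diff = a[f][:, None, :] - b[f][None, :, :]
        diff = minimum_image(diff, traj.box_length)
        r = np.linalg.norm(diff, axis=-1) * A_PER_NM
        r = r[~same]
        hist, _ = np.histogram(r, bins=edges)
        counts += hist

    volume = box_A**3
    rho_b = sel_b.size / volume
    n_pairs_per_frame = sel_a.size * sel_b.size - n_excluded
    # effective number of A-observations per frame
    n_a_eff = n_pairs_per_frame / sel_b.size
    r_lo, r_hi = edges[:-1], edges[1:]
    shell_vol = 4.0 / 3.0 * np.pi * (r_hi**3 - r_lo**3)
    ideal = traj.n_frames * n_a_eff * rho_b * shell_vol
    g = np.divide(counts, ideal, out=np.zeros_like(counts),
                  where=ideal > 0)
    return RadialDistribution(
        r_centers=0.5 * (r_lo + r_hi), g=g, shell_width=shell_width,
        reference_pair=labels)
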