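"""Three-term solute-solute interaction energy.

All energies are in kT.  Coordinates at this interface are bead lists or
(N, 3) arrays in nm; the desolvation cutoffs in :class:`DockingConfig`
are quoted in Angstrom and converted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import ConfigError, PepmpcError
from ..units import NM_PER_A, bjerrum_length, debye_kappa
from ..structure_model.beads import (
    NONPOLAR_CLASSES,
    Bead,
    charges_of,
    coords_of,
)
from .config import DockingConfig

IDENTITY_TOL = 1e-9


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposition of the total interaction energy (kT)."""

    U_EP: float
    U_dse: float
    U_dsh: float
    U_repr: float

    def __post_init__(self):
        if abs(self.U_repr - (self.U_EP + self.U_dse + self.U_dsh)) \
                > IDENTITY_TOL:
            raise PepmpcError(
                "U_repr must equal U_EP + U_dse + U_dsh to 1e-9 kT")

    @classmethod
    def zero(cls) -> "EnergyBreakdown":
        return cls(0.0, 0.0, 0.0, 0.0)


def total_interaction_energy(U_EP: float, U_dse: float,
                             U_dsh: float) -> EnergyBreakdown:
    """Aggregate the three components into a total interaction energy."""
    parts = (U_EP, U_dse, U_dsh)
    if any(not math.isfinite(x) for x in parts):
        raise PepmpcError("energy components must be finite")
    return EnergyBreakdown(U_EP, U_dse, U_dsh, U_EP + U_dse + U_dsh)


def _as_coords_charges(sites):
    if len(sites) and isinstance(sites[0], Bead):
        return coords_of(sites), charges_of(sites)
    raise PepmpcError("expected a bead list")


def electrostatic_energy(sites_A: Sequence[Bead], sites_B: Sequence[Bead],
                         config: DockingConfig) -> float:
    """Screened Coulomb energy between two charge-site sets, in kT.

    U = sum_ij q_i q_j l_B exp(-kappa r_ij) / r_ij with the Bjerrum
    length l_B of the solvent and the Debye constant kappa from the
    ionic strength.  Site pairs closer than ``clash_min_distance`` flag a
    clash and the energy is capped at ``U_max``.
    """
    if len(sites_A) < 1 or len(sites_B) < 1:
        raise PepmpcError("need at least one charge site on each side")
    ra, qa = _as_coords_charges(sites_A)
    rb, qb = _as_coords_charges(sites_B)
    return _electrostatic_energy_arrays(ra, qa, rb, qb, config)


def _electrostatic_energy_arrays(ra, qa, rb, qb,
                                 config: DockingConfig) -> float:
    lb = bjerrum_length(config.solvent_dielectric, config.temperature)
    kappa = debye_kappa(config.ionic_strength, config.solvent_dielectric,
                        config.temperature)
    r = cdist(ra, rb)
    if np.any(r < config.clash_min_distance * NM_PER_A):
        # overlapping charge sites: cap rather than diverge
        sign = np.sign(np.sum(np.outer(qa, qb)))
        return float(math.copysign(config.U_max, sign if sign != 0 else 1.0))
    u = float(np.sum(np.outer(qa, qb) * lb * np.exp(-kappa * r) / r))
    return float(np.clip(u, -config.U_max, config.U_max))


def electrostatic_desolvation(sites_A: Sequence[Bead],
                              surface_beads_B: Sequence[Bead],
                              config: DockingConfig) -> float:
    """Penalty (kT, >= 0) for charges of A near the low-dielectric body B.

    U = c * sum_i q_i^2 * sum_j exp(-r_ij / lambda); it vanishes at
    infinite separation.
    """
    if config.lambda_dse <= 0:
        raise ConfigError("lambda_dse must be positive")
    ra, qa = _as_coords_charges(sites_A)
    rb = coords_of(surface_beads_B)
    return _electrostatic_desolvation_arrays(ra, qa, rb, config)


def _electrostatic_desolvation_arrays(ra, qa, rb,
                                      config: DockingConfig) -> float:
    lam = config.lambda_dse * NM_PER_A
    r = cdist(ra, rb)
    proximity = np.exp(-r / lam).sum(axis=1)
    u = config.desolv_coeff_elec * float(np.dot(qa**2, proximity))
    return min(u, config.U_max)


def _nonpolar_mask(beads: Sequence[Bead]) -> np.ndarray:
    return np.array([b.element_class in NONPOLAR_CLASSES for b in beads])


def hydrophobic_desolvation(surface_beads_A: Sequence[Bead],
                            surface_beads_B: Sequence[Bead],
                            config: DockingConfig) -> float:
    """Favorable nonpolar burial term (kT, <= 0 for a negative coefficient).

    Counts nonpolar bead pairs within ``hydro_contact_cutoff`` and scales
    the count by ``desolv_coeff_hydro``.
    """
    ra = coords_of(surface_beads_A)[_nonpolar_mask(surface_beads_A)]
    rb = coords_of(surface_beads_B)[_nonpolar_mask(surface_beads_B)]
    return _hydrophobic_desolvation_arrays(ra, rb, config)


def _hydrophobic_desolvation_arrays(ra, rb, config: DockingConfig) -> float:
    if len(ra) == 0 or len(rb) == 0:
        return 0.0
    r = cdist(ra, rb)
    n_pairs = int(np.count_nonzero(r <= config.hydro_contact_cutoff
                                   * NM_PER_A))
    return config.desolv_coeff_hydro * n_pairs
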