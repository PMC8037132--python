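"""Docking configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ..errors import ConfigError


@dataclass
class DockingConfig:
    """Parameters of the Brownian-dynamics docking protocol.

    Units: distances in Angstrom at this interface (cutoffs, separations),
    diffusion in cm^2/s (translation) and rad^2/ps (rotation), energies
    in kT at ``temperature``.
    """

    ionic_strength: float = 0.010        # mol/L
    solvent_dielectric: float = 78.0
    solute_dielectric: float = 2.0
    temperature: float = 300.0           # K
    start_separation: float = 100.0      # A
    fine_step_distance: float = 50.0     # A; below this, dt = dt_fine
    dt_fine: float = 1.0                 # ps
    dt_coarse_max: float = 20.0          # ps cap of the far-field schedule
    n_runs: int = 5000
    run_length: float = 500.0            # ns per run
    n_record: int = 1000
    rmsd_distinct: float = 1.0           # A between stored poses
    escape_separation: float = 300.0     # A; run stops beyond this
    # translational (cm^2/s) and rotational (rad^2/ps) diffusion
    D_trans_peptide: float = 0.27e-5
    D_trans_cluster: float = 0.11e-5
    D_rot_peptide: float = 30.7e-5
    D_rot_cluster: float = 2.1e-5
    # desolvation model
    desolv_coeff_elec: float = 1.0       # kT per unit q^2 proximity
    lambda_dse: float = 3.0              # A decay length
    desolv_coeff_hydro: float = -0.5     # kT per nonpolar contact pair
    hydro_contact_cutoff: float = 4.5    # A
    # clash handling
    clash_overlap_factor: float = 0.9
    clash_min_distance: float = 0.5      # A; below this sites are "overlapping"
    U_max: float = 1e4                   # kT cap on clashed energies
    swap_period: int = 20                # BD steps between conformer swaps
    cluster_cutoff: float = 2.0          # A GROMOS cutoff for pose clustering
    rng_seed: int = 0
    # electrostatic grid kept for provenance only (grid potentials are
    # replaced by the analytic screened Coulomb model)
    grid_points: tuple = (161, 161, 161)
    grid_spacing: float = 1.0            # A

    def __post_init__(self):
        if self.ionic_strength < 0:
            raise ConfigError("ionic_strength must be non-negative")
        positive = [
            "solvent_dielectric", "solute_dielectric",
            "temperature", "start_separation", "fine_step_distance",
            "dt_fine", "run_length", "lambda_dse", "hydro_contact_cutoff",
            "rmsd_distinct", "escape_separation", "D_trans_peptide",
            "D_trans_cluster", "D_rot_peptide", "D_rot_cluster",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_runs < 1 or self.n_record < 1:
            raise ConfigError("n_runs and n_record must be >= 1")
        if self.swap_period < 1:
            raise ConfigError("swap_period must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
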