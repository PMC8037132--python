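"""Unit conventions and physical constants.

Internal conventions follow the GRO file format: lengths in nanometres,
times in picoseconds, energies in units of kT.  Interfaces that
conventionally use Angstrom (contact cutoffs, SASA, MSD) convert at the
boundary with the helpers below.
"""

from __future__ import annotations

import math

from scipy import constants as _c

#: Angstrom per nanometre.
A_PER_NM = 10.0
#: Nanometre per Angstrom.
NM_PER_A = 0.1

#: 1 cm^2/s expressed in A^2/ps.
A2_PER_PS_FROM_CM2_PER_S = 1e4
#: 1 A^2/ps expressed in cm^2/s.
CM2_PER_S_FROM_A2_PER_PS = 1e-4


def nm_to_A(x):
    return x * A_PER_NM


def A_to_nm(x):
    return x * NM_PER_A


def bjerrum_length(solvent_dielectric: float, temperature: float) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T) in nm."""
    lb_m = _c.e**2 / (
        4.0 * math.pi * _c.epsilon_0 * solvent_dielectric * _c.k * temperature
    )
    return lb_m * 1e9


def debye_kappa(ionic_strength: float, solvent_dielectric: float,
                temperature: float) -> float:
    """Inverse Debye screening length in nm^-1 for a 1:1 electrolyte.

    Parameters
    ----------
    ionic_strength
        Molar ionic strength (mol/L).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    lb = bjerrum_length(solvent_dielectric, temperature)
    # number density of each ion species in nm^-3: mol/L -> nm^-3
    n = ionic_strength * _c.N_A * 1e-24
    return math.sqrt(8.0 * math.pi * lb * n)
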