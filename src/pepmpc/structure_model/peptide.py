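"""Peptide builders, formal charges and counterion accounting."""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from ..errors import ConfigError, InvalidSequenceError, PepmpcError
from .beads import Bead, ElementClass, PeptideModel

#: Three-letter names for the 20 standard residues.
THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Side-chain formal charge at neutral pH; histidine is kept neutral
#: (side-chain pKa below 7).
SIDE_CHAIN_CHARGE = {
    "D": -1, "E": -1, "K": +1, "R": +1, "H": 0,
}

#: Residues carrying an explicit carboxylate-oxygen charge pair.
CARBOXYLATE_RESIDUES = frozenset({"D", "E"})

#: Calpha-Calpha spacing along the chain, nm.
CA_SPACING = 0.38
#: Offset of the terminal N / terminal C sites from the flanking Calpha, nm.
TERMINUS_OFFSET = 0.13

_BACKBONE_RADIUS = 0.23
_SITE_RADIUS = 0.15


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    bad = sorted(set(sequence) - set(THREE_LETTER))
    if bad:
        raise InvalidSequenceError(
            f"unknown residue letter(s) {''.join(bad)!r} in {sequence!r}"
        )


def formal_charge(sequence: str, termini: str = "zwitterionic") -> int:
    """Net formal charge of a peptide in elementary charges.

    Side chains contribute D/E: -1, K/R: +1, neutral His: 0, others: 0.
    Zwitterionic termini contribute +1 - 1 = 0; capped termini 0.
    """
    _validate_sequence(sequence)
    if termini not in ("zwitterionic", "capped"):
        raise ConfigError(f"unknown termini mode {termini!r}")
    return sum(SIDE_CHAIN_CHARGE.get(aa, 0) for aa in sequence)


def counterion_count(total_system_charge: int) -> tuple[int, int]:
    """(n_Na, n_Cl) monovalent counterions neutralizing a net charge."""
    if not float(total_system_charge).is_integer():
        raise PepmpcError("system charge must be an integer number of e")
    q = int(total_system_charge)
    return max(0, -q), max(0, q)


def _chain_path(n: int, mode: str, arc_degrees: float = 320.0) -> tuple:
    """Backbone positions plus unit tangents for ``n`` residues.

    ``extended`` lays the chain along +x; ``horseshoe`` bends it onto a
    circular arc (default 320 degrees) so that the termini approach.
    """
    if mode == "extended":
        pos = np.zeros((n, 3))
        pos[:, 0] = CA_SPACING * np.arange(n)
        tangents = np.tile([1.0, 0.0, 0.0], (n, 1))
    elif mode == "horseshoe":
        if n == 1:
            return _chain_path(1, "extended")
        theta_span = math.radians(arc_degrees)
        arc_len = CA_SPACING * (n - 1)
        radius = arc_len / theta_span
        angles = np.linspace(0.0, theta_span, n)
        pos = np.column_stack([
            radius * np.cos(angles),
            radius * np.sin(angles),
            np.zeros(n),
        ])
        tangents = np.column_stack([
            -np.sin(angles), np.cos(angles), np.zeros(n)
        ])
    else:
        raise ConfigError(f"unknown geometry mode {mode!r}")
    pos -= pos.mean(axis=0)
    return pos, tangents


def _build_conformer(sequence: str, mode: str, beads_per_residue: int,
                     termini: str) -> list[Bead]:
    n = len(sequence)
    ca_pos, tangents = _chain_path(n, mode)
    beads: list[Bead] = []
    serial = 1

    def add(name, res_idx, aa, element, position, charge, radius):
        nonlocal serial
        beads.append(Bead(
            serial=serial, name=name, residue_index=res_idx,
            residue_name=THREE_LETTER[aa], element_class=element,
            position=np.asarray(position, float), charge=charge,
            radius=radius,
        ))
        serial += 1

    terminal_charge = 1.0 if termini == "zwitterionic" else 0.0
    # N-terminal amine nitrogen of residue 1
    add("NT", 1, sequence[0], ElementClass.N,
        ca_pos[0] - TERMINUS_OFFSET * tangents[0] + [0, 0, 0.05],
        +terminal_charge, _SITE_RADIUS)

    for i, aa in enumerate(sequence):
        res_idx = i + 1
        add("CA", res_idx, aa, ElementClass.C, ca_pos[i], 0.0,
            _BACKBONE_RADIUS)
        for k in range(1, beads_per_residue):
            # extra backbone beads stacked above the Calpha
            add(f"B{k}", res_idx, aa, ElementClass.C,
                ca_pos[i] + [0, 0, 0.12 * k], 0.0, _BACKBONE_RADIUS)
        if aa in CARBOXYLATE_RESIDUES:
            # carboxylate oxygens share the side-chain -1 e
            base = ca_pos[i] + [0, 0, 0.20]
            side = 0.065 * tangents[i]
            add("OD1", res_idx, aa, ElementClass.O, base + side, -0.5,
                _SITE_RADIUS)
            add("OD2", res_idx, aa, ElementClass.O, base - side, -0.5,
                _SITE_RADIUS)
        elif aa in ("K", "R"):
            # basic side chain: one +1 e nitrogen site
            add("NZ", res_idx, aa, ElementClass.N,
                ca_pos[i] + [0, 0, 0.25], +1.0, _SITE_RADIUS)

    # C-terminal carboxyl carbon of the last residue
    add("CT", n, sequence[-1], ElementClass.C,
        ca_pos[-1] + TERMINUS_OFFSET * tangents[-1] + [0, 0, 0.05],
        -terminal_charge, _SITE_RADIUS)
    return beads


def build_peptide(sequence: str,
                  geometry_mode: str | Iterable[str] = "extended",
                  beads_per_residue: int = 1,
                  termini: str = "zwitterionic") -> PeptideModel:
    """Build a coarse peptide model.

    Parameters
    ----------
    sequence
        One-letter amino-acid string.
    geometry_mode
        ``"extended"``, ``"horseshoe"``, or an iterable of modes; one
        conformer is generated per mode (identical topology).
    beads_per_residue
        Number of backbone beads per residue (>= 1).
    """
    _validate_sequence(sequence)
    if beads_per_residue < 1:
        raise ConfigError("beads_per_residue must be >= 1")
    if termini not in ("zwitterionic", "capped"):
        raise ConfigError(f"unknown termini mode {termini!r}")
    modes = [geometry_mode] if isinstance(geometry_mode, str) \
        else list(geometry_mode)
    if not modes:
        raise ConfigError("at least one geometry mode required")
    conformers = [
        _build_conformer(sequence, m, beads_per_residue, termini)
        for m in modes
    ]
    net = formal_charge(sequence, termini)
    model = PeptideModel(sequence=sequence, conformers=conformers,
                         net_charge=net, termini=termini)
    # charge bookkeeping must close
    assert abs(sum(b.charge for b in conformers[0]) - net) < 1e-9
    return model
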