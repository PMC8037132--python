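"""Idealized monolayer-protected nanocluster builder.

The gold core is a sphere of configurable radius; ligand anchor (sulfur)
sites are placed quasi-uniformly on the core surface with a Fibonacci
lattice and each ligand chain extends radially, terminating in a
cationic nitrogen site (+1 e).
"""

from __future__ import annotations

import math

import numpy as np

from ..errors import ConfigError, PepmpcError
from .beads import Bead, ElementClass, NanoclusterModel

#: Bead spacing along a ligand chain, nm.
LIGAND_BEAD_SPACING = 0.15
#: Minimum allowed anchor-anchor separation, nm.
MIN_ANCHOR_SEPARATION = 0.3

_GOLD_RADIUS = 0.17
_CHAIN_RADIUS = 0.20
_N_RADIUS = 0.16


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """``n`` quasi-uniform points on a sphere (golden-spiral lattice)."""
    if n < 1:
        raise ConfigError("need at least one point")
    i = np.arange(n, dtype=float)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * math.pi * i / golden
    rho = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    return radius * np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    )


def _core_positions(n_core: int, core_radius: float) -> np.ndarray:
    """Fill the core ball with concentric Fibonacci shells."""
    if n_core == 1:
        return np.zeros((1, 3))
    # shell radii spaced so shell populations scale with area
    positions = [np.zeros((1, 3))]
    remaining = n_core - 1
    n_shells = max(1, round(core_radius / (2 * _GOLD_RADIUS)))
    radii = core_radius * (np.arange(1, n_shells + 1) / n_shells)
    weights = radii**2 / (radii**2).sum()
    counts = np.maximum(1, np.round(weights * remaining).astype(int))
    # adjust rounding drift on the outermost shell
    counts[-1] += remaining - counts.sum()
    for r, c in zip(radii, counts):
        if c > 0:
            positions.append(fibonacci_sphere(int(c), r))
    return np.vstack(positions)[:n_core]


def build_nanocluster(n_core: int = 144, n_ligands: int = 60,
                      chain_beads: int = 9,
                      core_radius: float = 0.9) -> NanoclusterModel:
    """Build an idealized cationic monolayer-protected cluster.

    Each ligand = anchor S on the core surface, ``chain_beads`` alkyl
    beads, and a terminal N carrying +1 e; total model charge equals
    ``n_ligands``.
    """
    if core_radius <= 0:
        raise ConfigError("core_radius must be positive")
    if n_ligands < 0:
        raise ConfigError("n_ligands must be non-negative")
    if n_core < 1:
        raise ConfigError("n_core must be >= 1")
    if chain_beads < 0:
        raise ConfigError("chain_beads must be non-negative")

    beads: list[Bead] = []
    serial = 1

    def add(name, res_idx, res_name, element, position, charge, radius):
        nonlocal serial
        beads.append(Bead(
            serial=serial, name=name, residue_index=res_idx,
            residue_name=res_name, element_class=element,
            position=np.asarray(position, float), charge=charge,
            radius=radius,
        ))
        serial += 1

    for pos in _core_positions(n_core, core_radius):
        add("AU", 1, "AUC", ElementClass.AU, pos, 0.0, _GOLD_RADIUS)
    core_beads = beads[:]

    ligands: list[list[Bead]] = []
    if n_ligands > 0:
        anchors = fibonacci_sphere(n_ligands, core_radius)
        if n_ligands > 1:
            d = np.linalg.norm(
                anchors[:, None, :] - anchors[None, :, :], axis=-1)
            min_sep = d[np.triu_indices(n_ligands, 1)].min()
            if min_sep <= MIN_ANCHOR_SEPARATION:
                raise PepmpcError(
                    f"{n_ligands} anchors on a {core_radius} nm core violate "
                    f"the {MIN_ANCHOR_SEPARATION} nm anchor separation"
                )
        for lig_idx, anchor in enumerate(anchors):
            direction = anchor / np.linalg.norm(anchor)
            res_idx = 2 + lig_idx
            start = len(beads)
            add("S", res_idx, "LIG", ElementClass.S, anchor, 0.0,
                _CHAIN_RADIUS)
            for k in range(1, chain_beads + 1):
                add(f"C{k}", res_idx, "LIG", ElementClass.C,
                    anchor + direction * LIGAND_BEAD_SPACING * k, 0.0,
                    _CHAIN_RADIUS)
            add("NL", res_idx, "LIG", ElementClass.N,
                anchor + direction * LIGAND_BEAD_SPACING * (chain_beads + 1),
                +1.0, _N_RADIUS)
            ligands.append(beads[start:])

    return NanoclusterModel(core_beads=core_beads, ligands=ligands,
                            core_radius=core_radius, n_ligands=n_ligands)
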