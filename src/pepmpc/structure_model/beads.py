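"""Domain types: beads, peptide and nanocluster models, trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from ..errors import PepmpcError


class ElementClass(str, Enum):
    C = "C"
    N = "N"
    O = "O"
    S = "S"
    AU = "AU"
    H = "H"
    GENERIC = "generic"


#: Element classes treated as nonpolar for hydrophobic desolvation.
NONPOLAR_CLASSES = frozenset({ElementClass.C, ElementClass.S, ElementClass.AU})


@dataclass
class Bead:
    """A single coarse site.

    Attributes
    ----------
    serial : int
        1-based serial, unique within a molecule.
    position : ndarray, shape (3,)
        Cartesian coordinates in nm.
    charge : float
        Formal/effective charge in elementary charges.
    radius : float
        Bead radius in nm.
    """

    serial: int
    name: str
    residue_index: int
    residue_name: str
    element_class: ElementClass
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.15

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise PepmpcError("bead position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise PepmpcError("bead position must be finite")
        if self.radius <= 0:
            raise PepmpcError("bead radius must be positive")
        if self.serial < 1:
            raise PepmpcError("bead serial must be a positive integer")

    def moved_to(self, position) -> "Bead":
        return replace(self, position=np.asarray(position, dtype=float))


def _validate_serials(beads: Sequence[Bead]) -> None:
    serials = [b.serial for b in beads]
    if len(set(serials)) != len(serials):
        raise PepmpcError("bead serials must be unique within a molecule")


def coords_of(beads: Sequence[Bead]) -> np.ndarray:
    """(N, 3) coordinate array in nm."""
    return np.array([b.position for b in beads], dtype=float)


def charges_of(beads: Sequence[Bead]) -> np.ndarray:
    return np.array([b.charge for b in beads], dtype=float)


def radii_of(beads: Sequence[Bead]) -> np.ndarray:
    return np.array([b.radius for b in beads], dtype=float)


@dataclass
class PeptideModel:
    """Multi-conformer coarse peptide.

    All conformers share the same bead topology (count, names, ordering);
    only positions differ.
    """

    sequence: str
    conformers: list[list[Bead]]
    net_charge: int
    termini: str = "zwitterionic"

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise PepmpcError("sequence must contain at least one residue")
        if not self.conformers:
            raise PepmpcError("at least one conformer required")
        ref = [(b.serial, b.name, b.residue_index) for b in self.conformers[0]]
        for conf in self.conformers[1:]:
            if [(b.serial, b.name, b.residue_index) for b in conf] != ref:
                raise PepmpcError("conformers must share identical topology")
        _validate_serials(self.conformers[0])

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return len(self.conformers[0])

    def coords(self, conformer: int = 0) -> np.ndarray:
        return coords_of(self.conformers[conformer])

    def charges(self) -> np.ndarray:
        return charges_of(self.conformers[0])

    def radii(self) -> np.ndarray:
        return radii_of(self.conformers[0])

    def residue_indices(self) -> np.ndarray:
        return np.array([b.residue_index for b in self.conformers[0]])

    def bead_index(self, name: str) -> int:
        for i, b in enumerate(self.conformers[0]):
            if b.name == name:
                return i
        raise PepmpcError(f"no bead named {name!r} in peptide model")

    def backbone_indices(self) -> np.ndarray:
        return np.array(
            [i for i, b in enumerate(self.conformers[0]) if b.name == "CA"]
        )


@dataclass
class NanoclusterModel:
    """Gold core plus thiolate ligand chains with cationic termini."""

    core_beads: list[Bead]
    ligands: list[list[Bead]]
    core_radius: float
    n_ligands: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_ligands is None:
            self.n_ligands = len(self.ligands)
        if self.n_ligands != len(self.ligands):
            raise PepmpcError("n_ligands inconsistent with ligand list")
        _validate_serials(self.all_beads())
        center = self.center()
        for chain in self.ligands:
            anchor = chain[0]
            r = float(np.linalg.norm(anchor.position - center))
            if abs(r - self.core_radius) > 0.05 * self.core_radius:
                raise PepmpcError("ligand anchor not on the core surface")

    def all_beads(self) -> list[Bead]:
        beads = list(self.core_beads)
        for chain in self.ligands:
            beads.extend(chain)
        return beads

    def center(self) -> np.ndarray:
        return coords_of(self.core_beads).mean(axis=0)

    def coords(self) -> np.ndarray:
        return coords_of(self.all_beads())

    def charges(self) -> np.ndarray:
        return charges_of(self.all_beads())

    def radii(self) -> np.ndarray:
        return radii_of(self.all_beads())

    def total_charge(self) -> float:
        return float(self.charges().sum())

    def terminal_n_positions(self) -> np.ndarray:
        """(n_ligands, 3) positions of the terminal cationic N sites."""
        return np.array([chain[-1].position for chain in self.ligands])

    def terminal_n_indices(self) -> np.ndarray:
        """Indices of the terminal N sites within ``all_beads()`` ordering."""
        idx = []
        offset = len(self.core_beads)
        for chain in self.ligands:
            idx.append(offset + len(chain) - 1)
            offset += len(chain)
        return np.array(idx)


@dataclass
class Trajectory:
    """Time-stamped multi-frame coordinates for one or more molecules.

    Attributes
    ----------
    times : ndarray, shape (n_frames,)
        Strictly increasing, in ps.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in nm.
    box_length : float | None
        Cubic box edge in nm; None for a non-periodic system.
    molecule_map : dict[str, tuple[int, int]]
        Molecule id -> half-open bead index range.
    """

    times: np.ndarray
    coords: np.ndarray
    box_length: float | None = None
    molecule_map: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise PepmpcError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise PepmpcError("frame count must equal time count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise PepmpcError("times must be strictly increasing")
        if self.box_length is not None and self.box_length <= 0:
            raise PepmpcError("box_length must be positive")
        if not self.molecule_map:
            self.molecule_map = {"all": (0, self.coords.shape[1])}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def molecule(self, molecule_id: str) -> np.ndarray:
        """Coordinate block (n_frames, n_mol_atoms, 3) for one molecule."""
        try:
            lo, hi = self.molecule_map[molecule_id]
        except KeyError:
            raise PepmpcError(f"unknown molecule id {molecule_id!r}") from None
        return self.coords[:, lo:hi, :]
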