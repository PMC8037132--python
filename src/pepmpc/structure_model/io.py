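"""Structure and trajectory input/output: PDB, GRO and XYZ.

PDB and GRO records are handled by :mod:`biotite`; XYZ (single and
multi-frame) is a trivial three-column format handled directly.  All
coordinates are converted to the internal nm convention on read (biotite
works in Angstrom, GRO files store nm, XYZ files store Angstrom).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from ..errors import ParseError, PepmpcError
from ..units import A_PER_NM, NM_PER_A
from .beads import Bead, ElementClass, Trajectory, coords_of

_ELEMENT_MAP = {
    "C": ElementClass.C, "N": ElementClass.N, "O": ElementClass.O,
    "S": ElementClass.S, "AU": ElementClass.AU, "H": ElementClass.H,
}

_DEFAULT_RADIUS = {
    ElementClass.C: 0.23, ElementClass.N: 0.16, ElementClass.O: 0.15,
    ElementClass.S: 0.20, ElementClass.AU: 0.17, ElementClass.H: 0.11,
    ElementClass.GENERIC: 0.2,
}

#: Formal charges re-attached on read, keyed by bead name.
_NAME_CHARGE = {"NL": 1.0, "OD1": -0.5, "OD2": -0.5, "NT": 1.0, "CT": -1.0}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = os.path.splitext(path)[1].lstrip(".").lower()
    if f not in ("pdb", "gro", "xyz"):
        raise PepmpcError(f"unsupported structure format {f!r}")
    return f


def _guess_element(name: str) -> ElementClass:
    token = "".join(c for c in name if c.isalpha()).upper()
    if token.startswith("AU"):
        return ElementClass.AU
    return _ELEMENT_MAP.get(token[:1], ElementClass.GENERIC)


def _beads_from_atom_array(arr: struc.AtomArray) -> list[Bead]:
    beads = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).upper() if "element" in \
            arr.get_annotation_categories() else ""
        element = _ELEMENT_MAP.get(elem) or _guess_element(
            str(arr.atom_name[i]))
        name = str(arr.atom_name[i])
        beads.append(Bead(
            serial=i + 1,
            name=name,
            residue_index=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            element_class=element,
            position=np.asarray(arr.coord[i], float) * NM_PER_A,
            charge=_NAME_CHARGE.get(name, 0.0),
            radius=_DEFAULT_RADIUS[element],
        ))
    return beads


def _atom_array_from_beads(beads: Sequence[Bead]) -> struc.AtomArray:
    n = len(beads)
    arr = struc.AtomArray(n)
    arr.coord = coords_of(beads).astype(np.float32) * A_PER_NM
    arr.atom_name = np.array([b.name for b in beads], dtype="U6")
    arr.res_id = np.array([b.residue_index for b in beads])
    arr.res_name = np.array([b.residue_name for b in beads], dtype="U5")
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.element = np.array(
        [b.element_class.value if b.element_class != ElementClass.GENERIC
         else "C" for b in beads], dtype="U2")
    arr.hetero = np.array([False] * n)
    return arr


def _prescan_pdb(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                raise ParseError("truncated coordinate record",
                                 path=path, line=lineno)


def read_structure(path: str, format: str | None = None) -> list[Bead]:
    """Read a single-model structure file into a bead list.

    Charges and radii are not stored by these formats; radii are assigned
    from a per-element default table and formal charges are re-attached
    for the package's named charge sites (NT, CT, OD1/OD2, NL).
    """
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        frames, names, _ = _read_xyz(path)
        beads = []
        for i, name in enumerate(names):
            element = _guess_element(name)
            beads.append(Bead(
                serial=i + 1, name=name, residue_index=1,
                residue_name="UNK", element_class=element,
                position=frames[0][i] * NM_PER_A,
                charge=_NAME_CHARGE.get(name, 0.0),
                radius=_DEFAULT_RADIUS[element]))
        return beads
    try:
        if fmt == "pdb":
            _prescan_pdb(path)
            arr = PDBFile.read(path).get_structure(model=1)
        else:
            arr = GROFile.read(path).get_structure(model=1)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"failed to parse {fmt.upper()} file: {exc}",
                         path=path) from exc
    return _beads_from_atom_array(arr)


def write_structure(beads: Sequence[Bead], path: str,
                    format: str | None = None) -> None:
    """Write a bead list as PDB, GRO or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(path, [coords_of(beads) * A_PER_NM],
                   [b.name for b in beads], [0.0])
        return
    arr = _atom_array_from_beads(beads)
    f = PDBFile() if fmt == "pdb" else GROFile()
    f.set_structure(arr)
    f.write(path)


def box_length_from_gro(path: str) -> float | None:
    """Cubic box edge (nm) from the final box line of a GRO file."""
    arr = GROFile.read(path).get_structure(model=1)
    if arr.box is None:
        return None
    return float(arr.box[0, 0]) * NM_PER_A


def read_trajectory(path: str, format: str | None = None,
                    dt: float = 1.0,
                    times: np.ndarray | None = None,
                    box_length: float | None = None,
                    molecule_map: dict | None = None) -> Trajectory:
    """Read a multi-frame coordinate file into a :class:`Trajectory`.

    Frame times come from XYZ comment metadata when present, from the
    ``times`` argument, or default to a uniform spacing ``dt`` (ps).
    """
    fmt = _infer_format(path, format)
    file_times = None
    if fmt == "xyz":
        frames, _, file_times = _read_xyz(path)
        coords = np.asarray(frames) * NM_PER_A
        if all(t is None for t in file_times):
            file_times = None
        elif any(t is None for t in file_times):
            raise ParseError("inconsistent time metadata across frames",
                             path=path)
    else:
        try:
            if fmt == "pdb":
                _prescan_pdb(path)
                stack = PDBFile.read(path).get_structure()
            else:
                stack = GROFile.read(path).get_structure()
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(
                f"failed to parse {fmt.upper()} trajectory: {exc}",
                path=path) from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        coords = np.asarray(stack.coord, float) * NM_PER_A
        if box_length is None and stack.box is not None:
            box = np.asarray(stack.box, float)
            box = box[0] if box.ndim == 3 else box
            if box[0, 0] > 0:
                box_length = float(box[0, 0]) * NM_PER_A
    if coords.shape[0] < 1:
        raise ParseError("trajectory contains no frames", path=path)
    if times is None:
        times = (np.asarray(file_times, float) if file_times is not None
                 else dt * np.arange(coords.shape[0]))
    return Trajectory(times=np.asarray(times, float), coords=coords,
                      box_length=box_length,
                      molecule_map=molecule_map or {})


def write_trajectory(traj: Trajectory, beads: Sequence[Bead], path: str,
                     format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB/GRO or multi-frame XYZ."""
    fmt = _infer_format(path, format)
    if traj.n_atoms != len(beads):
        raise PepmpcError("topology bead count does not match trajectory")
    if fmt == "xyz":
        _write_xyz(path, traj.coords * A_PER_NM,
                   [b.name for b in beads], traj.times)
        return
    arr = _atom_array_from_beads(beads)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = (traj.coords * A_PER_NM).astype(np.float32)
    if traj.box_length is not None:
        stack.box = np.tile(
            np.eye(3, dtype=np.float32) * traj.box_length * A_PER_NM,
            (traj.n_frames, 1, 1))
    f = PDBFile() if fmt == "pdb" else GROFile()
    f.set_structure(stack)
    f.write(path)


def _read_xyz(path: str):
    """Parse (multi-frame) XYZ: coordinates in Angstrom.

    Returns (frames, names, times); a frame comment ``t= <ps>`` is parsed
    into the per-frame time, otherwise the entry is None.
    """
    frames, names, times = [], None, []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", path=path, line=i + 1)
        if i + 2 + n_atoms > n_lines:
            raise ParseError("truncated frame", path=path, line=i + 1)
        comment = lines[i + 1]
        t = None
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                t = None
        frame_names, coords = [], []
        for j in range(n_atoms):
            lineno = i + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError("malformed XYZ atom record",
                                 path=path, line=lineno + 1)
            frame_names.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ParseError("non-numeric coordinate",
                                 path=path, line=lineno + 1)
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ParseError("inconsistent atom names/counts across frames",
                             path=path, line=i + 1)
        frames.append(np.array(coords))
        times.append(t)
        i += 2 + n_atoms
    if not frames:
        raise ParseError("no frames found", path=path)
    return frames, names, times


def _write_xyz(path, frames, names, times):
    with open(path, "w") as fh:
        for frame, t in zip(frames, times):
            fh.write(f"{len(names)}\n")
            fh.write(f"t= {float(t):.6f} ps\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
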