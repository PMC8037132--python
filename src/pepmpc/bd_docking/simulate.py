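"""Brownian-dynamics propagation and flexible docking driver.

The cluster is held fixed at the origin of the lab frame and the peptide
moves in relative coordinates with D_rel = D_trans_peptide +
D_trans_cluster (Ermak-McCammon overdamped update); the peptide is the
mobile rotating body.  Forces come from the analytic gradients of the
screened Coulomb and electrostatic-desolvation terms; the contact-count
nonpolar term contributes to recorded energies and conformer-swap
acceptance only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from ..errors import PepmpcError
from ..units import A_PER_NM, NM_PER_A, A2_PER_PS_FROM_CM2_PER_S, \
    bjerrum_length, debye_kappa
from ..structure_model.beads import (
    NONPOLAR_CLASSES, NanoclusterModel, PeptideModel,
)
from .config import DockingConfig
from .energy import EnergyBreakdown, total_interaction_energy

QUAT_TOL = 1e-8


@dataclass
class DockedPose:
    """Rigid placement of one peptide conformer relative to the cluster.

    ``displacement`` is the cluster-COM -> peptide-COM vector in Angstrom;
    ``orientation`` is a unit quaternion in scipy (x, y, z, w) order;
    ``coords`` optionally caches the peptide bead coordinates (Angstrom,
    cluster frame) at record time.
    """

    conformer_index: int
    displacement: np.ndarray
    orientation: np.ndarray
    energy: EnergyBreakdown | None = None
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        self.orientation = np.asarray(self.orientation, float)
        norm = np.linalg.norm(self.orientation)
        if abs(norm - 1.0) > QUAT_TOL:
            raise PepmpcError("orientation quaternion must be unit norm")

    @property
    def separation(self) -> float:
        """Center-to-center distance, Angstrom."""
        return float(np.linalg.norm(self.displacement))


def timestep_for_separation(separation: float,
                            config: DockingConfig) -> float:
    """BD timestep schedule (ps).

    ``dt_fine`` below ``fine_step_distance``; beyond it the step grows
    linearly (one dt_fine per 10 A) up to ``dt_coarse_max``.
    """
    if separation < config.fine_step_distance:
        return config.dt_fine
    scale = max(1.0, (separation - config.fine_step_distance) / 10.0)
    return min(config.dt_fine * scale, config.dt_coarse_max)


def bd_step(pose: DockedPose, force: np.ndarray, torque: np.ndarray,
            dt: float, config: DockingConfig,
            rng: np.random.Generator) -> DockedPose:
    """One Ermak-McCammon update of the relative coordinates.

    ``force`` in kT/A, ``torque`` in kT/rad, ``dt`` in ps.  Relative
    translational diffusion is the sum of the two solutes' coefficients;
    rotation uses the peptide rotational coefficient.
    """
    if dt <= 0:
        raise PepmpcError("dt must be positive")
    D_rel = (config.D_trans_peptide + config.D_trans_cluster) \
        * A2_PER_PS_FROM_CM2_PER_S  # A^2/ps
    drift = D_rel * np.asarray(force, float) * dt
    noise = rng.normal(0.0, math.sqrt(2.0 * D_rel * dt), size=3)
    new_disp = pose.displacement + drift + noise

    D_rot = config.D_rot_peptide  # rad^2/ps
    rot_drift = D_rot * np.asarray(torque, float) * dt
    rot_noise = rng.normal(0.0, math.sqrt(2.0 * D_rot * dt), size=3)
    dq = Rotation.from_rotvec(rot_drift + rot_noise)
    q = (dq * Rotation.from_quat(pose.orientation)).as_quat()
    q = q / np.linalg.norm(q)
    return replace(pose, displacement=new_disp, orientation=q,
                   energy=pose.energy, coords=None)


def metropolis_conformer_swap(
        pose: DockedPose, n_conformers: int,
        energy_of: Callable[[int], EnergyBreakdown | float],
        rng: np.random.Generator) -> DockedPose:
    """Attempt a move to an adjacent conformer (circular proposal).

    The trial conformer is the previous or next one in the list, each
    proposed with probability 1/2, and accepted with the Metropolis
    probability min(1, exp(-dU_repr)).  Position and orientation are
    preserved.  ``energy_of(i)`` evaluates the interaction energy of
    conformer ``i`` at the current pose.
    """
    if n_conformers < 2:
        raise PepmpcError("conformer swap needs at least two conformers")
    step = 1 if rng.random() < 0.5 else -1
    trial = (pose.conformer_index + step) % n_conformers
    e_cur = energy_of(pose.conformer_index)
    e_new = energy_of(trial)
    u_cur = e_cur.U_repr if isinstance(e_cur, EnergyBreakdown) else e_cur
    u_new = e_new.U_repr if isinstance(e_new, EnergyBreakdown) else e_new
    du = u_new - u_cur
    if du <= 0 or rng.random() < math.exp(-min(du, 700.0)):
        energy = e_new if isinstance(e_new, EnergyBreakdown) else None
        return replace(pose, conformer_index=trial, energy=energy,
                       coords=None)
    return pose


class _SoluteArrays:
    """Precomputed coordinate/charge arrays for fast energy evaluation."""

    def __init__(self, coords_nm, charges, radii, nonpolar):
        self.coords = coords_nm
        self.charges = charges
        self.radii = radii
        self.nonpolar = nonpolar
        self.charged = np.nonzero(charges)[0]

    @classmethod
    def from_peptide(cls, peptide: PeptideModel, conformer: int):
        coords = peptide.coords(conformer)
        coords = coords - coords.mean(axis=0)
        beads = peptide.conformers[conformer]
        return cls(coords, peptide.charges(), peptide.radii(),
                   np.array([b.element_class in NONPOLAR_CLASSES
                             for b in beads]))

    @classmethod
    def from_cluster(cls, cluster: NanoclusterModel):
        beads = cluster.all_beads()
        coords = cluster.coords() - cluster.center()
        return cls(coords, cluster.charges(), cluster.radii(),
                   np.array([b.element_class in NONPOLAR_CLASSES
                             for b in beads]))


def _pose_coords_nm(pose: DockedPose, pep: _SoluteArrays) -> np.ndarray:
    rot = Rotation.from_quat(pose.orientation)
    return rot.apply(pep.coords) + pose.displacement * NM_PER_A


def _energy_and_force(pep_coords, pep: _SoluteArrays, cl: _SoluteArrays,
                      config: DockingConfig, want_force: bool = True):
    """Energy breakdown plus force (kT/A) and torque (kT/rad) on the peptide.

    Returns (EnergyBreakdown, force, torque, clash).
    """
    diff = pep_coords[:, None, :] - cl.coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    clash = bool(np.any(
        r < config.clash_overlap_factor
        * (pep.radii[:, None] + cl.radii[None, :])))

    lb = bjerrum_length(config.solvent_dielectric, config.temperature)
    kappa = debye_kappa(config.ionic_strength, config.solvent_dielectric,
                        config.temperature)
    force_nm = np.zeros_like(pep_coords)

    # screened Coulomb over charged sites
    pi, ci = pep.charged, cl.charged
    r_pc = r[np.ix_(pi, ci)]
    r_safe = np.maximum(r_pc, config.clash_min_distance * NM_PER_A)
    qq = np.outer(pep.charges[pi], cl.charges[ci]) * lb
    screen = np.exp(-kappa * r_safe)
    u_ep = float(np.sum(qq * screen / r_safe))
    u_ep = float(np.clip(u_ep, -config.U_max, config.U_max))
    if want_force:
        coef = qq * screen * (kappa * r_safe + 1.0) / r_safe**2
        unit = diff[np.ix_(pi, ci)] / r_safe[..., None]
        force_nm[pi] += np.einsum("ij,ijk->ik", coef, unit)

    # electrostatic desolvation, both directions
    lam = config.lambda_dse * NM_PER_A
    prox_p = np.exp(-r[pi] / lam)                       # pep charge vs body B
    u_dse_p = float(np.dot(pep.charges[pi]**2, prox_p.sum(axis=1)))
    prox_c = np.exp(-r[:, ci] / lam)                    # cl charge vs body A
    u_dse_c = float(np.dot(prox_c.sum(axis=0), cl.charges[ci]**2))
    u_dse = min(config.desolv_coeff_elec * (u_dse_p + u_dse_c), config.U_max)
    if want_force:
        c_dse = config.desolv_coeff_elec
        w_p = c_dse * pep.charges[pi, None]**2 * prox_p / lam
        unit_p = diff[pi] / np.maximum(r[pi], 1e-6)[..., None]
        force_nm[pi] += np.einsum("ij,ijk->ik", w_p, unit_p)
        w_c = c_dse * prox_c * cl.charges[ci][None, :]**2 / lam
        unit_c = diff[:, ci] / np.maximum(r[:, ci], 1e-6)[..., None]
        force_nm += np.einsum("ij,ijk->ik", w_c, unit_c)

    # nonpolar burial (count-based; no force contribution)
    n_pairs = int(np.count_nonzero(
        r[np.ix_(pep.nonpolar, cl.nonpolar)]
        <= config.hydro_contact_cutoff * NM_PER_A))
    u_dsh = config.desolv_coeff_hydro * n_pairs

    if clash:
        u_ep = config.U_max
    energy = total_interaction_energy(u_ep, u_dse, u_dsh)
    force = force_nm.sum(axis=0) * NM_PER_A  # net force, kT/nm -> kT/A
    com = pep_coords.mean(axis=0)
    torque = np.cross(pep_coords - com, force_nm).sum(axis=0)  # kT/rad
    return energy, force, torque, clash


class PoseStore:
    """Bounded store of the lowest-energy mutually distinct poses."""

    def __init__(self, n_record: int, rmsd_distinct: float):
        self.n_record = n_record
        self.rmsd_distinct = rmsd_distinct
        self.poses: list[DockedPose] = []
        self._coords: list[np.ndarray] = []

    def __len__(self):
        return len(self.poses)

    def _rmsd_to_stored(self, coords: np.ndarray) -> np.ndarray:
        if not self._coords:
            return np.empty(0)
        stored = np.asarray(self._coords)
        d = stored - coords[None, :, :]
        return np.sqrt(np.einsum("nik,nik->n", d, d) / coords.shape[0])

    def consider(self, pose: DockedPose, coords_A: np.ndarray) -> bool:
        """Offer a pose; returns True if stored."""
        u = pose.energy.U_repr
        rmsds = self._rmsd_to_stored(coords_A)
        near = np.nonzero(rmsds <= self.rmsd_distinct)[0]
        if near.size:
            if u < min(self.poses[i].energy.U_repr for i in near):
                # the new pose supersedes every redundant neighbour
                for i in sorted(near, reverse=True):
                    del self.poses[i]
                    del self._coords[i]
                self.poses.append(replace(pose, coords=coords_A.copy()))
                self._coords.append(coords_A.copy())
                self._sort()
                return True
            return False
        if len(self.poses) < self.n_record:
            self.poses.append(replace(pose, coords=coords_A.copy()))
            self._coords.append(coords_A.copy())
            self._sort()
            return True
        if u < self.poses[-1].energy.U_repr:
            self.poses[-1] = replace(pose, coords=coords_A.copy())
            self._coords[-1] = coords_A.copy()
            self._sort()
            return True
        return False

    def _sort(self):
        order = np.argsort([p.energy.U_repr for p in self.poses],
                           kind="stable")
        self.poses = [self.poses[i] for i in order]
        self._coords = [self._coords[i] for i in order]


@dataclass
class DockingResult:
    poses: list[DockedPose]
    visit_fractions: np.ndarray
    n_runs: int
    n_steps: int = 0


def run_docking(peptide: PeptideModel, cluster: NanoclusterModel,
                config: DockingConfig) -> DockingResult:
    """Run the flexible BD docking protocol.

    Each run starts at ``start_separation`` with a random orientation and
    conformer, propagates until ``run_length`` or escape, attempts a
    conformer swap every ``swap_period`` steps, and feeds every evaluated
    pose to the bounded lowest-energy store.
    """
    n_conf = len(peptide.conformers)
    pep_arrays = [_SoluteArrays.from_peptide(peptide, c)
                  for c in range(n_conf)]
    cl_arrays = _SoluteArrays.from_cluster(cluster)
    store = PoseStore(config.n_record, config.rmsd_distinct)
    visits = np.zeros(n_conf)
    run_length_ps = config.run_length * 1000.0
    total_steps = 0

    for run in range(config.n_runs):
        rng = np.random.default_rng([config.rng_seed, run])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pose = DockedPose(
            conformer_index=int(rng.integers(n_conf)),
            displacement=direction * config.start_separation,
            orientation=Rotation.random(rng=rng).as_quat(),
        )
        coords = _pose_coords_nm(pose, pep_arrays[pose.conformer_index])
        energy, force, torque, clash = _energy_and_force(
            coords, pep_arrays[pose.conformer_index], cl_arrays, config)
        pose.energy = energy
        t, step = 0.0, 0
        while t < run_length_ps and pose.separation \
                < config.escape_separation:
            dt = timestep_for_separation(pose.separation, config)
            trial = bd_step(pose, force, torque, dt, config, rng)
            tc = _pose_coords_nm(trial, pep_arrays[trial.conformer_index])
            t_energy, t_force, t_torque, t_clash = _energy_and_force(
                tc, pep_arrays[trial.conformer_index], cl_arrays, config)
            if not t_clash:
                pose, coords, clash = trial, tc, t_clash
                pose.energy, force, torque = t_energy, t_force, t_torque
            # clashed trial: keep the previous pose, advance time
            t += dt
            step += 1
            visits[pose.conformer_index] += 1
            if not clash:
                store.consider(pose, coords * A_PER_NM)
            if n_conf >= 2 and step % config.swap_period == 0:
                def energy_of(i, _pose=pose):
                    c = _pose_coords_nm(replace(_pose, conformer_index=i),
                                        pep_arrays[i])
                    e, *_ = _energy_and_force(c, pep_arrays[i], cl_arrays,
                                              config, want_force=False)
                    return e
                swapped = metropolis_conformer_swap(pose, n_conf,
                                                    energy_of, rng)
                if swapped.conformer_index != pose.conformer_index:
                    pose = swapped
                    coords = _pose_coords_nm(
                        pose, pep_arrays[pose.conformer_index])
                    _, force, torque, clash = _energy_and_force(
                        coords, pep_arrays[pose.conformer_index],
                        cl_arrays, config)
        total_steps += step

    if visits.sum() > 0:
        fractions = visits / visits.sum()
    else:
        fractions = np.full(n_conf, 1.0 / n_conf)
    return DockingResult(poses=store.poses, visit_fractions=fractions,
                         n_runs=config.n_runs, n_steps=total_steps)
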