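"""Synthetic-trajectory generators with exact ground truth.

All generators are deterministic under a fixed ``spec.seed`` (a fresh
``numpy`` Generator is created from it) and return internal-unit
(:class:`~pepmpc.structure_model.beads.Trajectory`, nm/ps) trajectories
plus a :class:`GroundTruth` record.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from ..errors import ConfigError, PepmpcError
from ..units import A2_PER_PS_FROM_CM2_PER_S, NM_PER_A
from ..structure_model.beads import (
    NanoclusterModel, PeptideModel, Trajectory,
)
from .spec import GeneratorSpec, GroundTruth


def _require_kind(spec: GeneratorSpec, kind: str) -> None:
    if spec.kind != kind:
        raise ConfigError(f"spec.kind must be {kind!r}, got {spec.kind!r}")


def _rng(spec: GeneratorSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _ou_series(n: int, mean: float, sigma: float, tau_frames: float,
               rng: np.random.Generator, x0: float | None = None
               ) -> np.ndarray:
    """Discrete Ornstein-Uhlenbeck path with stationary SD ``sigma``."""
    if sigma == 0.0:
        return np.full(n, mean)
    rho = math.exp(-1.0 / tau_frames)
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = mean if x0 is None else x0
    noise = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = mean + rho * (x[t - 1] - mean) + noise[t]
    return x


def _ou_vector(n: int, center: np.ndarray, sigma: float, tau_frames: float,
               rng: np.random.Generator) -> np.ndarray:
    return np.column_stack([
        _ou_series(n, center[k], sigma, tau_frames, rng)
        for k in range(3)
    ])


def gen_free_diffusion(spec: GeneratorSpec):
    """Free Brownian motion of a point solute.

    Per-axis Gaussian increments of variance 2 D dt; coordinates start
    at the origin.
    """
    _require_kind(spec, "free_diffusion")
    rng = _rng(spec)
    D = spec.D_trans * A2_PER_PS_FROM_CM2_PER_S  # A^2/ps
    sd = math.sqrt(2.0 * D * spec.dt)
    increments = rng.normal(0.0, sd, size=(spec.n_frames - 1, 3)) \
        if spec.n_frames > 1 else np.zeros((0, 3))
    pos_A = np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])
    traj = Trajectory(
        times=spec.dt * np.arange(spec.n_frames),
        coords=pos_A[:, None, :] * NM_PER_A,
        box_length=None,
        molecule_map={"peptide": (0, 1)},
    )
    truth = GroundTruth(spec=spec.to_dict(),
                        extras={"D_trans": spec.D_trans})
    return traj, truth


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product in scipy (x, y, z, w) order."""
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def _rotvec_to_quat(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.array([0.0, 0.0, 0.0, 1.0])
    axis = v / angle
    s = math.sin(angle / 2.0)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s,
                     math.cos(angle / 2.0)])


def gen_rotational_diffusion(spec: GeneratorSpec):
    """Isotropic rotational diffusion as a unit-quaternion series.

    Each step applies a random rotation whose rotation-vector components
    are N(0, 2 D_rot dt); a tracked body axis then decorrelates as
    exp(-2 D_rot tau).
    """
    _require_kind(spec, "rotational_diffusion")
    rng = _rng(spec)
    var = 2.0 * spec.D_rot * spec.dt
    if 2.0 * var > 0.1:  # tilt variance of a tracked axis
        warnings.warn("rotational step variance > 0.1 rad^2; "
                      "reduce dt for faithful diffusion")
    sd = math.sqrt(var)
    quats = np.empty((spec.n_frames, 4))
    q = np.array([0.0, 0.0, 0.0, 1.0])
    quats[0] = q
    steps = rng.normal(0.0, sd, size=(spec.n_frames - 1, 3))
    for t in range(1, spec.n_frames):
        q = _quat_mul(_rotvec_to_quat(steps[t - 1]), q)
        q /= np.linalg.norm(q)
        quats[t] = q
    truth = GroundTruth(spec=spec.to_dict(), extras={"D_rot": spec.D_rot})
    return quats, truth


def gen_staged_association(spec: GeneratorSpec):
    """Piecewise-constant COM-distance profile with OU fluctuations.

    The peptide (single bead) drifts slowly on the sphere around a
    static cluster bead at the origin while its radial distance follows
    stage means; stage labels are emitted per frame.
    """
    _require_kind(spec, "staged_association")
    if len(spec.stage_distances) < 2:
        raise ConfigError("need at least two stages")
    if len(spec.stage_distances) != len(spec.stage_durations):
        raise ConfigError("one duration per stage distance required")
    means = np.asarray(spec.stage_distances, float)
    if np.any(np.abs(np.diff(means)) < 2 * spec.noise_sigma):
        warnings.warn("adjacent stage means closer than 2 sigma; "
                      "segmentation may be unidentifiable")
    rng = _rng(spec)
    frames_per_stage = [max(2, int(round(d * 1000.0 / spec.dt)))
                        for d in spec.stage_durations]
    n = sum(frames_per_stage)
    d_series = np.concatenate([
        _ou_series(m, mean, spec.noise_sigma, spec.ou_relaxation_frames,
                   rng)
        for m, mean in zip(frames_per_stage, means)
    ])
    labels = np.concatenate([
        np.full(m, s, dtype=int) for s, m in enumerate(frames_per_stage)
    ])
    # slow angular drift on the unit sphere
    theta = np.empty(n)
    phi = np.empty(n)
    th, ph = 1.0, 0.5
    ang_sd = 0.002
    dth = rng.normal(0.0, ang_sd, size=n)
    dph = rng.normal(0.0, ang_sd, size=n)
    for t in range(n):
        th = min(max(th + dth[t], 0.05), math.pi - 0.05)
        ph += dph[t]
        theta[t] = th
        phi[t] = ph
    unit = np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])
    pep_A = d_series[:, None] * unit
    coords = np.stack([pep_A * NM_PER_A,
                       np.zeros_like(pep_A)], axis=1)
    traj = Trajectory(
        times=spec.dt * np.arange(n),
        coords=coords,
        box_length=spec.box_length * NM_PER_A,
        molecule_map={"peptide": (0, 1), "cluster": (1, 2)},
    )
    truth = GroundTruth(spec=spec.to_dict(), stage_labels=labels,
                        extras={"stage_means": means.tolist(),
                                "d_series": d_series})
    return traj, truth


def gen_conformer_chain(spec: GeneratorSpec, peptide: PeptideModel):
    """Two-state Markov switching between peptide conformer templates.

    The peptide toggles between the first (label 0) and second (label 1)
    conformer with per-ns rates ``switch_rate_fwd``/``switch_rate_rev``;
    Gaussian positional noise of ``noise_sigma`` (A) is added per bead.
    """
    _require_kind(spec, "conformer_chain")
    if len(peptide.conformers) < 2:
        raise PepmpcError("peptide must provide two conformer templates")
    p_fwd = spec.switch_rate_fwd * spec.dt / 1000.0
    p_rev = spec.switch_rate_rev * spec.dt / 1000.0
    if p_fwd > 1 or p_rev > 1:
        raise ConfigError("switch rate too high for this dt")
    for p in (p_fwd, p_rev):
        if p > 0 and 1.0 / p < 10:
            warnings.warn("expected conformer dwell below 10 frames")
    rng = _rng(spec)
    n = spec.n_frames
    labels = np.empty(n, dtype=int)
    state = 0
    u = rng.random(n)
    for t in range(n):
        labels[t] = state
        p = p_fwd if state == 0 else p_rev
        if u[t] < p:
            state = 1 - state
    templates = [peptide.coords(0), peptide.coords(1)]
    noise = rng.normal(0.0, spec.noise_sigma * NM_PER_A,
                       size=(n,) + templates[0].shape)
    coords = np.asarray([templates[lab] for lab in labels]) + noise
    traj = Trajectory(
        times=spec.dt * np.arange(n),
        coords=coords,
        box_length=None,
        molecule_map={"peptide": (0, peptide.n_beads)},
    )
    truth = GroundTruth(spec=spec.to_dict(), conformer_labels=labels)
    return traj, truth


def gen_bound_complex(spec: GeneratorSpec, peptide: PeptideModel,
                      cluster: NanoclusterModel):
    """Bound peptide-cluster trajectory with a designated binding patch.

    The peptide COM is OU-confined near the patch; patch ligand terminal
    N sites are pinned within contact range of designated peptide sites,
    other ligands fluctuate around their ideal geometry and are kept
    outside contact range.  The confined COM yields sub-linear MSD at
    long lags by construction.
    """
    _require_kind(spec, "bound_complex")
    rng = _rng(spec)
    n = spec.n_frames
    patch = list(spec.patch_ligand_ids)
    if not patch:
        raise ConfigError("patch_ligand_ids must be non-empty")
    n_lig = cluster.n_ligands
    if any(not 1 <= lig <= n_lig for lig in patch):
        raise PepmpcError("patch ligand id out of range")

    center = cluster.center()
    cl_coords = cluster.coords() - center          # nm, static template
    n_idx = cluster.terminal_n_indices()
    anchors = np.array([cluster.ligands[lig - 1][0].position - center
                        for lig in patch])
    directions = anchors / np.linalg.norm(anchors, axis=1, keepdims=True)
    pair_dots = directions @ directions.T
    if pair_dots.min() < -0.25:
        raise PepmpcError("patch ligands lie on opposite sides of the "
                          "cluster; no single tether point exists")
    bind_dir = directions.mean(axis=0)
    bind_norm = np.linalg.norm(bind_dir)
    if bind_norm < 1e-9:
        raise PepmpcError("patch spans opposite sides of the cluster")
    bind_dir /= bind_norm

    outer_r = float(np.linalg.norm(cl_coords, axis=1).max())
    tether = bind_dir * (outer_r + 0.25)           # nm
    pep_template = peptide.coords(min(1, len(peptide.conformers) - 1))
    pep_template = pep_template - pep_template.mean(axis=0)

    sigma_axis = spec.confinement_radius * NM_PER_A / math.sqrt(3.0)
    com_path = _ou_vector(n, tether, sigma_axis,
                          spec.ou_relaxation_frames, rng)

    n_beads_pep = pep_template.shape[0]
    pep_sites = [i % n_beads_pep for i in range(len(patch))]
    contact_nm = spec.contact_distance * NM_PER_A
    noise_nm = spec.noise_sigma * NM_PER_A
    exclusion_nm = 0.45                            # 4.5 A
    patch_set = set(patch)

    coords = np.empty((n, n_beads_pep + cl_coords.shape[0], 3))
    lig_noise = rng.normal(0.0, noise_nm, size=(n, n_lig, 3))
    pin_noise = rng.normal(0.0, noise_nm, size=(n, len(patch), 3))
    bead_noise = rng.normal(0.0, 0.5 * noise_nm,
                            size=(n, n_beads_pep, 3))
    for t in range(n):
        pep = pep_template + com_path[t] + bead_noise[t]
        frame_cl = cl_coords.copy()
        # free ligand N jitter
        frame_cl[n_idx] += lig_noise[t]
        # pin patch terminal N within contact range of peptide sites
        for k, lig in enumerate(patch):
            site = pep[pep_sites[k]]
            anchor_dir = directions[k]
            pos = site + anchor_dir * contact_nm * 0.8 + pin_noise[t, k]
            offset = pos - site
            dist = np.linalg.norm(offset)
            if dist > 0.28:                        # keep <= 2.8 A
                pos = site + offset * (0.28 / dist)
            frame_cl[n_idx[lig - 1]] = pos
        # keep non-patch terminal N outside contact range
        for j in range(n_lig):
            if (j + 1) in patch_set:
                continue
            idx = n_idx[j]
            d = np.linalg.norm(pep - frame_cl[idx], axis=1).min()
            if d < exclusion_nm:
                away = frame_cl[idx] - com_path[t]
                away /= np.linalg.norm(away)
                frame_cl[idx] = frame_cl[idx] + away * (exclusion_nm - d
                                                        + 0.15)
        coords[t, :n_beads_pep] = pep
        coords[t, n_beads_pep:] = frame_cl

    traj = Trajectory(
        times=spec.dt * np.arange(n),
        coords=coords,
        box_length=spec.box_length * NM_PER_A,
        molecule_map={"peptide": (0, n_beads_pep),
                      "cluster": (n_beads_pep,
                                  n_beads_pep + cl_coords.shape[0])},
    )
    truth = GroundTruth(
        spec=spec.to_dict(),
        bound_flags=np.ones(n, dtype=bool),
        patch_ligand_ids=tuple(patch),
        extras={
            "terminal_n_indices": n_beads_pep + n_idx,
            "com_path": com_path,
            "tether_point": tether,
        },
    )
    return traj, truth
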