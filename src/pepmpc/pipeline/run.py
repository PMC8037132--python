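"""End-to-end pipeline: build -> dock -> select -> simulate -> analyze."""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from .. import __version__
from ..errors import PepmpcError
from ..structure_model import build_nanocluster, build_peptide, \
    counterion_count, formal_charge
from ..bd_docking import cluster_poses, contacting_residues, run_docking
from ..association_metrics import (
    association_profile, distribution, end_to_end, msd, segment_stages,
)
from ..association_metrics.profile import label_stages
from ..contact_mapping import (
    gromos_cluster, ligand_contacts, simultaneous_contact_matrix,
)
from ..synthetic_data import (
    GeneratorSpec, gen_bound_complex, gen_staged_association,
)
from ..units import A_PER_NM
from .config import PipelineConfig

log = logging.getLogger("pepmpc.pipeline")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PepmpcError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write a report bundle.

    Stages: (i) coarse model building with charge accounting, (ii)
    flexible BD docking and pose clustering, (iii) synthetic bound-state
    trajectory in place of atomistic refinement (clearly labelled), then
    the association/contact/conformation analyses.  Returns the summary
    dictionary (also written to ``summary.json``).
    """
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "pipeline.log"),
                                  mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    summary: dict = {"version": __version__, "seed": config.seed,
                     "stages": {}}

    try:
        # ---- stage i: models and charge accounting -----------------
        peptide, cluster, charges = _build_models(config)
        summary["stages"]["build"] = charges

        # ---- stage ii: docking -------------------------------------
        docking_cfg = config.docking
        docking_cfg.rng_seed = config.seed
        result = run_docking(peptide, cluster, docking_cfg)
        table = _docking_table(result, peptide, cluster, config, outdir)
        summary["stages"]["docking"] = {
            "n_poses": len(result.poses),
            "visit_fractions": result.visit_fractions.tolist(),
            "table": os.path.join(outdir, "docking_table.csv"),
        }

        # ---- stage iii: synthetic refinement substitute ------------
        patch = _select_patch(result, cluster, config)
        traj, truth = _refinement_trajectory(config, peptide, cluster,
                                             patch)
        summary["stages"]["refinement"] = {
            "note": "synthetic bound-complex trajectory substituted "
                    "for atomistic refinement",
            "patch_ligand_ids": list(patch),
        }

        # ---- analyses ----------------------------------------------
        summary["stages"]["analysis"] = _analyze(
            config, peptide, traj, truth, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()

    summary["runtime_s"] = time.time() - t0
    summary["docking_table_head"] = table.head(3).to_dict("records")
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True,
                  default=_json_default)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(os.listdir(outdir)),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True,
                  default=_json_default)
    return summary


@_stage("build")
def _build_models(config: PipelineConfig):
    peptide = build_peptide(config.sequence,
                            ["extended", "horseshoe"])
    cluster = build_nanocluster(config.n_core, config.n_ligands,
                                config.chain_beads, config.core_radius)
    q_pep = formal_charge(config.sequence)
    q_cluster = int(round(cluster.total_charge()))
    charges = {
        "peptide_net_charge": q_pep,
        "cluster_net_charge": q_cluster,
        "counterions_peptide": counterion_count(q_pep),
        "counterions_cluster": counterion_count(q_cluster),
        "counterions_complex": counterion_count(q_pep + q_cluster),
    }
    return peptide, cluster, charges


@_stage("docking")
def _docking_table(result, peptide, cluster, config, outdir):
    rows = []
    if result.poses:
        by_conf = {}
        for pose in result.poses:
            by_conf.setdefault(pose.conformer_index, []).append(pose)
        for conf, poses in sorted(by_conf.items()):
            for row in cluster_poses(poses, n_clusters=5,
                                     cutoff=config.docking.cluster_cutoff):
                e = row.representative_energy
                rows.append({
                    "ConfIndex": conf + 1,
                    "ClustIndex": row.clust_index,
                    "RelPop": row.rel_pop,
                    "U_repr": e.U_repr if e else float("nan"),
                    "U_EP": e.U_EP if e else float("nan"),
                    "U_dse": e.U_dse if e else float("nan"),
                    "U_dsh": e.U_dsh if e else float("nan"),
                    "Spread": row.spread,
                })
    table = pd.DataFrame(
        rows, columns=["ConfIndex", "ClustIndex", "RelPop", "U_repr",
                       "U_EP", "U_dse", "U_dsh", "Spread"])
    table.to_csv(os.path.join(outdir, "docking_table.csv"), index=False)
    if result.poses:
        best = result.poses[0]
        contacts = contacting_residues(best, peptide, cluster,
                                       config.docking_contact_cutoff)
        table.attrs["best_pose_contacts"] = contacts
    return table


def _select_patch(result, cluster, config) -> tuple:
    """Ligands whose terminal N lies closest to the best docked pose."""
    n_patch = min(config.n_patch_ligands, cluster.n_ligands)
    if not result.poses:
        return tuple(range(1, n_patch + 1))
    best = result.poses[0]
    pose_coords_nm = best.coords / A_PER_NM
    n_pos = cluster.terminal_n_positions() - cluster.center()
    d = np.linalg.norm(
        n_pos[:, None, :] - pose_coords_nm[None, :, :], axis=-1
    ).min(axis=1)
    order = np.argsort(d)
    chosen = sorted(int(i) + 1 for i in order[:n_patch])
    # patch ligands must share a hemisphere for the generator tether
    dirs = n_pos[np.array(chosen) - 1]
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    mean_dir = dirs.mean(axis=0)
    if np.linalg.norm(mean_dir) < 1e-9 or \
            np.any(dirs @ (mean_dir / np.linalg.norm(mean_dir)) <= 0):
        return tuple(range(1, n_patch + 1))
    return tuple(chosen)


@_stage("refinement")
def _refinement_trajectory(config, peptide, cluster, patch):
    spec = GeneratorSpec(
        kind="bound_complex",
        dt=config.refine_dt,
        n_frames=config.n_refine_frames,
        seed=config.seed + 1,
        patch_ligand_ids=tuple(patch),
        ou_relaxation_frames=10.0,
    )
    return gen_bound_complex(spec, peptide, cluster)


@_stage("analysis")
def _analyze(config, peptide, traj, truth, outdir) -> dict:
    out: dict = {}
    # association profile of a staged-approach trajectory
    stage_spec = GeneratorSpec(
        kind="staged_association",
        dt=config.refine_dt,
        seed=config.seed + 2,
        stage_distances=tuple(config.stage_distances),
        stage_durations=tuple(config.stage_durations),
        ou_relaxation_frames=5.0,
    )
    staged, staged_truth = gen_staged_association(stage_spec)
    profile = association_profile(staged)
    breaks = segment_stages(profile.d_com,
                            max_segments=len(config.stage_distances),
                            min_len=5)
    profile.stage_labels = label_stages(len(profile.d_com), breaks)
    pd.DataFrame({
        "time_ps": profile.times, "d_com_A": profile.d_com,
        "theta_rad": profile.theta, "phi_rad": profile.phi,
        "stage": profile.stage_labels,
    }).to_csv(os.path.join(outdir, "association_profile.csv"),
              index=False)
    out["stage_breakpoints"] = breaks
    out["stage_means_A"] = [
        float(profile.d_com[profile.stage_labels == s].mean())
        for s in np.unique(profile.stage_labels)
    ]

    # bound-state MSD and diffusion
    pep_com_A = traj.molecule("peptide").mean(axis=1) * A_PER_NM
    res = msd(pep_com_A, dt=float(np.diff(traj.times)[0]))
    out["bound_msd"] = {"D_fit_cm2_s": res.D_fit, "alpha": res.alpha}
    pd.DataFrame({"lag_ps": res.lags, "msd_A2": res.msd}).to_csv(
        os.path.join(outdir, "bound_msd.csv"), index=False)

    # ligand contacts
    table = ligand_contacts(
        traj, truth.extras["terminal_n_indices"],
        cutoff=config.ligand_contact_cutoff)
    ids, sim = simultaneous_contact_matrix(table)
    pd.DataFrame({
        "ligand_id": list(table.probability.keys()),
        "P_contact": list(table.probability.values()),
    }).to_csv(os.path.join(outdir, "ligand_contacts.csv"), index=False)
    np.savetxt(os.path.join(outdir, "simultaneous_contacts.csv"), sim,
               fmt="%d", delimiter=",")
    out["high_P_ligands"] = table.high_probability_ligands(0.5)

    # conformational clustering of the bound peptide
    assignment = gromos_cluster(traj.molecule("peptide"),
                                cutoff=config.cluster_cutoff_nm)
    out["cluster_sizes"] = assignment.sizes[:5]

    # end-to-end distribution
    e2e = np.array([
        end_to_end(peptide, frame) * A_PER_NM
        for frame in traj.molecule("peptide")
    ])
    summ = distribution(e2e, n_bins=30)
    out["end_to_end_A"] = {"mean": summ.mean, "spread": summ.spread,
                           "mode_count": summ.mode_count}
    with open(os.path.join(outdir, "analysis.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True,
                  default=_json_default)
    return out
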