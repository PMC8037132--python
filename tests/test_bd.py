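import math

import numpy as np
import pytest

from pepmpc.errors import PepmpcError
from pepmpc.structure_model import build_nanocluster, build_peptide
from pepmpc.bd_docking import (
    DockedPose,
    DockingConfig,
    bd_step,
    cluster_poses,
    contacting_residues,
    metropolis_conformer_swap,
    run_docking,
    timestep_for_separation,
    total_interaction_energy,
)
from pepmpc.bd_docking.simulate import PoseStore
from pepmpc.units import A2_PER_PS_FROM_CM2_PER_S

IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


def make_pose(disp=(100.0, 0.0, 0.0), conf=0, energy=None, coords=None):
    return DockedPose(conformer_index=conf,
                      displacement=np.asarray(disp, float),
                      orientation=IDENTITY_Q.copy(),
                      energy=energy, coords=coords)


def zero_energy():
    return total_interaction_energy(0.0, 0.0, 0.0)


class TestTimestepSchedule:
    def test_fine_regime(self):
        cfg = DockingConfig()
        assert timestep_for_separation(49.0, cfg) == cfg.dt_fine

    def test_coarse_regime(self):
        cfg = DockingConfig()
        assert timestep_for_separation(200.0, cfg) > cfg.dt_fine

    def test_cap(self):
        cfg = DockingConfig()
        assert timestep_for_separation(1e4, cfg) == cfg.dt_coarse_max


class TestBdStep:
    def test_deterministic_drift(self, rng):
        cfg = DockingConfig()

        class NoNoise:
            def normal(self, loc, scale, size):
                return np.zeros(size)

        force = np.array([1.0, -2.0, 0.5])
        pose = make_pose()
        new = bd_step(pose, force, np.zeros(3), 1.0, cfg, NoNoise())
        D_rel = (cfg.D_trans_peptide + cfg.D_trans_cluster) \
            * A2_PER_PS_FROM_CM2_PER_S
        expected = pose.displacement + D_rel * force * 1.0
        assert np.allclose(new.displacement, expected, atol=1e-12)

    def test_displacement_variance(self, rng):
        # Monte-Carlo variance vs the analytic 2 D_rel dt per axis
        cfg = DockingConfig()
        D_rel = (cfg.D_trans_peptide + cfg.D_trans_cluster) \
            * A2_PER_PS_FROM_CM2_PER_S
        dt = 1.0
        n = 100_000
        pose = make_pose()
        steps = np.empty((n, 3))
        for i in range(n):
            new = bd_step(pose, np.zeros(3), np.zeros(3), dt, cfg, rng)
            steps[i] = new.displacement - pose.displacement
        var = steps.var(axis=0)
        assert np.allclose(var, 2 * D_rel * dt, rtol=0.05)

    def test_quaternion_normalized(self, rng):
        cfg = DockingConfig()
        pose = make_pose()
        for _ in range(100):
            pose = bd_step(pose, np.zeros(3), np.zeros(3), 1.0, cfg, rng)
        assert abs(np.linalg.norm(pose.orientation) - 1.0) < 1e-8

    def test_invalid_dt(self, rng):
        with pytest.raises(PepmpcError):
            bd_step(make_pose(), np.zeros(3), np.zeros(3), 0.0,
                    DockingConfig(), rng)


class TestMetropolisSwap:
    def test_downhill_always_accepted(self, rng):
        pose = make_pose(conf=0, energy=zero_energy())
        for _ in range(50):
            new = metropolis_conformer_swap(
                pose, 3, lambda i: 0.0 if i == pose.conformer_index
                else -5.0, rng)
            assert new.conformer_index != pose.conformer_index

    def test_huge_barrier_rejected(self, rng):
        pose = make_pose(conf=0, energy=zero_energy())
        for _ in range(50):
            new = metropolis_conformer_swap(
                pose, 3, lambda i: 0.0 if i == 0 else 1e6, rng)
            assert new.conformer_index == 0

    def test_acceptance_ratio_one_kt(self, rng):
        # dU = +1 kT -> acceptance probability e^-1
        n = 100_000
        accepted = 0
        pose = make_pose(conf=0, energy=zero_energy())
        for _ in range(n):
            new = metropolis_conformer_swap(
                pose, 2, lambda i: 0.0 if i == 0 else 1.0, rng)
            if new.conformer_index == 1:
                accepted += 1
        assert accepted / n == pytest.approx(math.exp(-1), rel=0.02)

    def test_position_preserved(self, rng):
        pose = make_pose(disp=(10.0, 5.0, -2.0), conf=0,
                         energy=zero_energy())
        new = metropolis_conformer_swap(pose, 2, lambda i: -1.0 * i, rng)
        assert np.allclose(new.displacement, pose.displacement)
        assert np.allclose(new.orientation, pose.orientation)

    def test_needs_two_conformers(self, rng):
        with pytest.raises(PepmpcError):
            metropolis_conformer_swap(make_pose(), 1, lambda i: 0.0, rng)

    def test_detailed_balance_two_state(self, rng):
        # occupancy ratio must reach exp(-(E2 - E1)) within 3%
        e = {0: 0.0, 1: 1.0}
        pose = make_pose(conf=0, energy=zero_energy())
        n = 1_000_000
        visits = np.zeros(2)
        energy_of = e.__getitem__
        for _ in range(n):
            pose = metropolis_conformer_swap(pose, 2, energy_of, rng)
            visits[pose.conformer_index] += 1
        ratio = visits[1] / visits[0]
        assert ratio == pytest.approx(math.exp(-(e[1] - e[0])), rel=0.03)


class TestFreeDiffusionMSD:
    def test_msd_slope(self):
        # all charges zero: pure diffusion; MSD slope must be 6 D_rel
        cfg = DockingConfig()
        D_rel = (cfg.D_trans_peptide + cfg.D_trans_cluster) \
            * A2_PER_PS_FROM_CM2_PER_S
        dt = 1.0
        n_steps, n_rep = 6000, 12
        lags = np.arange(5, 51, 5)
        msds = []
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            pose = make_pose(disp=(0.0, 0.0, 0.0))
            track = np.empty((n_steps + 1, 3))
            track[0] = pose.displacement
            for i in range(n_steps):
                pose = bd_step(pose, np.zeros(3), np.zeros(3), dt, cfg,
                               rng)
                track[i + 1] = pose.displacement
            msds.append([
                np.mean(np.sum((track[lag:] - track[:-lag]) ** 2, axis=1))
                for lag in lags
            ])
        mean_msd = np.mean(msds, axis=0)
        # per-lag slope average keeps short, well-sampled lags dominant
        slope = float(np.mean(mean_msd / (lags * dt)))
        assert slope == pytest.approx(6 * D_rel, rel=0.05)


class TestPoseStore:
    def _pose_with(self, u, x):
        coords = np.zeros((4, 3)) + x
        return make_pose(
            disp=(x, 0, 0), energy=total_interaction_energy(u, 0.0, 0.0),
            coords=coords), coords

    def test_bounded_and_sorted(self, rng):
        store = PoseStore(n_record=5, rmsd_distinct=0.5)
        for k in range(50):
            u = float(rng.normal())
            pose, coords = self._pose_with(u, 10.0 * k)
            store.consider(pose, coords)
        assert len(store) <= 5
        us = [p.energy.U_repr for p in store.poses]
        assert us == sorted(us)

    def test_distinctness(self, rng):
        store = PoseStore(n_record=10, rmsd_distinct=1.0)
        for k in range(30):
            pose, coords = self._pose_with(float(rng.normal()),
                                           0.1 * (k % 3))
            store.consider(pose, coords)
        coords = np.asarray([p.coords for p in store.poses])
        for i in range(len(store)):
            for j in range(i + 1, len(store)):
                d = coords[i] - coords[j]
                r = math.sqrt((d ** 2).sum() / d.shape[0])
                assert r > 1.0


@pytest.fixture(scope="module")
def docked():
    pep = build_peptide("HWDDD", ["extended", "horseshoe"])
    cl = build_nanocluster(n_core=20, n_ligands=12, chain_beads=3)
    cfg = DockingConfig(n_runs=3, run_length=0.3, n_record=50,
                        start_separation=30.0, rng_seed=11)
    return run_docking(pep, cl, cfg), cfg


class TestRunDocking:
    def test_visit_fractions_sum(self, docked):
        result, _ = docked
        assert result.visit_fractions.sum() == pytest.approx(1.0)

    def test_store_contract(self, docked):
        result, cfg = docked
        assert 0 < len(result.poses) <= cfg.n_record
        us = [p.energy.U_repr for p in result.poses]
        assert us == sorted(us)

    def test_energy_identity_on_poses(self, docked):
        result, _ = docked
        for p in result.poses:
            e = p.energy
            assert abs(e.U_repr - (e.U_EP + e.U_dse + e.U_dsh)) < 1e-9

    def test_repulsive_system(self):
        # like charges only: every recorded pose has positive energy
        pep = build_peptide("KKK", "extended")
        cl = build_nanocluster(n_core=20, n_ligands=12, chain_beads=3)
        cfg = DockingConfig(n_runs=2, run_length=0.1, n_record=50,
                            start_separation=30.0, rng_seed=5,
                            desolv_coeff_hydro=0.0)
        result = run_docking(pep, cl, cfg)
        assert all(p.energy.U_repr > 0 for p in result.poses)


class TestClusterPoses:
    def _family(self, center, n, u, spread=0.1, seed=0):
        rng = np.random.default_rng(seed)
        poses = []
        for _ in range(n):
            coords = np.zeros((5, 3)) + center \
                + rng.normal(scale=spread, size=(5, 3))
            poses.append(make_pose(
                disp=(center, 0, 0),
                energy=total_interaction_energy(u, 0.0, 0.0),
                coords=coords))
        return poses

    def test_identical_poses(self):
        coords = np.ones((5, 3))
        poses = [make_pose(energy=zero_energy(), coords=coords.copy())
                 for _ in range(8)]
        rows = cluster_poses(poses, n_clusters=3)
        assert len(rows) == 1
        assert rows[0].rel_pop == pytest.approx(100.0)
        assert rows[0].spread == 0.0

    def test_two_families_60_40(self):
        poses = self._family(0.0, 60, -5.0, seed=1) \
            + self._family(50.0, 40, -3.0, seed=2)
        rows = cluster_poses(poses, n_clusters=5, cutoff=2.0)
        pops = sorted((r.rel_pop for r in rows), reverse=True)
        assert pops[0] == pytest.approx(60.0, abs=2.0)
        assert pops[1] == pytest.approx(40.0, abs=2.0)

    def test_population_conservation_with_residual(self):
        poses = []
        for k in range(10):
            poses += self._family(20.0 * k, 3, -1.0, seed=k)
        rows = cluster_poses(poses, n_clusters=2, cutoff=2.0)
        assert sum(r.rel_pop for r in rows) == pytest.approx(100.0,
                                                             abs=0.1)
        assert rows[-1].clust_index == "rest"

    def test_invalid_n_clusters(self):
        with pytest.raises(PepmpcError):
            cluster_poses([make_pose(coords=np.zeros((2, 3)),
                                     energy=zero_energy())], 0)


class TestContactingResidues:
    def test_far_pose_empty(self, h1_peptide, small_cluster):
        pose = make_pose(disp=(100.0, 0.0, 0.0))
        assert contacting_residues(pose, h1_peptide, small_cluster) == []

    def test_fixture_residues(self, h1_peptide):
        # single-bead "cluster" placed 3 A from residues 2 and 3
        from pepmpc.structure_model.nanocluster import build_nanocluster
        cl = build_nanocluster(n_core=1, n_ligands=0, core_radius=0.9)
        coords = h1_peptide.coords(0)
        coords = coords - coords.mean(axis=0)
        res = h1_peptide.residue_indices()
        ca = [i for i, b in enumerate(h1_peptide.conformers[0])
              if b.name == "CA"]
        # place the peptide so CA of residues 2,3 are ~3 A from origin
        mid = 0.5 * (coords[ca[1]] + coords[ca[2]])
        shift = -mid + np.array([0.0, 0.25, 0.0])
        pose = make_pose(disp=tuple(shift * 10.0))
        got = contacting_residues(pose, h1_peptide, cl, cutoff=3.5)
        assert got == [2, 3]

    def test_boundary_strict(self, h1_peptide):
        from pepmpc.structure_model.nanocluster import build_nanocluster
        cl = build_nanocluster(n_core=1, n_ligands=0, core_radius=0.9)
        # brute-force check of strict inequality on the full distance set
        pose = make_pose(disp=(25.0, 0.0, 0.0))
        got = contacting_residues(pose, h1_peptide, cl, cutoff=3.5)
        from pepmpc.bd_docking.simulate import (
            _SoluteArrays, _pose_coords_nm)
        pep = _SoluteArrays.from_peptide(h1_peptide, 0)
        coords_A = _pose_coords_nm(pose, pep) * 10.0
        res = h1_peptide.residue_indices()
        expect = sorted({
            int(res[i]) for i in range(len(coords_A))
            if np.linalg.norm(coords_A[i]) < 3.5
        })
        assert got == expect
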