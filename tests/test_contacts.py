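import math

import numpy as np
import pytest

from pepmpc.errors import PepmpcError
from pepmpc.structure_model import Trajectory, build_peptide
from pepmpc.contact_mapping import (
    gromos_cluster,
    hbond_count,
    inter_ligand_distances,
    kabsch,
    ligand_contacts,
    native_contact_map,
    pair_correlation,
    rmsd,
    simultaneous_contact_matrix,
)
from pepmpc.units import NM_PER_A


def contact_traj(lig_positions_by_frame, pep_positions_by_frame,
                 box=None):
    """Build a trajectory: peptide beads first, ligand N sites after."""
    n = len(lig_positions_by_frame)
    pep = np.asarray(pep_positions_by_frame, float)
    lig = np.asarray(lig_positions_by_frame, float)
    coords = np.concatenate([pep, lig], axis=1)
    n_pep = pep.shape[1]
    return Trajectory(
        times=np.arange(n, dtype=float), coords=coords, box_length=box,
        molecule_map={"peptide": (0, n_pep),
                      "cluster": (n_pep, coords.shape[1])},
    ), np.arange(n_pep, coords.shape[1])


class TestLigandContacts:
    def test_permanent_contact(self):
        pep = np.zeros((10, 1, 3))
        lig = np.full((10, 1, 3), 0.2)  # 2 A * sqrt(3)? -> 3.46 A; use axis
        lig[:] = [0.2, 0.0, 0.0]        # 2 A away
        traj, idx = contact_traj(lig, pep)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        assert table.probability[1] == 1.0

    def test_never_close(self):
        pep = np.zeros((10, 1, 3))
        lig = np.full((10, 1, 3), [1.0, 0.0, 0.0])  # 10 A
        traj, idx = contact_traj(lig, pep)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        assert table.probability[1] == 0.0

    def test_half_frames(self):
        pep = np.zeros((10, 1, 3))
        lig = np.zeros((10, 1, 3))
        lig[:5] = [0.25, 0.0, 0.0]   # 2.5 A: contact
        lig[5:] = [0.8, 0.0, 0.0]    # 8 A: no contact
        traj, idx = contact_traj(lig, pep)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        assert table.probability[1] == 0.5

    def test_inclusive_cutoff(self):
        pep = np.zeros((1, 1, 3))
        lig = np.array([[[0.3, 0.0, 0.0]]])  # exactly 3 A
        traj, idx = contact_traj(lig, pep)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        assert table.probability[1] == 1.0

    def test_minimum_image(self):
        pep = np.zeros((1, 1, 3))
        lig = np.array([[[3.8, 0.0, 0.0]]])
        traj, idx = contact_traj(lig, pep, box=4.0)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        assert table.probability[1] == 1.0  # wrapped distance 2 A

    def test_no_sites_tagged(self):
        pep = np.zeros((1, 1, 3))
        lig = np.zeros((1, 1, 3))
        traj, _ = contact_traj(lig, pep)
        with pytest.raises(PepmpcError):
            ligand_contacts(traj, [], cutoff=3.0)

    def test_brute_force_oracle(self, rng):
        pep = rng.normal(scale=0.3, size=(8, 4, 3))
        lig = rng.normal(scale=0.3, size=(8, 6, 3))
        traj, idx = contact_traj(lig, pep)
        table = ligand_contacts(traj, idx, cutoff=3.0)
        for j in range(6):
            hits = 0
            for f in range(8):
                close = any(
                    math.dist(pep[f, p], lig[f, j]) <= 3.0 * NM_PER_A
                    for p in range(4))
                hits += close
            assert table.probability[j + 1] == pytest.approx(hits / 8)


class TestSimultaneousContacts:
    def test_disjoint_epochs(self):
        pep = np.zeros((6, 1, 3))
        lig = np.full((6, 2, 3), 2.0)
        lig[:3, 0] = [0.2, 0, 0]
        lig[3:, 1] = [0.2, 0, 0]
        traj, idx = contact_traj(lig, pep)
        ids, counts = simultaneous_contact_matrix(
            ligand_contacts(traj, idx, cutoff=3.0))
        assert counts[0, 1] == 0
        assert counts[0, 0] == 3 and counts[1, 1] == 3

    def test_always_cobound(self):
        pep = np.zeros((5, 1, 3))
        lig = np.tile([0.2, 0.0, 0.0], (5, 2, 1))
        traj, idx = contact_traj(lig, pep)
        ids, counts = simultaneous_contact_matrix(
            ligand_contacts(traj, idx, cutoff=3.0))
        assert counts[0, 1] == 5

    def test_three_ligand_staged_hand_enumeration(self):
        pep = np.zeros((4, 1, 3))
        far = [5.0, 0, 0]
        near = [0.2, 0, 0]
        lig = np.array([
            [near, near, far],
            [near, far, far],
            [near, near, near],
            [far, far, near],
        ])
        traj, idx = contact_traj(lig, pep)
        ids, counts = simultaneous_contact_matrix(
            ligand_contacts(traj, idx, cutoff=3.0))
        expect = np.array([[3, 2, 1],
                           [2, 2, 1],
                           [1, 1, 2]])
        assert np.array_equal(counts, expect)
        assert np.array_equal(counts, counts.T)


class TestInterLigandDistances:
    def test_rigid_cluster_constant(self):
        pep = np.zeros((5, 1, 3))
        lig = np.tile(np.array([[0.0, 0, 0], [0.5, 0, 0], [0, 0.5, 0]]),
                      (5, 1, 1))
        traj, idx = contact_traj(lig, pep)
        out = inter_ligand_distances(traj, [1, 2, 3], idx)
        assert np.allclose(out["series"].std(axis=1), 0.0)

    def test_known_geometry(self):
        pep = np.zeros((2, 1, 3))
        lig = np.tile(np.array([[0.0, 0, 0], [0.3, 0.4, 0]]), (2, 1, 1))
        traj, idx = contact_traj(lig, pep)
        out = inter_ligand_distances(traj, [1, 2], idx)
        assert out["mean"][0] == pytest.approx(5.0)  # 3-4-5 triangle, A
        assert out["pooled_mean"] == pytest.approx(5.0)

    def test_unknown_id(self):
        pep = np.zeros((2, 1, 3))
        lig = np.zeros((2, 2, 3))
        traj, idx = contact_traj(lig, pep)
        with pytest.raises(PepmpcError):
            inter_ligand_distances(traj, [1, 99], idx)


class TestPairCorrelation:
    def test_ideal_gas(self, rng):
        box = 5.0
        n_frames, n_a, n_b = 30, 40, 40
        coords = rng.uniform(0, box, size=(n_frames, n_a + n_b, 3))
        traj = Trajectory(times=np.arange(n_frames, dtype=float),
                          coords=coords, box_length=box)
        rdf = pair_correlation(traj, np.arange(n_a),
                               np.arange(n_a, n_a + n_b),
                               r_max=20.0, shell_width=2.0)
        assert np.all(rdf.g >= 0)
        assert np.abs(rdf.g[2:] - 1.0).mean() < 0.1

    def test_hard_exclusion(self, rng):
        box = 6.0
        pts = rng.uniform(0, box, size=(10, 3))
        # second set displaced by >= 4 A from every first-set point
        other = pts + 0.45
        coords = np.concatenate([pts, other])[None, ...]
        traj = Trajectory(times=[0.0], coords=coords, box_length=box)
        rdf = pair_correlation(traj, np.arange(10), np.arange(10, 20),
                               r_max=25.0, shell_width=1.0)
        assert np.all(rdf.g[:4] == 0.0)

    def test_single_pair_spike_hand_normalized(self):
        box = 10.0
        coords = np.array([[[0.0, 0, 0], [0.5, 0, 0]]])  # 5 A apart
        traj = Trajectory(times=[0.0], coords=coords, box_length=box)
        rdf = pair_correlation(traj, [0], [1], r_max=10.0,
                               shell_width=1.0)
        shell = int(5.0 // 1.0)  # histogram bin [5, 6) holds r = 5 A
        expect = np.zeros_like(rdf.g)
        box_A = 100.0
        shell_vol = 4 / 3 * math.pi * (6.0**3 - 5.0**3)
        expect[shell] = 1.0 / (1.0 / box_A**3 * shell_vol)
        assert np.allclose(rdf.g, expect)

    def test_r_max_violation(self):
        traj = Trajectory(times=[0.0], coords=np.zeros((1, 2, 3)),
                          box_length=4.0)
        with pytest.raises(PepmpcError):
            pair_correlation(traj, [0], [1], r_max=25.0, shell_width=1.0)


class TestHbonds:
    # coordinates in nm; cutoffs in A
    def test_linear_bond_counted(self):
        coords = np.array([[0.0, 0, 0],      # donor
                           [0.1, 0, 0],      # hydrogen
                           [0.28, 0, 0]])    # acceptor at 2.8 A
        assert hbond_count(coords, [(0, 1)], [2]) == 1

    def test_far_pair_not_counted(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.5, 0, 0]])
        assert hbond_count(coords, [(0, 1)], [2]) == 0

    def test_right_angle_not_counted(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.1, 0.26, 0]])
        # D...A distance 2.8 A but D-H...A angle is 90 deg
        assert math.dist(coords[0], coords[2]) == pytest.approx(
            0.28, abs=0.01)
        assert hbond_count(coords, [(0, 1)], [2]) == 0

    def test_missing_hydrogen(self):
        with pytest.raises(PepmpcError):
            hbond_count(np.zeros((2, 3)), [(0, None)], [1])


class TestRmsd:
    def test_identical(self, rng):
        x = rng.normal(size=(10, 3))
        assert rmsd(x, x) == 0.0

    def test_rigid_rotation_superposed(self, rng):
        from scipy.spatial.transform import Rotation
        x = rng.normal(size=(10, 3))
        y = Rotation.random(rng=rng).apply(x) + [1.0, -2.0, 0.5]
        assert rmsd(x, y, superpose=True) == pytest.approx(0.0, abs=1e-6)
        assert rmsd(x, y, superpose=False) > 0.1

    def test_quaternion_oracle(self, rng):
        # independent quaternion-eigenvalue method for optimal RMSD
        for _ in range(5):
            A = rng.normal(size=(12, 3))
            B = rng.normal(size=(12, 3))
            got = rmsd(A, B, superpose=True)
            assert got == pytest.approx(_quaternion_rmsd(A, B), abs=1e-9)

    def test_mismatched(self):
        with pytest.raises(PepmpcError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def _quaternion_rmsd(A, B):
    """Horn's closed-form quaternion method (oracle)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx, Sxy, Sxz = (A[:, 0] * B[:, 0]).sum(), (A[:, 0] * B[:, 1]).sum(), \
        (A[:, 0] * B[:, 2]).sum()
    Syx, Syy, Syz = (A[:, 1] * B[:, 0]).sum(), (A[:, 1] * B[:, 1]).sum(), \
        (A[:, 1] * B[:, 2]).sum()
    Szx, Szy, Szz = (A[:, 2] * B[:, 0]).sum(), (A[:, 2] * B[:, 1]).sum(), \
        (A[:, 2] * B[:, 2]).sum()
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    e0 = (A**2).sum() + (B**2).sum()
    msd_val = max(0.0, (e0 - 2 * lam) / A.shape[0])
    return math.sqrt(msd_val)


class TestGromosCluster:
    def test_identical_frames(self):
        frames = np.ones((7, 4, 3))
        out = gromos_cluster(frames, cutoff=0.1)
        assert out.sizes == [7]
        assert np.all(out.membership == 0)

    def test_two_generator_families(self, h3_peptide):
        from pepmpc.synthetic_data import (
            GeneratorSpec, gen_conformer_chain)
        spec = GeneratorSpec(kind="conformer_chain", dt=1.0,
                             n_frames=300, seed=7, noise_sigma=0.2,
                             switch_rate_fwd=50.0, switch_rate_rev=50.0)
        traj, truth = gen_conformer_chain(spec, h3_peptide)
        out = gromos_cluster(traj.coords, cutoff=0.15)
        n0 = int((truth.conformer_labels == 0).sum())
        n1 = int((truth.conformer_labels == 1).sum())
        top_two = sorted(out.sizes, reverse=True)[:2]
        assert sorted(top_two) == sorted([n0, n1])

    def test_cluster_count_monotone_in_cutoff(self, rng):
        frames = rng.normal(size=(40, 5, 3))
        counts = [gromos_cluster(frames, cutoff=c).n_clusters
                  for c in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_permutation_invariant_sizes(self, rng):
        # shuffling frame order must not change the size spectrum
        # (memberships may differ only at documented representative ties)
        frames = np.repeat(rng.normal(size=(6, 4, 3)), 5, axis=0)
        perm = rng.permutation(len(frames))
        a = gromos_cluster(frames, cutoff=0.5)
        b = gromos_cluster(frames[perm], cutoff=0.5)
        assert sorted(a.sizes) == sorted(b.sizes)

    def test_sizes_sum_to_frames(self, rng):
        frames = rng.normal(size=(30, 4, 3))
        out = gromos_cluster(frames, cutoff=1.0)
        assert sum(out.sizes) == 30

    def test_invalid_cutoff(self):
        with pytest.raises(PepmpcError):
            gromos_cluster(np.zeros((2, 2, 3)), cutoff=0.0)


class TestNativeContacts:
    def test_extended_chain_empty_map(self):
        pep = build_peptide("HHHWDDD", "extended")
        ca = pep.coords(0)[pep.backbone_indices()]
        out = native_contact_map(ca, ca[None, ...], cutoff=6.5, seq_sep=3)
        # minimum |i-j| >= 3 distance is 3 * 3.8 = 11.4 A > 6.5 A
        assert out.pairs == []

    def test_horseshoe_terminal_contact(self, h3_peptide):
        ca = h3_peptide.coords(1)[h3_peptide.backbone_indices()]
        out = native_contact_map(ca, ca[None, ...], cutoff=6.5, seq_sep=3)
        assert (1, 6) in out.pairs or (2, 7) in out.pairs
        assert out.q[0] == 1.0

    def test_q_reference_is_one(self, rng):
        ref = rng.normal(scale=0.3, size=(8, 3))
        out = native_contact_map(ref, ref[None, ...])
        if out.pairs:
            assert out.q[0] == 1.0

    def test_invalid_seq_sep(self):
        with pytest.raises(PepmpcError):
            native_contact_map(np.zeros((4, 3)), np.zeros((1, 4, 3)),
                               seq_sep=0)
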