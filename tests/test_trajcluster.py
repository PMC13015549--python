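"""Restraint energy, PCA embedding and clustering behaviour."""

import warnings

import numpy as np
import pytest

from metamorphscan.structures import RegionSpec
from metamorphscan.synthetic import (
    build_ideal_helix,
    simulate_transition_trajectory,
)
from metamorphscan.trajcluster import (
    ClusterAssignment,
    TMDParams,
    Trajectory,
    build_pca_map,
    cluster_structures_by_rmsd,
    frame_rmsd,
    kmeans_cluster,
    project,
    project_all,
    select_representative_trajectories,
    tmd_energy,
    trajectory_from_structures,
)

FIT = RegionSpec(1, 12)
ANA = RegionSpec(13, 30)


def _traj(seed, noise=0.0, n_frames=15, traj_id="t"):
    a = build_ideal_helix(30, seed=101)
    b = build_ideal_helix(30, seed=102)
    return simulate_transition_trajectory(
        a, b, n_frames=n_frames, noise_sd=noise, seed=seed, traj_id=traj_id
    )


def _traj_fixed_ntd(n_frames=11, traj_id="fixed"):
    """Interpolation whose fit-region atoms never move, so the frame
    alignment is the identity and the embedding is exactly linear."""
    from metamorphscan.synthetic import structure_atoms_flat

    a = build_ideal_helix(30, seed=103)
    c0, resi, names = structure_atoms_flat(a)
    c1 = c0.copy()
    c1[resi >= ANA.start] += np.array([3.0, 1.0, -2.0])
    ts = np.linspace(0.0, 1.0, n_frames)
    frames = np.array([(1 - t) * c0 + t * c1 for t in ts])
    return Trajectory(
        frames=frames, atom_residues=resi, atom_names=names, traj_id=traj_id
    )


class TestTmdEnergy:
    def test_zero_at_target(self):
        assert tmd_energy(3.0, TMDParams(k=0.01, n_atoms=252, rmsd_target=3.0)) == 0.0

    def test_worked_example(self):
        # ½ · 0.01 · 252 · (5 − 0)² = 31.5 kcal/mol
        assert tmd_energy(5.0, TMDParams(k=0.01, n_atoms=252)) == pytest.approx(31.5)

    def test_quadratic_identities(self):
        p = TMDParams(k=0.37, n_atoms=52, rmsd_target=2.0)
        e1 = tmd_energy(3.0, p)  # displacement 1
        e2 = tmd_energy(4.0, p)  # displacement 2
        assert e2 == pytest.approx(4 * e1)
        assert tmd_energy(1.0, p) == pytest.approx(e1)  # symmetric in sign
        assert e1 > 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TMDParams(k=0.0, n_atoms=10)
        with pytest.raises(ValueError):
            tmd_energy(-1.0, TMDParams(k=1.0, n_atoms=1))


class TestPcaMap:
    def test_noiseless_interpolation_is_rank_one(self):
        m = build_pca_map([_traj(0)], FIT, ANA)
        assert m.eigenvalues[0] / m.total_variance >= 0.999

    def test_noisy_interpolation_pc1_dominant(self):
        m = build_pca_map([_traj(1, noise=0.1, n_frames=50)], FIT, ANA)
        assert m.eigenvalues[0] / m.total_variance >= 0.95

    def test_identical_frames_degenerate(self):
        t = _traj(0)
        t_const = Trajectory(
            frames=np.repeat(t.frames[:1], 4, axis=0),
            atom_residues=t.atom_residues,
            atom_names=t.atom_names,
        )
        with pytest.warns(RuntimeWarning, match="degenerate"):
            m = build_pca_map([t_const], FIT, ANA)
        assert m.total_variance == pytest.approx(0.0, abs=1e-12)

    def test_variance_conservation(self):
        t = _traj(2, noise=0.2)
        m = build_pca_map([t], FIT, ANA)
        full = project(t, m, n_components=len(m.eigenvalues))
        assert np.var(full, axis=0, ddof=1).sum() == pytest.approx(
            m.total_variance, rel=1e-8
        )

    def test_basis_orthonormal(self):
        m = build_pca_map([_traj(3, noise=0.3)], FIT, ANA)
        G = m.eigenvectors @ m.eigenvectors.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)


class TestProject:
    def test_round_trip_with_full_basis(self):
        t = _traj(4, noise=0.2)
        m = build_pca_map([t], FIT, ANA)
        z = project(t, m, n_components=len(m.eigenvalues))
        recon = z @ m.eigenvectors + m.mean
        from metamorphscan.trajcluster import _aligned_region_frames

        X, _, _ = _aligned_region_frames([t], FIT, ANA, ref_fit=m.ref_fit_coords)
        assert np.allclose(recon, X, atol=1e-6)

    def test_mean_frame_projects_to_origin(self):
        t = _traj(5)
        m = build_pca_map([t], FIT, ANA)
        z = project(t, m)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-8)

    def test_mirror_frames_project_oppositely(self):
        t = _traj_fixed_ntd()
        m = build_pca_map([t], FIT, ANA)
        z = project(t, m)
        # frames interpolate linearly with a fixed fit region, so first and
        # last frames are mirror images about the mean in PCA space
        assert np.allclose(z[0], -z[-1], atol=1e-6)

    def test_atom_mismatch_rejected(self):
        t = _traj(7)
        m = build_pca_map([t], FIT, ANA)
        # a trajectory over a shorter residue range exposes fewer Cα
        short = simulate_transition_trajectory(
            build_ideal_helix(25, seed=1),
            build_ideal_helix(25, seed=2),
            n_frames=5,
        )
        with pytest.raises(ValueError):
            project(short, m)


class TestKmeans:
    def test_k_equals_n_points(self, rng):
        pts = rng.normal(size=(6, 2)) * 10
        asg = kmeans_cluster(pts, 6, seed=0)
        assert len(set(asg.labels.tolist())) == 6
        inertia = sum(
            np.sum((pts[i] - asg.centers[asg.labels[i]]) ** 2) for i in range(6)
        )
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_planted_blobs_recovered(self, rng):
        a = rng.normal(scale=0.1, size=(40, 2))
        b = rng.normal(scale=0.1, size=(40, 2)) + np.array([10.0, 0.0])
        pts = np.vstack([a, b])
        asg = kmeans_cluster(pts, 2, seed=1)
        assert len(set(asg.labels[:40].tolist())) == 1
        assert len(set(asg.labels[40:].tolist())) == 1
        assert asg.labels[0] != asg.labels[-1]

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(50, 2))
        l1 = kmeans_cluster(pts, 5, seed=7).labels
        l2 = kmeans_cluster(pts, 5, seed=7).labels
        assert np.array_equal(l1, l2)

    def test_lloyd_fixed_point(self, rng):
        """Every point sits closest to its own center (local optimum)."""
        pts = rng.normal(size=(60, 2)) * 3
        asg = kmeans_cluster(pts, 4, seed=0)
        d = np.linalg.norm(pts[:, None, :] - asg.centers[None, :, :], axis=2)
        assert np.array_equal(np.argmin(d, axis=1), asg.labels)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(3, 2)), 5, seed=0)


class TestRepresentatives:
    def test_single_trajectory_any_k(self):
        t = _traj(8, noise=0.05, n_frames=20, traj_id="only")
        m = build_pca_map([t], FIT, ANA)
        pts, ids = project_all([t], m)
        asg = kmeans_cluster(pts, 5, seed=0)
        assert select_representative_trajectories(pts, ids, asg) == ["only"]

    def test_disjoint_half_planes(self):
        pts = np.array([[x, 0.0] for x in (-5, -4, -4.5)] + [[x, 0.0] for x in (4, 5, 4.5)])
        ids = ["left"] * 3 + ["right"] * 3
        asg = kmeans_cluster(pts, 2, seed=0)
        assert sorted(select_representative_trajectories(pts, ids, asg)) == [
            "left",
            "right",
        ]

    def test_cardinality_bounded_by_k(self, rng):
        """Selecting representatives from many trajectories with k clusters
        yields at most k (and at most n_traj) trajectories."""
        pts = rng.normal(size=(600, 2)) * 5
        ids = [f"t{i // 10}" for i in range(600)]  # 60 trajectories
        asg = kmeans_cluster(pts, 100, seed=0)
        reps = select_representative_trajectories(pts, ids, asg)
        assert len(reps) <= 100
        assert len(reps) <= 60
        assert set(reps) <= set(ids)

    def test_representative_frame_belongs_to_cluster(self, rng):
        pts = rng.normal(size=(80, 2))
        ids = [f"t{i % 8}" for i in range(80)]
        asg = kmeans_cluster(pts, 6, seed=2)
        select_representative_trajectories(pts, ids, asg)
        for cluster, frame in asg.representative.items():
            assert asg.labels[frame] == cluster


class TestRmsdClustering:
    def test_two_reference_copies(self):
        alpha = build_ideal_helix(25, seed=31)
        beta = build_ideal_helix(25, seed=32)
        structures = [alpha] * 5 + [beta] * 5
        asg = cluster_structures_by_rmsd(
            structures, alpha, beta, RegionSpec(3, 24), k=2, seed=0
        )
        assert len(set(asg.labels[:5].tolist())) == 1
        assert len(set(asg.labels[5:].tolist())) == 1
        for cluster, medoid in asg.representative.items():
            assert asg.labels[medoid] == cluster

    def test_singleton_medoid_is_only_member(self):
        alpha = build_ideal_helix(25, seed=31)
        beta = build_ideal_helix(25, seed=32)
        structures = [alpha, alpha, beta]
        asg = cluster_structures_by_rmsd(
            structures, alpha, beta, RegionSpec(3, 24), k=2, seed=0
        )
        for cluster, medoid in asg.representative.items():
            members = asg.members(cluster)
            assert medoid in members
            if len(members) == 1:
                assert medoid == members[0]

    def test_three_conformation_groups_recovered(self):
        s1 = build_ideal_helix(25, seed=41)
        s2 = build_ideal_helix(25, seed=42)
        s3 = build_ideal_helix(25, seed=43)
        structures = [s1] * 4 + [s2] * 4 + [s3] * 4
        asg = cluster_structures_by_rmsd(
            structures, s1, s2, RegionSpec(3, 24), k=3, seed=0
        )
        groups = [set(asg.labels[i : i + 4].tolist()) for i in (0, 4, 8)]
        assert all(len(g) == 1 for g in groups)
        assert len({g.pop() for g in groups}) == 3


class TestTrajectoryIO:
    def test_from_structures_round_trip(self):
        a = build_ideal_helix(10, seed=51)
        b = build_ideal_helix(10, seed=52)
        traj = trajectory_from_structures([a, b], traj_id="x")
        assert traj.n_frames == 2
        from metamorphscan.synthetic import structure_atoms_flat

        ca, _, _ = structure_atoms_flat(a)
        assert np.allclose(traj.frames[0], ca)

    def test_layout_mismatch_rejected(self):
        a = build_ideal_helix(10, seed=51)
        b = build_ideal_helix(11, seed=52)
        with pytest.raises(ValueError):
            trajectory_from_structures([a, b])

    def test_frame_rmsd_monotone_on_noiseless_interpolation(self):
        # non-rigid interpolation: only part of the structure moves
        t = _traj_fixed_ntd(n_frames=10)
        target = t.frames[-1]
        r = frame_rmsd(t, target)
        assert np.all(np.diff(r) <= 1e-9)
        assert r[-1] == pytest.approx(0.0, abs=1e-9)
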