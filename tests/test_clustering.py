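"""Superposition, ligand COM extraction, and DBSCAN against two oracles
(a brute-force re-implementation and scikit-learn's DBSCAN)."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tndyn.clustering import (
    align_trajectory,
    cluster_summary,
    dbscan_cluster,
    ligand_centers,
    medoid_frame,
)
from tndyn.core import Trajectory
from tndyn.synthetic import GeneratorSpec, make_condition_fixture, simulate_hinge_trajectory

from conftest import rigid_motion


def brute_force_dbscan(points, eps, min_points):
    """Independent O(n^2) DBSCAN with the same determinism conventions:
    min_points counts the point itself, ascending-index processing, border
    points to the first claiming cluster, labels by descending size."""
    D = cdist(points, points)
    neighbors = [np.flatnonzero(row <= eps) for row in D]
    core = np.array([len(nb) >= min_points for nb in neighbors])
    labels = np.full(len(points), -1, dtype=int)
    cid = 0
    for i in range(len(points)):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    sizes = np.bincount(labels[labels >= 0], minlength=cid)
    first = [int(np.argmax(labels == c)) for c in range(cid)]
    order = sorted(range(cid), key=lambda c: (-sizes[c], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] if l >= 0 else -1 for l in labels])


def _blobs(rng, centers, sizes, sigma=2.0):
    pts = np.concatenate(
        [c + sigma * rng.standard_normal((n, 3)) for c, n in zip(np.atleast_2d(centers), sizes)]
    )
    return rng.permutation(pts)


class TestAlign:
    def test_rigid_copies_align_to_reference(self, toy_model):
        """Frames that are rigid copies of frame 0 superpose to ~0 RMSD."""
        # sigma ~ 0 and occupancy target 1.0: every frame is a rigid copy
        spec = GeneratorSpec(seed=51, n_frames=20, hinge_sigma=1e-9, bond_occupancy_target=1.0)
        traj, _, _ = simulate_hinge_trajectory(spec, toy_model)
        aligned = align_trajectory(traj, reference_frame=0)
        ref = aligned.coordinates[0]
        for f in range(traj.n_frames):
            rmsd = np.sqrt(((aligned.coordinates[f] - ref) ** 2).sum(axis=1).mean())
            assert rmsd < 1e-6

    def test_idempotent_on_aligned_trajectory(self, toy_model):
        spec = GeneratorSpec(seed=52, n_frames=10)
        traj, _, _ = simulate_hinge_trajectory(spec, toy_model)
        once = align_trajectory(traj)
        twice = align_trajectory(once)
        np.testing.assert_allclose(twice.coordinates, once.coordinates, atol=1e-9)

    def test_ligand_com_recovers_body_frame_truth(self, toy_model):
        """With no internal motion, alignment undoes the per-frame global
        motion and ligand COMs equal the generator's body-frame draws."""
        spec = GeneratorSpec(seed=53, n_frames=30, hinge_sigma=1e-9)
        traj, truths, model = make_condition_fixture(spec, toy_model)
        aligned = align_trajectory(traj, reference_frame=0)
        poses = ligand_centers(aligned)
        # frame 0 retains its own global motion; map truth through it
        R0 = truths["hinge"].global_rotations[0]
        t0 = truths["hinge"].global_translations[0]
        expected = truths["poses"].body_coms @ R0.T + t0
        np.testing.assert_allclose(poses.points, expected, atol=1e-6)

    def test_medoid_frame_matches_exhaustive_scan(self, toy_model):
        spec = GeneratorSpec(seed=54, n_frames=12)
        traj, _, _ = simulate_hinge_trajectory(spec, toy_model)
        from tndyn.core import protein_calpha, resolve_selection
        from tndyn.geometry import kabsch_fit

        idx = resolve_selection(traj.topology, protein_calpha())
        totals = []
        for a in range(traj.n_frames):
            tot = 0.0
            for b in range(traj.n_frames):
                if a != b:
                    tot += kabsch_fit(traj.coordinates[b][idx], traj.coordinates[a][idx]).rmsd
            totals.append(tot)
        assert medoid_frame(traj) == int(np.argmin(totals))


class TestLigandCenters:
    def test_equal_mass_midpoint(self):
        from tndyn.core import Atom, Topology

        topo = Topology(
            atoms=(
                Atom(1, "C1", "C", 1, "LIG", "L", 12.0),
                Atom(2, "C2", "C", 1, "LIG", "L", 12.0),
            ),
            chain_roles={"L": "ligand"},
        )
        traj = Trajectory(topology=topo, coordinates=np.array([[[0.0, 0, 0], [2.0, 0, 0]]]))
        np.testing.assert_allclose(ligand_centers(traj).points, [[1.0, 0.0, 0.0]])

    def test_unequal_masses_weighted_mean(self):
        from tndyn.core import Atom, Topology

        topo = Topology(
            atoms=(
                Atom(1, "C1", "C", 1, "LIG", "L", 12.0),
                Atom(2, "H1", "H", 1, "LIG", "L", 1.0),
            ),
            chain_roles={"L": "ligand"},
        )
        traj = Trajectory(topology=topo, coordinates=np.array([[[0.0, 0, 0], [2.0, 0, 0]]]))
        np.testing.assert_allclose(ligand_centers(traj).points, [[2.0 / 13.0, 0.0, 0.0]])

    def test_matches_direct_mass_weighted_sum(self, toy_model):
        spec = GeneratorSpec(seed=55, n_frames=15)
        traj, _, model = make_condition_fixture(spec, toy_model)
        poses = ligand_centers(traj)
        rows, m = model.rows_ligand, model.ligand_masses
        for f in range(traj.n_frames):
            direct = (traj.coordinates[f][rows] * m[:, None]).sum(axis=0) / m.sum()
            np.testing.assert_allclose(poses.points[f], direct, atol=1e-12)


class TestDBSCAN:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        pts = _blobs(rng, [[0, 0, 0], [60.0, 0, 0]], [100, 100])
        res = dbscan_cluster(pts, eps=10.0, min_points=2)
        assert len(res.occupancy) == 2
        assert res.occupancy[0] == res.occupancy[1] == pytest.approx(0.5)
        assert res.noise_fraction == 0.0

    def test_all_points_identical(self):
        res = dbscan_cluster(np.zeros((50, 3)), eps=1.0, min_points=5)
        assert res.occupancy == {0: 1.0}

    def test_matches_brute_force_and_sklearn(self):
        """Dual oracle on a 3-component mixture: exact label agreement with
        the brute-force implementation and partition agreement with
        scikit-learn's DBSCAN, at eps 5/10/20."""
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(1)
        pts = _blobs(rng, [[45, 0, 0], [-45, 0, 0], [0, 45, 0]], [900, 70, 30])
        for eps in (5.0, 10.0, 20.0):
            res = dbscan_cluster(pts, eps=eps, min_points=10)
            brute = brute_force_dbscan(pts, eps, 10)
            np.testing.assert_array_equal(res.labels, brute)
            sk = DBSCAN(eps=eps, min_samples=10).fit_predict(pts)
            # same partition: noise agrees and cluster maps are 1-1
            np.testing.assert_array_equal(res.labels == -1, sk == -1)
            pairs = {(a, b) for a, b in zip(res.labels, sk) if a >= 0}
            assert len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})

    def test_mixture_occupancy_recovery(self):
        rng = np.random.default_rng(2)
        n = 2000
        sizes = [int(0.90 * n), int(0.07 * n), int(0.03 * n)]
        pts = _blobs(rng, [[45, 0, 0], [-45, 0, 0], [0, 45, 0]], sizes)
        res = dbscan_cluster(pts, eps=10.0, min_points=int(0.01 * n))
        occ = sorted(res.occupancy.values(), reverse=True)
        np.testing.assert_allclose(occ, [0.90, 0.07, 0.03], atol=0.02)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        pts = _blobs(rng, [[45, 0, 0], [-45, 0, 0]], [150, 50])
        base = dbscan_cluster(pts, eps=10.0, min_points=5)
        for seed in range(3):
            R, t = rigid_motion(np.random.default_rng(seed))
            moved = dbscan_cluster(pts @ R.T + t, eps=10.0, min_points=5)
            np.testing.assert_array_equal(moved.labels, base.labels)

    def test_occupancies_and_noise_sum_to_one(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([_blobs(rng, [[0, 0, 0]], [80]), rng.uniform(-200, 200, (40, 3))])
        res = dbscan_cluster(pts, eps=8.0, min_points=10)
        assert sum(res.occupancy.values()) + res.noise_fraction == pytest.approx(1.0, abs=1e-12)
        for c, f in res.occupancy.items():
            assert f * len(pts) >= res.min_points  # clusters respect min size

    def test_empty_pose_set_rejected(self):
        with pytest.raises(ValueError):
            dbscan_cluster(np.empty((0, 3)), eps=1.0)


class TestClusterSummary:
    def test_single_cluster_medoid_verified_exhaustively(self):
        rng = np.random.default_rng(5)
        pts = _blobs(rng, [[0, 0, 0]], [60])
        res = dbscan_cluster(pts, eps=10.0, min_points=5)
        table = cluster_summary(res)
        assert table["occupancy_pct"].iloc[0] == pytest.approx(100.0)
        center = pts.mean(axis=0)
        expected = int(np.argmin(np.linalg.norm(pts - center, axis=1)))
        assert table["representative_frame"].iloc[0] == expected

    def test_noise_only_result(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-500, 500, (30, 3))
        res = dbscan_cluster(pts, eps=1.0, min_points=5)
        assert res.noise_fraction == 1.0
        assert cluster_summary(res).empty

    def test_two_cluster_representatives_are_constructed_medoids(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])  # medoid: index 1
        b = np.array([[60.0, 0, 0], [61.0, 0, 0], [62.0, 0, 0], [63.0, 0, 0]])
        pts = np.concatenate([a, b])
        res = dbscan_cluster(pts, eps=5.0, min_points=2)
        # cluster 0 = larger blob (b); its mean is 61.5, nearest members 61/62, tie -> lower frame
        assert res.representative_frame[0] == 4
        assert res.representative_frame[1] == 1
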