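"""Pose pooling, RMSD matrix, clustering, Kelley selection, medoids."""

import itertools

import numpy as np
import pytest

from cardkit import synth
from cardkit.structures import write_structure, Trajectory
from cardkit.consensus import (pool_poses, harmonize, pairwise_pose_rmsd,
                               hierarchical_cluster, cluster_labels,
                               kelley_select, representatives,
                               cluster_ensemble, _avg_within_spread,
                               DegenerateClusteringError)
from cardkit.geometry import rmsd, RigidTransform
from scipy.spatial.transform import Rotation


@pytest.fixture(scope="module")
def small_ensemble():
    dimer = synth.build_dimer(synth.DimerSpec(contacts=synth.default_contacts(2),
                                              chain_a_length=10, chain_b_length=10))
    poses, engines, labels = synth.build_pose_ensemble(
        dimer, synth.PoseEnsembleSpec(n_clusters=3, poses_per_cluster=4, seed=5))
    return harmonize(poses, engines), np.asarray(labels)


class TestPooling:
    def test_cap_per_engine(self, mixed_dimer, tmp_path):
        poses, engines, _ = synth.build_pose_ensemble(
            mixed_dimer, synth.PoseEnsembleSpec(n_clusters=2, poses_per_cluster=4,
                                                seed=0))
        path = tmp_path / "engine.pdb"
        write_structure(Trajectory(frames=poses[:7]), path)
        ens = pool_poses([path, path], ["e1", "e2"], cap_per_engine=3)
        assert len(ens) == 6
        assert ens.source_engine == ["e1"] * 3 + ["e2"] * 3

    def test_harmonization_drops_mismatched_atoms_ensemble_wide(self, mixed_dimer):
        poses, engines, _ = synth.build_pose_ensemble(
            mixed_dimer, synth.PoseEnsembleSpec(n_clusters=2, poses_per_cluster=2,
                                                seed=0))
        # remove one residue's atoms from a single pose
        victim = poses[1]
        drop_key = victim.residue_key(0)
        keep = np.array([victim.residue_key(i) != drop_key
                         for i in range(len(victim))])
        poses[1] = victim.subset(keep)
        ens = harmonize(poses, engines)
        ids = set(ens.poses[0].identity_tuples())
        assert all(set(p.identity_tuples()) == ids for p in ens.poses)
        assert not any(k[1] == drop_key.res_seq and k[0] == drop_key.chain_id
                       for k in ids)


class TestRmsdMatrix:
    def test_duplicate_and_rigid_copy_are_zero(self, small_ensemble, rng):
        ens, _ = small_ensemble
        d = pairwise_pose_rmsd(ens)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        pose = ens.poses[0]
        R = Rotation.random(rng=rng).as_matrix()
        moved = pose.with_coords(RigidTransform(R, [4, 5, 6]).apply(pose.coords))
        assert rmsd(moved.coords, pose.coords, superpose=True) < 1e-6

    def test_matrix_matches_per_pair_kabsch(self, small_ensemble):
        ens, _ = small_ensemble
        d = pairwise_pose_rmsd(ens)
        for i, j in [(0, 5), (2, 9), (4, 11)]:
            assert d[i, j] == pytest.approx(
                rmsd(ens.poses[i].coords, ens.poses[j].coords), abs=1e-10)


class TestHierarchy:
    def test_closest_pair_merges_first(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
        tree = hierarchical_cluster(d)
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_two_points_single_merge(self):
        tree = hierarchical_cluster(np.array([[0, 2.0], [2.0, 0]]))
        assert tree.shape == (1, 4)

    def test_average_linkage_matches_exhaustive_agglomeration(self, rng):
        """Merge heights equal a brute-force average-linkage agglomeration."""
        n = 8
        pts = rng.normal(size=(n, 2)) * 5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = hierarchical_cluster(d, "average")

        # brute force: repeatedly merge the pair of clusters with minimal
        # average inter-cluster distance
        clusters = {i: [i] for i in range(n)}
        heights = []
        next_key = n
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(sorted(clusters), 2):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or avg < best[0] - 1e-12:
                    best = (avg, a, b)
            avg, a, b = best
            heights.append(avg)
            clusters[next_key] = clusters.pop(a) + clusters.pop(b)
            next_key += 1
        assert np.allclose(sorted(tree[:, 2]), sorted(heights), atol=1e-8)


class TestKelley:
    def test_two_identical_pairs_far_apart_select_k2(self):
        d = np.array([
            [0, 0.1, 20, 20],
            [0.1, 0, 20, 20],
            [20, 20, 0, 0.1],
            [20, 20, 0.1, 0.0]])
        tree = hierarchical_cluster(d)
        k, penalties, _ = kelley_select(tree, d)
        assert k == 2

    def test_penalty_matches_brute_force_partition_evaluation(self, rng):
        n = 10
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = hierarchical_cluster(d)
        k_sel, penalties, labels_by_k = kelley_select(tree, d)

        # recompute penalties independently from the flat partitions
        spreads = {}
        for k, labels in labels_by_k.items():
            per_cluster = []
            for c in set(labels):
                members = [i for i in range(n) if labels[i] == c]
                if len(members) < 2:
                    continue
                ds = [d[i, j] for i, j in itertools.combinations(members, 2)]
                per_cluster.append(np.mean(ds))
            if per_cluster:
                spreads[k] = np.mean(per_cluster)
        lo, hi = min(spreads.values()), max(spreads.values())
        for k, s in spreads.items():
            norm = 1.0 if hi == lo else 1 + (s - lo) * (n - 2) / (hi - lo)
            assert penalties[k] == pytest.approx(norm + k, abs=1e-10)

    def test_planted_clusters_recovered(self, small_ensemble):
        ens, truth = small_ensemble
        res = cluster_ensemble(ens)
        assert res.selected_k == 3
        # partition matches truth up to relabeling
        mapping = {}
        for found, true in zip(res.labels, truth):
            mapping.setdefault(found, true)
            assert mapping[found] == true

    def test_all_singletons_degenerate(self):
        d = np.array([[0, 5.0], [5.0, 0]])
        tree = hierarchical_cluster(d)
        # only k=2 available -> both singletons -> degenerate
        with pytest.raises(DegenerateClusteringError):
            kelley_select(tree, d, k_range=[2])


class TestRepresentatives:
    def test_singleton_is_its_own_representative(self):
        d = np.array([[0, 1.0, 9], [1.0, 0, 9], [9, 9, 0.0]])
        reps, top = representatives(np.array([1, 1, 2]), d)
        assert reps[2] == 2
        assert top == reps[1]  # larger cluster wins

    def test_matches_brute_force_medoid(self, small_ensemble, rng):
        ens, _ = small_ensemble
        d = pairwise_pose_rmsd(ens)
        labels = rng.integers(1, 4, size=len(ens))
        reps, _ = representatives(labels, d)
        for c, rep in reps.items():
            members = np.flatnonzero(labels == c)
            means = {int(i): d[i, members].mean() for i in members}
            assert means[rep] == pytest.approx(min(means.values()))

    def test_size_tie_goes_to_lowest_pose_index(self):
        d = np.zeros((4, 4))
        reps, top = representatives(np.array([2, 2, 1, 1]), d)
        assert top == 0  # cluster containing pose 0 wins the tie

    def test_input_order_invariance_up_to_tiebreak(self, small_ensemble):
        ens, _ = small_ensemble
        res1 = cluster_ensemble(ens)
        perm = np.arange(len(ens))[::-1]
        from cardkit.consensus import PoseEnsemble
        rev = PoseEnsemble(poses=[ens.poses[i] for i in perm],
                           source_engine=[ens.source_engine[i] for i in perm])
        res2 = cluster_ensemble(rev)
        assert res2.selected_k == res1.selected_k
        # same partition under the permutation
        part1 = {frozenset(np.flatnonzero(res1.labels == c))
                 for c in np.unique(res1.labels)}
        part2 = {frozenset(perm[np.flatnonzero(res2.labels == c)])
                 for c in np.unique(res2.labels)}
        assert part1 == part2
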