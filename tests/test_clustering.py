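import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from phasemark.clustering import (
    PhaseLabelMatrix,
    derive_seed,
    per_phase_clustering,
    prune_empty_clusters,
    second_stage_som,
    super_cluster,
    two_stage_cluster,
)
from phasemark.datatypes import ExpressionMatrix, PhaseTensor
from phasemark.som import SOMTrainParams, init_grid, train_som
from phasemark.synthetic import generate_case_cohort


def _tensor_from_arrays(arrays, ids=None):
    n, p = arrays[0].shape
    ids = ids or [f"s{i:02d}" for i in range(n)]
    probes = [f"g{j}" for j in range(p)]
    return PhaseTensor(
        tuple(ExpressionMatrix(ids, probes, a.copy()) for a in arrays)
    )


def _two_group_tensor(seed=0, sep=8.0):
    rng = np.random.default_rng(seed)
    arrays = []
    for _ in range(3):
        a = rng.normal(0.0, 1.0, size=(10, 6))
        b = rng.normal(0.0, 1.0, size=(10, 6)) + sep
        arrays.append(np.vstack([a, b]))
    return _tensor_from_arrays(arrays), np.array([0] * 10 + [1] * 10)


def test_derive_seed_deterministic_and_bounded():
    assert derive_seed(3, 1) == derive_seed(3, 1)
    assert derive_seed(3, 1) != derive_seed(3, 2)
    assert 0 <= derive_seed(2**20, 99) < 2**31


class TestPerPhase:
    def test_identical_phases_and_shared_seed_give_identical_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        tensor = _tensor_from_arrays([X, X, X])
        lm, _ = per_phase_clustering(
            tensor, SOMTrainParams(seed=4), phase_seed_offsets=(0, 0, 0)
        )
        np.testing.assert_array_equal(lm.labels[:, 0], lm.labels[:, 1])
        np.testing.assert_array_equal(lm.labels[:, 0], lm.labels[:, 2])

    def test_planted_two_groups_separated_in_every_phase(self):
        """Each per-phase column separates the planted groups: no node mixes
        members of both groups (the map may refine a group into several
        pure nodes), and the dendrogram cut at k=2 recovers the partition
        exactly."""
        tensor, truth = _two_group_tensor()
        lm, _ = per_phase_clustering(tensor, SOMTrainParams(seed=1))
        for k in range(3):
            for node in np.unique(lm.labels[:, k]):
                assert np.unique(truth[lm.labels[:, k] == node]).size == 1
        lm2, _, _, _ = two_stage_cluster(tensor, SOMTrainParams(seed=1), cut_k=2)
        assert adjusted_rand_score(truth, lm2.super_labels) == 1.0

    def test_label_matrix_shape(self):
        tensor, _ = _two_group_tensor()
        lm, models = per_phase_clustering(tensor, SOMTrainParams(seed=0))
        assert lm.labels.shape == (20, 3)
        assert len(models) == 3
        assert lm.labels.min() >= 1 and lm.labels.max() <= 9


class TestSecondStage:
    def test_single_label_row_maps_to_one_node(self):
        lm = PhaseLabelMatrix(
            [f"s{i}" for i in range(8)], np.tile([2, 5, 7], (8, 1))
        )
        _, labels = second_stage_som(lm, SOMTrainParams(seed=0))
        assert np.unique(labels).size == 1

    def test_two_distinct_rows_give_two_nodes(self):
        rows = np.vstack([np.tile([1, 1, 1], (10, 1)), np.tile([9, 9, 9], (10, 1))])
        lm = PhaseLabelMatrix([f"s{i}" for i in range(20)], rows)
        _, labels = second_stage_som(lm, SOMTrainParams(seed=0))
        assert np.unique(labels).size == 2
        assert np.unique(labels[:10]).size == 1 and np.unique(labels[10:]).size == 1

    @pytest.mark.parametrize("encoding", ["raw", "grid", "onehot"])
    def test_encodings_all_run(self, encoding):
        lm = PhaseLabelMatrix(
            [f"s{i}" for i in range(6)],
            np.array([[1, 2, 3]] * 3 + [[7, 8, 9]] * 3),
        )
        _, labels = second_stage_som(lm, SOMTrainParams(seed=1), encoding=encoding)
        assert labels.shape == (6,)

    def test_unknown_encoding_rejected(self):
        lm = PhaseLabelMatrix(["a", "b"], np.array([[1, 1, 1], [2, 2, 2]]))
        with pytest.raises(ValueError):
            second_stage_som(lm, SOMTrainParams(seed=0), encoding="bogus")


class TestPruneAndSuperCluster:
    def test_prune_reports_counts(self):
        model = init_grid(3, 3, 2, None, seed=0)
        labels = np.array([1, 1, 3, 7, 8, 9, 9])
        survivors, counts = prune_empty_clusters(model, labels)
        assert survivors == [1, 3, 7, 8, 9]
        assert counts == {1: 2, 3: 1, 7: 1, 8: 1, 9: 2}

    def test_full_cut_gives_singleton_superclusters(self):
        model = init_grid(3, 3, 2, None, seed=1)
        labels = np.array([1, 2, 3, 4, 5])
        tree, supers = super_cluster(model, labels, cut_k=5)
        assert sorted(supers.tolist()) == [1, 2, 3, 4, 5]
        assert tree.cut_k == 5

    def test_mutually_nearest_pair_merges_at_cut(self):
        model = init_grid(3, 3, 2, None, seed=2)
        # five prototypes; nodes 8 and 9 (indices 7, 8) nearly coincide
        model.weights[[0, 2, 6]] = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        model.weights[7] = np.array([10.0, 10.0])
        model.weights[8] = np.array([10.1, 10.0])
        labels = np.array([1, 3, 7, 8, 9])
        _, supers = super_cluster(model, labels, cut_k=4)
        assert supers[3] == supers[4]  # clusters 8 and 9 merged
        assert np.unique(supers).size == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_average_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = init_grid(3, 3, 3, None, seed=seed)
        model.weights = rng.normal(size=(9, 3))
        labels = np.arange(1, 7)  # six populated prototypes
        cut_k = 3
        _, supers = super_cluster(model, labels, cut_k=cut_k)

        # naive agglomeration: repeatedly merge the pair of clusters with
        # the smallest average inter-point distance
        pts = {i: [model.weights[i]] for i in range(6)}
        while len(pts) > cut_k:
            keys = sorted(pts)
            best = None
            for a in range(len(keys)):
                for b in range(a + 1, len(keys)):
                    ka, kb = keys[a], keys[b]
                    d = np.mean(
                        [
                            np.linalg.norm(u - v)
                            for u in pts[ka]
                            for v in pts[kb]
                        ]
                    )
                    if best is None or d < best[0]:
                        best = (d, ka, kb)
            pts[best[1]] = pts[best[1]] + pts[best[2]]
            del pts[best[2]]
        oracle = np.empty(6, dtype=int)
        for g, (key, members) in enumerate(sorted(pts.items()), start=1):
            for m in members:
                for i in range(6):
                    if np.array_equal(model.weights[i], m):
                        oracle[i] = g
        assert adjusted_rand_score(oracle, supers) == 1.0

    def test_cut_k_exceeding_survivors_is_error(self):
        model = init_grid(3, 3, 2, None, seed=0)
        with pytest.raises(ValueError, match="cut_k"):
            super_cluster(model, np.array([1, 1, 2]), cut_k=3)


class TestTwoStageWorkflow:
    def test_partition_consistency_and_count_conservation(self):
        tensor, truth = generate_case_cohort(seed=2)
        lm, _, _, tree = two_stage_cluster(tensor, SOMTrainParams(seed=2))
        lm.validate_refinement()  # super labels never split a node
        sizes = np.bincount(lm.super_labels)[1:]
        assert sizes.sum() == 20
        assert sorted(sizes.tolist(), reverse=True) == [7, 6, 5, 2]

    def test_permuting_patients_permutes_labels_identically(self):
        tensor, _ = generate_case_cohort(seed=3, n_probes=400, n_phase_specific=180)
        perm = np.random.default_rng(0).permutation(20)
        ids = tensor.sample_ids
        permuted = PhaseTensor(
            tuple(
                ExpressionMatrix(
                    [ids[i] for i in perm], m.probe_ids, m.values[perm]
                )
                for m in tensor.matrices
            )
        )
        lm1, _, _, _ = two_stage_cluster(tensor, SOMTrainParams(seed=3))
        lm2, _, _, _ = two_stage_cluster(permuted, SOMTrainParams(seed=3))
        order = {p: i for i, p in enumerate(lm1.patient_ids)}
        for p2, label in zip(lm2.patient_ids, lm2.labels):
            np.testing.assert_array_equal(label, lm1.labels[order[p2]])
        assert adjusted_rand_score(
            lm2.super_labels, lm1.super_labels[[order[p] for p in lm2.patient_ids]]
        ) == 1.0
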