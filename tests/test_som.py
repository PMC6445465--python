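"""Hexagonal batch SOM: geometry, kernel, training, errors, sizing.

The headline correctness check is the batch-SOM/k-means equivalence: with a
neighbourhood radius below the unit lattice distance the batch update
degenerates to a Lloyd iteration, which an independent Lloyd oracle verifies
exactly.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from phenosom.som import (
    SomMap,
    TrainingSchedule,
    batch_train,
    bmu,
    bmus,
    ep_neighbourhood,
    hex_positions,
    init_map,
    quantization_error,
    second_bmu,
    select_map_size,
    topographic_error,
    u_matrix,
)


def lloyd_oracle(x, codebook, n_iter):
    """Independent Lloyd iteration with keep-on-empty and lowest-index ties."""
    cb = codebook.copy()
    for _ in range(n_iter):
        assign = cdist(x, cb).argmin(axis=1)
        for j in range(len(cb)):
            members = x[assign == j]
            if len(members):
                cb[j] = members.mean(axis=0)
    return cb


def constant_radius_schedule(radius, epochs):
    return TrainingSchedule(rough_epochs=epochs, fine_epochs=0,
                            rough_radius=(radius, radius))


class TestGeometry:
    def test_hex_neighbours_at_unit_distance(self):
        pos = hex_positions(4, 5)
        d = cdist(pos, pos)
        nonzero = d[d > 0]
        assert nonzero.min() == pytest.approx(1.0)
        # every interior node has exactly 6 unit-distance neighbours
        counts = ((d > 0) & (d < 1.001)).sum(axis=1)
        assert counts.max() == 6

    def test_map_node_count(self):
        som = init_map(8, 6, 3, np.random.default_rng(0).normal(size=(10, 3)), 0)
        assert som.n_nodes == 48


class TestEpNeighbourhood:
    @pytest.mark.parametrize("d,r,expected",
                             [(0.0, 2.0, 1.0), (2.0, 2.0, 0.0),
                              (1.0, 2.0, 0.75), (3.0, 2.0, 0.0)])
    def test_kernel_values(self, d, r, expected):
        assert ep_neighbourhood(d, r) == pytest.approx(expected)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            ep_neighbourhood(1.0, 0.0)


class TestInitMap:
    def test_seed_determinism(self):
        data = np.random.default_rng(1).normal(size=(20, 3))
        a = init_map(2, 2, 3, data, seed=5)
        b = init_map(2, 2, 3, data, seed=5)
        assert np.array_equal(a.codebook, b.codebook)

    def test_constant_feature_collapses_codebook(self):
        data = np.full((10, 2), 3.0)
        som = init_map(2, 3, 2, data, seed=0)
        assert np.all(som.codebook == 3.0)

    def test_codebook_within_data_range(self):
        data = np.random.default_rng(2).normal(size=(50, 4))
        som = init_map(3, 3, 4, data, seed=1)
        assert np.all(som.codebook >= data.min(axis=0))
        assert np.all(som.codebook <= data.max(axis=0))

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            init_map(2, 2, 5, np.zeros((4, 3)), 0)


class TestBmu:
    def test_exact_codebook_row_is_its_own_bmu(self):
        som = SomMap(2, 2, np.arange(8.0).reshape(4, 2))
        assert bmu(som, som.codebook[3]) == 3

    def test_equidistant_tie_breaks_to_lowest_index(self):
        som = SomMap(1, 3, np.array([[0.0], [2.0], [9.0]]))
        assert bmu(som, [1.0]) == 0

    def test_two_node_map_exhausts_both_ranks(self):
        som = SomMap(1, 2, np.array([[0.0], [5.0]]))
        assert {bmu(som, [1.0]), second_bmu(som, [1.0])} == {0, 1}


class TestErrors:
    def test_qe_zero_when_data_on_codebook(self):
        cb = np.array([[0.0], [4.0]])
        som = SomMap(1, 2, cb)
        assert quantization_error(som, cb) == 0.0

    def test_qe_unit_for_symmetric_single_value(self):
        som = SomMap(1, 2, np.array([[1.0], [100.0]]))
        assert quantization_error(som, np.array([[0.0], [2.0]])) == 1.0

    def test_te_zero_on_two_node_map(self):
        som = SomMap(1, 2, np.array([[0.0], [4.0]]))
        data = np.array([[0.1], [3.9], [2.0]])
        assert topographic_error(som, data) == 0.0

    def test_te_bounds(self):
        rng = np.random.default_rng(0)
        som = batch_train(init_map(3, 3, 4, rng.normal(size=(30, 4)), 0),
                          rng.normal(size=(30, 4)))
        assert 0.0 <= som.te <= 1.0
        assert som.qe >= 0.0


class TestUMatrix:
    def test_constant_codebook_gives_zeros(self):
        som = SomMap(2, 2, np.ones((4, 3)))
        assert np.all(u_matrix(som) == 0.0)

    def test_two_node_map_entries_equal_codebook_distance(self):
        som = SomMap(1, 2, np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert np.allclose(u_matrix(som), 5.0)

    def test_entries_nonnegative(self):
        rng = np.random.default_rng(1)
        som = SomMap(3, 4, rng.normal(size=(12, 5)))
        assert np.all(u_matrix(som) >= 0.0)


class TestBatchTrain:
    def test_sub_lattice_radius_equals_lloyd_oracle(self):
        """Radius below the unit lattice spacing decouples the nodes: each
        batch epoch must match an independent Lloyd iteration exactly."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 3))
        som = init_map(2, 3, 3, x, seed=4)
        for epochs in (1, 3, 7):
            trained = batch_train(som, x, constant_radius_schedule(0.5, epochs))
            assert np.array_equal(trained.codebook,
                                  lloyd_oracle(x, som.codebook, epochs))

    def test_fixed_point_when_each_node_owns_its_datum(self):
        cb = np.array([[0.0, 0.0], [10.0, 0.0]])
        som = SomMap(1, 2, cb.copy())
        trained = batch_train(som, cb, constant_radius_schedule(0.9, 5))
        assert np.array_equal(trained.codebook, cb)
        assert trained.qe == 0.0

    def test_two_blob_codebook_converges_to_blob_means(self, two_blobs):
        x, labels = two_blobs
        som = init_map(1, 2, x.shape[1], x, seed=0)
        trained = batch_train(som, x)
        means = np.sort(np.array([x[labels == 1].mean(axis=0),
                                  x[labels == 2].mean(axis=0)]), axis=0)
        got = np.sort(trained.codebook, axis=0)
        assert np.allclose(got, means, atol=1e-6)

    def test_sse_monotone_at_sub_lattice_radius(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(40, 4))
        som = init_map(3, 3, 4, x, seed=2)
        trained = batch_train(som, x, constant_radius_schedule(0.5, 15))
        sse = [entry[2] for entry in trained.training_log]
        assert all(b <= a + 1e-9 for a, b in zip(sse, sse[1:]))
        qe_log = [entry[1] for entry in trained.training_log]
        assert trained.qe <= qe_log[0] + 1e-9

    def test_lattice_symmetry_preserves_qe_te_and_umatrix(self):
        """Reversing the column order of a one-row map is a lattice-preserving
        relabeling; QE, TE and the multiset of U-matrix values must agree."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 3))
        som = batch_train(init_map(1, 6, 3, x, seed=1), x)
        flipped = SomMap(1, 6, som.codebook[::-1].copy())
        assert quantization_error(flipped, x) == pytest.approx(
            quantization_error(som, x))
        assert topographic_error(flipped, x) == pytest.approx(
            topographic_error(som, x))
        assert np.allclose(np.sort(u_matrix(flipped).ravel()),
                           np.sort(u_matrix(som).ravel()))

    def test_empty_data_rejected(self):
        som = SomMap(1, 2, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            batch_train(som, np.empty((0, 3)))


class TestSelectMapSize:
    def test_single_candidate_returned(self, two_blobs):
        x, _ = two_blobs
        (size, table) = select_map_size(x, [(2, 3)], seed=0)
        assert size == (2, 3)
        assert len(table) == 1

    def test_rank_sum_dominance(self, monkeypatch):
        """A candidate with strictly lower QE and TE must win."""
        import phenosom.som as som_mod

        metrics = {(2, 2): (1.0, 0.2), (3, 3): (0.5, 0.1)}

        def fake_train(som, data, schedule=None):
            som.qe, som.te = metrics[(som.n_rows, som.n_cols)]
            return som

        monkeypatch.setattr(som_mod, "batch_train", fake_train)
        x = np.random.default_rng(0).normal(size=(20, 3))
        size, _ = som_mod.select_map_size(x, [(2, 2), (3, 3)], seed=0)
        assert size == (3, 3)

    def test_selection_deterministic_under_fixed_seed(self, default_z):
        a = select_map_size(default_z, [(8, 6), (7, 7)], seed=3)
        b = select_map_size(default_z, [(8, 6), (7, 7)], seed=3)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_empty_candidates_rejected(self, two_blobs):
        with pytest.raises(ValueError):
            select_map_size(two_blobs[0], [], seed=0)


class TestBmus:
    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 3))
        som = init_map(2, 3, 3, x, seed=0)
        assert [bmu(som, row) for row in x] == list(bmus(som, x))
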