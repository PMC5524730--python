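import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sweetgate as sg
from sweetgate.datasets import FingerprintMatrix, FingerprintParams, InputError
from sweetgate.similarity import (
    ClusterReference,
    average_cluster_distance,
    classical_mds,
    derive_threshold,
    distance_matrix,
    tanimoto_similarity,
)
from conftest import random_binary_matrix


def vec(bits_on, length=16):
    v = np.zeros(length, dtype=np.uint8)
    v[list(bits_on)] = 1
    return v


def make_fps(rows, length=16, ids=None):
    bits = np.vstack([vec(r, length) for r in rows])
    ids = ids or [f"m{i}" for i in range(len(rows))]
    return FingerprintMatrix(ids, bits, FingerprintParams(n_bits=length))


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({1, 5, 9}, {1, 5, 9}, 1.0), ({1, 2}, {3, 4}, 0.0), ({1, 2}, {2, 3}, 1 / 3)],
    )
    def test_examples(self, a, b, expected):
        assert tanimoto_similarity(vec(a), vec(b)) == pytest.approx(expected)

    def test_symmetry_and_length_mismatch(self):
        a, b = vec({1, 2}), vec({2, 5, 7})
        assert tanimoto_similarity(a, b) == tanimoto_similarity(b, a)
        with pytest.raises(InputError):
            tanimoto_similarity(vec({1}, 8), vec({1}, 16))

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto_similarity(vec(set()), vec(set())) == 1.0

    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    @settings(max_examples=200, derandomize=True)
    def test_distance_triangle_inequality(self, xa, xb, xc):
        to_vec = lambda x: np.array([(x >> i) & 1 for i in range(20)], dtype=np.uint8)
        a, b, c = to_vec(xa), to_vec(xb), to_vec(xc)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dab = 1 - tanimoto_similarity(a, b)
            dbc = 1 - tanimoto_similarity(b, c)
            dac = 1 - tanimoto_similarity(a, c)
        assert dac <= dab + dbc + 1e-12


class TestAverageClusterDistance:
    def test_identical_to_single_member_is_zero(self):
        ref = ClusterReference("S1", make_fps([{0, 1, 2}]), 0.6)
        assert average_cluster_distance(vec({0, 1, 2}), ref) == pytest.approx(0.0)

    def test_disjoint_from_every_member_is_one(self):
        ref = ClusterReference("S1", make_fps([{0, 1}, {2, 3}]), 0.6)
        assert average_cluster_distance(vec({8, 9}), ref) == pytest.approx(1.0)

    def test_mean_of_member_distances(self):
        # similarities to the query are 0.8 and 0.4, so distance = mean(0.2, 0.6)
        query = vec(set(range(8)))
        ref = ClusterReference("S1", make_fps([set(range(10)), {0, 1, 2, 3, 8, 9}]), 0.6)
        assert average_cluster_distance(query, ref) == pytest.approx(0.4)

    def test_monotone_under_added_member(self):
        members = [set(range(10)), {0, 1, 2, 3, 8, 9}]
        query = vec(set(range(8)))
        before = average_cluster_distance(query, ClusterReference("S1", make_fps(members), 0.6))
        # new member at distance 0.8 (> current mean) raises the mean
        grown = ClusterReference("S1", make_fps(members + [{0, 1, 10, 11, 12, 13, 14, 15}]), 0.6)
        assert average_cluster_distance(query, grown) > before

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ClusterReference("S1", make_fps([]), 0.6)


class TestDeriveThreshold:
    def test_bimodal_distances_give_gap_midpoint(self):
        # distances to the single-member reference: 0.1, 0.2 (members), 0.7, 0.8
        ref = ClusterReference("S1", make_fps([set(range(10))], ids=["ref"]), 0.6)
        train = make_fps(
            [set(range(9)), set(range(8)), {0, 1, 2}, {0, 1}],
            ids=["a", "b", "c", "d"],
        )
        cutoff = derive_threshold(train, ref, member_ids={"a", "b"})
        assert cutoff == pytest.approx(0.45)

    def test_no_gap_returns_fallback_with_warning(self):
        ref = ClusterReference("S1", make_fps([set(range(10))], ids=["ref"]), 0.6)
        train = make_fps([set(range(9)), set(range(8))], ids=["a", "b"])
        with pytest.warns(UserWarning):
            assert derive_threshold(train, ref, member_ids={"a", "b"}, fallback=0.6) == 0.6

    def test_degenerate_equal_distances_error(self):
        ref = ClusterReference("S1", make_fps([set(range(10))], ids=["ref"]), 0.6)
        train = make_fps([set(range(8)), set(range(8))], ids=["a", "b"])
        with pytest.raises(InputError, match="manual"):
            derive_threshold(train, ref, member_ids={"a"})


class TestDistanceMatrix:
    def test_identical_and_disjoint(self):
        fps = make_fps([{0, 1}, {0, 1}, {4, 5}])
        D = distance_matrix(fps)
        assert D[0, 1] == pytest.approx(0.0)
        assert D[0, 2] == pytest.approx(1.0)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_entries_match_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        bits = random_binary_matrix(rng, 6, 32)
        fps = FingerprintMatrix([f"m{i}" for i in range(6)], bits,
                                FingerprintParams(n_bits=32))
        D = distance_matrix(fps)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else 1 - tanimoto_similarity(bits[i], bits[j])
                assert D[i, j] == pytest.approx(expected, abs=1e-12)


class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        coords = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(coords[:, None] - coords[None, :])
        with pytest.warns(UserWarning):  # k exceeds the rank-1 embedding
            result = classical_mds(D, k=2)
        assert result.explained_variance[0] == pytest.approx(1.0)
        reconstructed = np.abs(result.coords[:, 0][:, None] - result.coords[:, 0][None, :])
        assert np.allclose(reconstructed, D, atol=1e-8)

    def test_all_zero_distances_give_zero_coordinates(self):
        result = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(result.coords, 0.0)

    def test_euclidean_distances_reproduced_and_variance_non_increasing(self):
        rng = np.random.default_rng(2)
        points = rng.standard_normal((10, 3))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        result = classical_mds(D, k=3)
        rec = np.linalg.norm(result.coords[:, None] - result.coords[None, :], axis=2)
        assert np.allclose(rec, D, atol=1e-8)
        assert np.all(np.diff(result.explained_variance) <= 1e-12)
        assert result.explained_variance.sum() <= 1 + 1e-9

    def test_matches_independent_principal_coordinates(self):
        # scikit-bio's PCoA is an independent implementation of the same method
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(4)
        points = rng.standard_normal((12, 4))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        ours = classical_mds(D, k=3)
        theirs = skbio_pcoa(D, number_of_dimensions=3)
        ref = theirs.samples.to_numpy()[:, :3]
        for j in range(3):
            assert (np.allclose(ours.coords[:, j], ref[:, j], atol=1e-6)
                    or np.allclose(ours.coords[:, j], -ref[:, j], atol=1e-6))

    def test_planted_clusters_separate_in_two_dimensions(self, default_dataset):
        from sklearn.metrics import silhouette_score

        fps, _, _, meta = default_dataset
        members = {m for mm in meta.cluster_members.values() for m in mm}
        in_cluster = np.array([m in members for m in fps.ids])
        result = classical_mds(distance_matrix(fps), k=2)
        assert silhouette_score(result.coords, in_cluster) > 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(InputError):
            classical_mds(D, k=1)
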