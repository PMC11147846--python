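import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcbench.core import (
    Atlas,
    ConnectivityMatrix,
    DegenerateInputError,
    compute_efc,
    devectorize,
    group_average,
    make_folds,
    n_edges,
    vectorize,
)


class TestComputeEfc:
    def test_identical_columns_correlate_perfectly(self):
        ts = np.column_stack([np.arange(5.0), np.arange(5.0), np.arange(5.0) * 2])
        fc = compute_efc(ts)
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_reversed_columns_anticorrelate(self):
        ts = np.column_stack([[1.0, 2, 3], [3.0, 2, 1]])
        assert compute_efc(ts).values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # columns (1,2,4) and (1,3,3): centered dot 8/3, norms sqrt(42)/3 and
        # sqrt(24)/3, hence r = 24/sqrt(1008) = 0.7559289460184544
        ts = np.column_stack([[1.0, 2, 4], [1.0, 3, 3]])
        assert compute_efc(ts).values[0, 1] == pytest.approx(0.7559289460184544, abs=1e-12)

    def test_matches_explicit_covariance_normalization(self, rng):
        ts = rng.standard_normal((50, 8))
        fc = compute_efc(ts).values
        z = (ts - ts.mean(axis=0)) / ts.std(axis=0)
        oracle = z.T @ z / ts.shape[0]
        np.fill_diagonal(oracle, 1.0)
        assert np.allclose(fc, oracle, atol=1e-12)

    def test_output_is_psd_with_unit_diagonal(self, rng):
        fc = compute_efc(rng.standard_normal((30, 10))).values
        assert np.allclose(np.diag(fc), 1.0)
        assert np.linalg.eigvalsh(fc).min() >= -1e-10

    def test_zero_variance_region_names_the_parcel(self):
        ts = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
        with pytest.raises(DegenerateInputError, match=r"\[1\]"):
            compute_efc(ts)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            compute_efc(np.ones((2, 4)))


class TestEdgeVector:
    @pytest.mark.parametrize("p,length", [(3, 3), (68, 2278), (200, 19900)])
    def test_edge_count(self, p, length):
        assert n_edges(p) == length
        m = np.eye(p)
        assert vectorize(m).size == length

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    def test_round_trip_is_lossless_off_diagonal(self, p, seed):
        r = np.random.default_rng(seed)
        m = r.standard_normal((p, p))
        m = (m + m.T) / 2
        back = devectorize(vectorize(m), diagonal=0.0)
        off = ~np.eye(p, dtype=bool)
        assert np.array_equal(back[off], m[off])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            vectorize(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_canonical_ordering_row_major(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert np.array_equal(vectorize(m), [1.0, 2.0, 3.0])


class TestGroupAverage:
    def test_idempotent_on_identical_matrices(self, rng):
        fc = compute_efc(rng.standard_normal((40, 6)))
        avg = group_average([fc, fc, fc])
        assert np.allclose(avg.values, fc.values)

    def test_elementwise_mean(self):
        a = devectorize([0.2, 0.0, 0.0])
        b = devectorize([0.4, 0.0, 0.0])
        avg = group_average([ConnectivityMatrix(a, "FC"), ConnectivityMatrix(b, "FC")])
        assert avg.values[0, 1] == pytest.approx(0.3)

    def test_average_of_correlation_matrices_stays_psd(self, rng):
        # convexity: the PSD cone is convex, so the mean of valid
        # correlation matrices must have smallest eigenvalue >= 0
        fcs = [compute_efc(rng.standard_normal((25, 7))) for _ in range(5)]
        avg = group_average(fcs)
        assert np.linalg.eigvalsh(avg.values).min() >= -1e-10

    def test_commutes_with_vectorize(self, rng):
        fcs = [compute_efc(rng.standard_normal((25, 7))) for _ in range(4)]
        mean_of_vecs = np.mean([vectorize(f.values) for f in fcs], axis=0)
        assert np.allclose(vectorize(group_average(fcs).values), mean_of_vecs, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_average([])


class TestFolds:
    def test_ten_folds_of_hundred(self):
        folds = make_folds(1000, 10, seed=3)
        sizes = [folds.validation_indices(f).size for f in range(10)]
        assert sizes == [100] * 10

    def test_singleton_folds(self):
        folds = make_folds(10, 10, seed=0)
        assert sorted(folds.assignment) == list(range(10))

    def test_deterministic_for_fixed_seed(self):
        a = make_folds(57, 7, seed=11).assignment
        b = make_folds(57, 7, seed=11).assignment
        assert np.array_equal(a, b)

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, seed=0)

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(min_value=2, max_value=200),
        st.integers(min_value=2, max_value=12),
        st.integers(0, 2**31 - 1),
    )
    def test_partition_properties(self, n, k, seed):
        if k > n:
            return
        folds = make_folds(n, k, seed)
        sizes = [folds.validation_indices(f).size for f in range(k)]
        # folds partition the cohort with sizes differing by at most one
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        all_idx = np.concatenate([folds.validation_indices(f) for f in range(k)])
        assert sorted(all_idx) == list(range(n))
        for f in range(k):
            assert not set(folds.validation_indices(f)) & set(folds.training_indices(f))


class TestAtlas:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Atlas(labels=("a", "a"), networks=("VN", "VN"))

    def test_unknown_network_rejected(self):
        with pytest.raises(ValueError, match="unknown network"):
            Atlas(labels=("a", "b"), networks=("VN", "XXX"))

    def test_network_lookup_by_index_and_label(self):
        atlas = Atlas(labels=("a", "b", "c"), networks=("VN", "DMN", "DMN"))
        assert atlas.network_of(0) == "VN"
        assert atlas.network_of("b") == "DMN"
        assert list(atlas.parcels_in("DMN")) == [1, 2]


class TestConnectivityMatrix:
    def test_fc_range_enforced(self):
        bad = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            ConnectivityMatrix(bad, "FC")

    def test_sc_counts_nonnegative_zero_diagonal(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ConnectivityMatrix(np.array([[0.0, -1], [-1, 0]]), "SC_counts")
        with pytest.raises(ValueError, match="diagonal"):
            ConnectivityMatrix(np.array([[2.0, 1], [1, 2]]), "SC_counts")

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(np.array([[1.0, 0.2], [0.3, 1.0]]), "FC")
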