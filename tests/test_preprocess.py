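import numpy as np
import pandas as pd
import pytest

from hybridgo.preprocess import (
    component_similarity,
    filter_matrix,
    knn_impute,
    pca_gene_features,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class TestFilter:
    def test_row_over_missing_cut_removed_others_kept(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((10, 10))
        arr[3, :4] = np.nan  # 40% missing
        m = make_matrix(arr)
        out, report = filter_matrix(m, max_missing=0.30)
        assert "g4" not in out.row_ids
        assert len(out.row_ids) == 9
        assert ("g4", "row", report.removed[0][2]) == report.removed[0]

    def test_constant_row_removed_even_if_complete(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((5, 6))
        arr[2] = 3.14
        out, report = filter_matrix(make_matrix(arr), 0.30)
        assert "g3" not in out.row_ids
        assert any("standard deviation" in r for _, _, r in report.removed)

    def test_clean_matrix_is_identity(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.standard_normal((8, 8)))
        out, report = filter_matrix(m, 0.30)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert report.removed == []

    def test_samples_removed_before_rows(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((10, 10))
        arr[:, 0] = np.nan  # dead sample
        arr[0, :4] = np.nan  # row at 40% counting the dead sample, 33% without
        out, report = filter_matrix(make_matrix(arr), 0.35)
        assert "s1" in report.removed_cols
        # after dropping s1 the row is 3/9 = 0.33 missing, under the cut
        assert "g1" in out.row_ids

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.standard_normal((30, 12))
        arr[rng.random((30, 12)) < 0.25] = np.nan
        once, _ = filter_matrix(make_matrix(arr), 0.30)
        twice, report = filter_matrix(once, 0.30)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report.removed == []

    def test_empty_result_is_error(self):
        arr = np.full((3, 3), np.nan)
        arr[0, 0] = 1.0
        with pytest.raises(ValueError, match="empty"):
            filter_matrix(make_matrix(arr), 0.30)


# ---------------------------------------------------------------------------
# k-NN imputation
# ---------------------------------------------------------------------------


def knn_oracle(X, k):
    """Exhaustive-distance re-implementation of the imputation rule."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    out = X.copy()
    col_means = np.nanmean(X, axis=0)
    for i in range(n):
        for j in range(d):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i:
                    dists.append(np.inf)
                    continue
                both = ~np.isnan(X[i]) & ~np.isnan(X[r])
                if not both.any():
                    dists.append(np.inf)
                    continue
                sq = np.sum((X[i, both] - X[r, both]) ** 2)
                dists.append(np.sqrt(sq * d / both.sum()))
            order = np.argsort(np.asarray(dists), kind="stable")[:k]
            donors = X[order, j]
            donors = donors[~np.isnan(donors)]
            out[i, j] = donors.mean() if donors.size else col_means[j]
    return out


class TestKnnImpute:
    def test_complete_matrix_is_identity(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((6, 4)))
        out = knn_impute(m, k=5)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_single_missing_cell_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((6, 4))
        arr[2, 1] = np.nan
        out = knn_impute(make_matrix(arr), k=5)
        np.testing.assert_allclose(out.values, knn_oracle(arr, 5), atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_patterns_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.standard_normal((12, 6))
        arr[rng.random((12, 6)) < 0.2] = np.nan
        arr[np.isnan(arr).all(axis=1)] = 0.0  # keep rows imputable
        out = knn_impute(make_matrix(arr), k=3)
        np.testing.assert_allclose(out.values, knn_oracle(arr, 3), atol=1e-8)

    def test_identical_rows_recover_shared_value(self):
        arr = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        arr[0, 2] = np.nan
        out = knn_impute(make_matrix(arr), k=3)
        assert out.values[0, 2] == pytest.approx(3.0)

    def test_observed_entries_preserved_exactly(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((10, 5))
        arr[rng.random((10, 5)) < 0.2] = np.nan
        m = make_matrix(arr)
        out = knn_impute(m, k=4)
        obs = ~np.isnan(arr)
        np.testing.assert_array_equal(out.values[obs], arr[obs])
        assert out.is_complete

    def test_column_mean_fallback_when_all_neighbors_missing(self):
        # rows g2..g4 are nearest to g1 but all lack column 3
        arr = np.array(
            [
                [0.0, 0.0, np.nan],
                [0.1, 0.1, np.nan],
                [0.0, 0.1, np.nan],
                [0.1, 0.0, np.nan],
                [9.0, 9.0, 5.0],
                [9.1, 9.1, 7.0],
            ]
        )
        out = knn_impute(make_matrix(arr), k=3)
        assert out.values[0, 2] == pytest.approx(6.0)  # column mean of {5, 7}

    def test_unimputable_row_is_an_error(self):
        arr = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="g1"):
            knn_impute(make_matrix(arr), k=2)


# ---------------------------------------------------------------------------
# PCA gene features
# ---------------------------------------------------------------------------


class TestPCA:
    def test_rank_one_matrix_first_component_dominates(self):
        rng = np.random.default_rng(0)
        # mixed-sign gene weights: rows z-score to +/- z(b), still rank one
        a = rng.uniform(0.5, 2.0, size=40) * rng.choice([-1.0, 1.0], size=40)
        b = rng.standard_normal(10)
        m = make_matrix(np.outer(a, b))
        pcs = pca_gene_features(m, n_components=3)
        assert pcs.explained_variance_ratio[0] >= 0.999

    def test_full_reconstruction_matches_zscored_matrix(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.standard_normal((30, 8)))
        pcs = pca_gene_features(m, n_components=8)
        Z = m.data.sub(m.data.mean(axis=1), axis=0).div(m.data.std(axis=1, ddof=0), axis=0)
        recon = pcs.scores.to_numpy() @ pcs.loadings.to_numpy() + Z.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_variance_ratios_match_direct_eigendecomposition(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.standard_normal((200, 30)))
        pcs = pca_gene_features(m, n_components=30)
        Z = m.data.sub(m.data.mean(axis=1), axis=0).div(
            m.data.std(axis=1, ddof=0), axis=0
        ).to_numpy()
        Zc = Z - Z.mean(axis=0)
        cov = Zc.T @ Zc / (Zc.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            pcs.explained_variance_ratio, eig / eig.sum(), atol=1e-8
        )

    def test_cumulative_variance_monotone_and_target_selection(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.standard_normal((100, 20)))
        full = pca_gene_features(m, n_components=20)
        cum = full.cumulative_variance
        assert (np.diff(cum) >= -1e-12).all()
        target = float(cum[4])  # attained exactly at 5 components
        chosen = pca_gene_features(m, variance_target=target - 1e-9)
        assert chosen.n_components == 5

    def test_unattainable_variance_target_is_error(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.standard_normal((20, 6)))
        with pytest.raises(ValueError, match="target"):
            pca_gene_features(m, variance_target=1.0)

    def test_incomplete_matrix_rejected(self):
        arr = np.ones((4, 3)) + np.arange(12).reshape(4, 3)
        arr[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pca_gene_features(make_matrix(arr), n_components=2)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.standard_normal((50, 10)))
        a = pca_gene_features(m, n_components=4)
        b = pca_gene_features(m, n_components=4)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for c in range(4):
            row = a.loadings.iloc[c].to_numpy()
            assert row[np.argmax(np.abs(row))] > 0


class TestComponentSimilarity:
    def test_self_similarity_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((40, 12)))
        pcs = pca_gene_features(m, n_components=5)
        sim = component_similarity(pcs, pcs)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0, atol=1e-10)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.standard_normal((40, 12)))
        pcs = pca_gene_features(m, n_components=5)
        flipped = pca_gene_features(m, n_components=5)
        flipped.loadings.iloc[:] = -flipped.loadings.to_numpy()
        sim = component_similarity(pcs, flipped)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0, atol=1e-10)

    def test_independent_random_bases_are_dissimilar(self):
        # Monte Carlo over 20 seeds in 50 dimensions
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            A = np.linalg.qr(rng.standard_normal((50, 50)))[0][:5]
            B = np.linalg.qr(rng.standard_normal((50, 50)))[0][:5]
            means.append(np.abs(A @ B.T).mean())
        assert np.mean(means) < 0.3

    def test_disjoint_samples_is_error(self):
        rng = np.random.default_rng(2)
        a = pca_gene_features(make_matrix(rng.standard_normal((20, 6))), n_components=2)
        b = pca_gene_features(
            make_matrix(rng.standard_normal((20, 6)), col_prefix="t"), n_components=2
        )
        with pytest.raises(ValueError, match="shared"):
            component_similarity(a, b)
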