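"""Normalization, diffusion, clustering and outlier-removal contracts,
each checked against an independent dense/brute-force oracle."""

import numpy as np
import pytest
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from keranet.io import ConfigurationError, CountMatrix
from keranet.staging import (
    StageAssignment,
    approx_spectral_cluster,
    build_diffusion_operator,
    impute,
    normalize_log_cpm,
    orient_stages,
    remove_outliers,
    stage_profile,
)


class TestNormalizeLogCpm:
    def test_single_cell_closed_form(self):
        counts = CountMatrix(np.array([[1], [0]]), ["g1", "g2"], ["c1"])
        out = normalize_log_cpm(counts)
        assert out[0, 0] == pytest.approx(np.log2(1e6 + 1))
        assert out[1, 0] == 0.0

    def test_inverse_recovers_proportions(self, tiny_counts):
        out = normalize_log_cpm(tiny_counts)
        cpm = 2.0**out - 1.0
        recovered = cpm / cpm.sum(axis=0)
        expected = tiny_counts.values / tiny_counts.values.sum(axis=0)
        np.testing.assert_allclose(recovered, expected, atol=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        values = rng.integers(0, 50, size=(50, 20))
        values[:, values.sum(0) == 0] += 1
        counts = CountMatrix(values, [f"g{i}" for i in range(50)], [f"c{i}" for i in range(20)])
        out = normalize_log_cpm(counts)
        colsum = values.sum(axis=0)
        for i in range(50):
            for j in range(0, 20, 3):
                assert out[i, j] == pytest.approx(np.log2(1e6 * values[i, j] / colsum[j] + 1))

    def test_zero_cell_is_named(self):
        counts = CountMatrix(np.array([[1, 0], [2, 0]]), ["g1", "g2"], ["good", "empty"])
        with pytest.raises(ConfigurationError, match="empty"):
            normalize_log_cpm(counts)


def _dense_diffusion_oracle(X, k, ka):
    """All-pairs distances, kNN mask, adaptive kernel, symmetrize, normalize."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    A = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(D[i])
        neighbors = [j for j in order if j != i][:k]
        sigma = D[i, neighbors[ka - 1]]
        if sigma == 0:
            pos = D[D > 0]
            sigma = np.median(pos) if len(pos) else 1.0
        for j in neighbors:
            A[i, j] = np.exp(-((D[i, j] / sigma) ** 2))
        A[i, i] = 1.0
    A = (A + A.T) / 2
    return A / A.sum(axis=1, keepdims=True)


class TestDiffusionOperator:
    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(80, 5))
        op = build_diffusion_operator(X, 15, 5)
        rows = np.asarray(op.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0, atol=1e-10)

    def test_matches_dense_oracle(self, rng):
        X = rng.normal(size=(10, 2))
        op = build_diffusion_operator(X, 4, 2)
        expected = _dense_diffusion_oracle(X, 4, 2)
        np.testing.assert_allclose(op.matrix.toarray(), expected, atol=1e-12)

    def test_separated_clusters_have_no_cross_mass(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (50, 3)), rng.normal(50, 0.1, (50, 3))])
        op = build_diffusion_operator(X, 10, 4)
        M = op.matrix.toarray()
        assert M[:50, 50:].sum() < 1e-6
        assert M[50:, :50].sum() < 1e-6

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ConfigurationError):
            build_diffusion_operator(rng.normal(size=(5, 2)), 5, 2)

    def test_duplicate_points_fall_back(self):
        X = np.array([[0.0, 0], [0, 0], [0, 0], [1, 0], [2, 0]])
        op = build_diffusion_operator(X, 3, 2)  # sigma would be 0 for duplicates
        assert np.isfinite(op.matrix.toarray()).all()


class TestImpute:
    def test_t_zero_is_identity(self, rng):
        X = rng.normal(size=(30, 3))
        op = build_diffusion_operator(X, 5, 2)
        expr = rng.random((7, 30))
        np.testing.assert_array_equal(impute(expr, op, 0), expr)

    def test_three_cell_chain_hand_oracle(self):
        import scipy.sparse

        from keranet.staging import DiffusionOperator

        M = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])
        op = DiffusionOperator(scipy.sparse.csr_matrix(M), 1, 1)
        expr = np.array([[1.0, 2.0, 4.0]])
        got = impute(expr, op, 1)
        want = expr @ M.T  # cell i becomes sum_j M[i, j] expr[j]
        np.testing.assert_allclose(got, want)
        np.testing.assert_allclose(got, [[1.5, 2.25, 3.0]])

    def test_spread_shrinks_toward_stationary_mean(self, rng):
        X = rng.normal(size=(40, 2))
        op = build_diffusion_operator(X, 8, 3)
        expr = rng.random((5, 40))
        spreads = []
        for t in (1, 2, 4, 8):
            spreads.append(impute(expr, op, t).std(axis=1).sum())
        assert all(a >= b - 1e-12 for a, b in zip(spreads, spreads[1:]))
        heavy = impute(expr, op, 256)
        assert heavy.std(axis=1).max() < 0.05 * expr.std(axis=1).max()

    def test_negative_t_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        op = build_diffusion_operator(X, 4, 2)
        with pytest.raises(ConfigurationError):
            impute(np.ones((2, 20)), op, -1)


def _exact_spectral_oracle(X, K, seed):
    """Plain normalized spectral clustering on all points, same construction."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    off = D[~np.eye(n, dtype=bool)]
    sigma = np.median(off) if np.median(off) > 0 else 1.0
    A = np.exp(-((D / sigma) ** 2))
    np.fill_diagonal(A, 0)
    d = A.sum(1)
    M = A / np.sqrt(d)[:, None] / np.sqrt(d)[None, :]
    _, vecs = eigh(M, subset_by_index=(n - K, n - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1
    emb = vecs / norms
    return KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(emb)


class TestApproxSpectralCluster:
    def test_separated_blobs_perfect_ari(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], dtype=float)
        X = np.vstack([rng.normal(c, 1.0, (40, 2)) for c in centers])
        truth = np.repeat(np.arange(4), 40)
        got = approx_spectral_cluster(X, 40, 4, seed=0)
        assert adjusted_rand_score(truth, got.labels) == 1.0

    def test_m_equals_n_matches_exact_spectral(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(6, 1, (30, 3))])
        got = approx_spectral_cluster(X, len(X), 2, seed=1)
        oracle = _exact_spectral_oracle(X, 2, seed=1)
        assert adjusted_rand_score(oracle, got.labels) == 1.0

    def test_cell_order_invariance(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(8, 0.5, (30, 2))])
        a = approx_spectral_cluster(X, len(X), 2, seed=0)
        perm = rng.permutation(len(X))
        b = approx_spectral_cluster(X[perm], len(X), 2, seed=0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_labels_ordered_along_first_axis(self, rng):
        X = np.vstack([rng.normal([i * 10, 0], 0.5, (25, 2)) for i in range(3)])
        got = approx_spectral_cluster(X, len(X), 3, seed=0)
        means = [X[got.labels == k, 0].mean() for k in (1, 2, 3)]
        assert means == sorted(means)


class TestRemoveOutliers:
    def test_identical_points_keep_everything(self):
        X = np.zeros((40, 2))
        stages = StageAssignment(np.ones(40, dtype=int), 1)
        assert remove_outliers(X, stages, 3.0).all()

    def test_single_far_outlier_removed(self, rng):
        X = rng.normal(0, 0.5, (100, 2))
        X[17] = [60, 60]
        stages = StageAssignment(np.ones(100, dtype=int), 1)
        mask = remove_outliers(X, stages, 3.0)
        assert not mask[17]
        assert mask.sum() >= 95

    def test_infinite_c_removes_nothing(self, rng):
        X = rng.normal(size=(50, 3))
        stages = StageAssignment(np.repeat([1, 2], 25), 2)
        assert remove_outliers(X, stages, np.inf).all()

    def test_tiny_stage_skipped_with_warning(self, rng):
        X = rng.normal(size=(24, 2))
        labels = np.ones(24, dtype=int)
        labels[:3] = 2
        with pytest.warns(UserWarning, match="fewer than 5"):
            mask = remove_outliers(X, StageAssignment(labels, 2), 0.0)
        assert mask[:3].all()


class TestStageProfile:
    def test_constant_gene_flagged_and_zeroed(self):
        imputed = np.vstack([np.full(6, 10.0), np.arange(6, dtype=float)])
        stages = StageAssignment(np.repeat([1, 2, 3], 2), 3)
        prof = stage_profile(imputed, ["flat", "dyn"], stages)
        assert "flat" in prof.constant_genes
        np.testing.assert_array_equal(prof.normalized.loc["flat"].to_numpy(), 0.0)

    def test_two_stage_closed_form(self):
        imputed = np.array([[4.0, 4.0, 16.0, 16.0]])
        stages = StageAssignment(np.array([1, 1, 2, 2]), 2)
        prof = stage_profile(imputed, ["g"], stages)
        diff = prof.mean_expr.loc["g", 2] - prof.mean_expr.loc["g", 1]
        assert diff == pytest.approx(np.log2(17) - np.log2(5))

    def test_matches_groupby_zscore_oracle(self, rng):
        imputed = rng.random((8, 30)) * 100
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]
        stages = StageAssignment(labels, 3)
        prof = stage_profile(imputed, [f"g{i}" for i in range(8)], stages)
        for i in range(8):
            means = [np.log2(imputed[i, labels == s].mean() + 1) for s in (1, 2, 3)]
            np.testing.assert_allclose(prof.mean_expr.iloc[i].to_numpy(), means, atol=1e-12)
            z = (np.array(means) - np.mean(means)) / np.std(means)
            np.testing.assert_allclose(prof.normalized.iloc[i].to_numpy(), z, atol=1e-12)

    def test_empty_stage_in_subset_errors(self):
        stages = StageAssignment(np.array([1, 1, 2, 2]), 3)
        with pytest.raises(ConfigurationError):
            stage_profile(np.ones((1, 4)), ["g"], stages, stage_subset=[1, 3])

    def test_minmax_option(self):
        imputed = np.array([[1.0, 3.0, 7.0, 15.0]])
        stages = StageAssignment(np.array([1, 1, 2, 2]), 2)
        prof = stage_profile(imputed, ["g"], stages, normalization="minmax")
        np.testing.assert_allclose(prof.normalized.loc["g"].to_numpy(), [0.0, 1.0])


class TestOrientation:
    def test_flip_when_anchors_peak_late(self):
        labels = np.array([1, 2, 3, 4])
        new, flipped = orient_stages(labels, 4, {"a": 4, "b": 4}, {"a": 1.0, "b": 1.0})
        assert flipped
        np.testing.assert_array_equal(new, [4, 3, 2, 1])

    def test_no_flip_when_anchors_peak_early(self):
        labels = np.array([1, 2, 3, 4])
        new, flipped = orient_stages(labels, 4, {"a": 1}, {"a": 2.0})
        assert not flipped
        np.testing.assert_array_equal(new, labels)
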