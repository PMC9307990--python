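import numpy as np
import pytest

from tsgeeg import (SimilarityModel, TSGTransformer, build_similarity,
                    correlation_graph, correlation_graphs, embed,
                    out_of_sample)
from conftest import windows_with_correlation


class TestCorrelationGraph:
    def test_identical_channels_fully_correlated(self, rng):
        x = rng.standard_normal(100)
        A = correlation_graph(np.stack([x, x]))
        np.testing.assert_allclose(A, 1.0)

    def test_negated_channel(self, rng):
        x = rng.standard_normal(100)
        A = correlation_graph(np.stack([x, -x]))
        assert A[0, 1] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self, rng):
        A = correlation_graph(rng.standard_normal((6, 5000)))
        off = A[~np.eye(6, dtype=bool)]
        assert np.mean(np.abs(off) < 0.05) >= 0.93

    def test_zero_variance_channel_zeroed_with_warning(self, rng):
        win = rng.standard_normal((3, 50))
        win[1] = 4.2
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            A = correlation_graph(win)
        assert A[1, 1] == 1.0 and A[0, 1] == 0.0 and A[1, 2] == 0.0

    def test_graph_invariants(self, rng):
        for _ in range(5):
            A = correlation_graph(rng.standard_normal((5, 40)))
            np.testing.assert_allclose(A, A.T, atol=1e-10)
            np.testing.assert_allclose(np.diag(A), 1.0)
            assert (np.abs(A) <= 1.0 + 1e-12).all()


def graphs_on_a_line(coords, n_c=4, seed=0):
    """Graph stack A_k = I + c_k * E with fixed symmetric zero-diagonal E.

    Pairwise Frobenius distances are then |c_i - c_j| * ||E||_F, so B is a
    triangular kernel on the coordinates — symmetric PSD by construction.
    """
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n_c, n_c))
    E = (E + E.T) / 2
    np.fill_diagonal(E, 0.0)
    E /= np.linalg.norm(E)
    return np.stack([np.eye(n_c) + c * 0.4 * E for c in coords])


class TestBuildSimilarity:
    def test_two_graph_minmax(self):
        graphs = graphs_on_a_line([0.0, 1.0])
        sim = build_similarity(graphs)
        np.testing.assert_allclose(sim.B, np.eye(2), atol=1e-12)

    def test_three_graphs_hand_computed(self):
        # place three graphs in a 2-D matrix plane with pairwise
        # distances 0.5, 1.0, 1.0; then B off-diagonals are {0.5, 0, 0}
        E1 = np.zeros((3, 3)); E1[0, 1] = E1[1, 0] = 1 / np.sqrt(2)
        E2 = np.zeros((3, 3)); E2[0, 2] = E2[2, 0] = 1 / np.sqrt(2)
        P = [(0.0, 0.0), (0.5, 0.0), (0.25, np.sqrt(1 - 0.0625))]
        graphs = np.stack([x * E1 + y * E2 for x, y in P])
        sim = build_similarity(graphs)
        np.testing.assert_allclose(sim.D[0, 1], 0.5, atol=1e-12)
        np.testing.assert_allclose(sim.B[0, 1], 0.5, atol=1e-12)
        np.testing.assert_allclose(sim.B[0, 2], 0.0, atol=1e-12)
        np.testing.assert_allclose(sim.B[1, 2], 0.0, atol=1e-12)

    def test_similarity_invariants(self, rng):
        graphs = correlation_graphs(rng.standard_normal((10, 4, 60)))
        sim = build_similarity(graphs)
        assert (sim.B >= -1e-12).all() and (sim.B <= 1 + 1e-12).all()
        np.testing.assert_allclose(sim.B, sim.B.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim.B), 1.0)
        np.testing.assert_allclose(np.diag(sim.D), 0.0)
        assert sim.d_min == 0.0

    def test_distinct_pairs_min_convention(self, rng):
        graphs = correlation_graphs(rng.standard_normal((6, 4, 60)))
        sim = build_similarity(graphs, distinct_pairs_min=True)
        off = sim.D[~np.eye(6, dtype=bool)]
        assert sim.d_min == pytest.approx(off.min())
        # the diagonal of B then exceeds 1 (similarity of a graph to itself)
        assert (np.diag(sim.B) > 1.0).all()

    def test_identical_graphs_degenerate(self):
        graphs = np.stack([np.eye(3)] * 4)
        with pytest.raises(ValueError, match="identical"):
            build_similarity(graphs)


class TestEmbed:
    def test_rank_one_recovery(self, rng):
        z = rng.uniform(0.2, 1.0, size=6)
        B = np.outer(z, z)
        emb = embed(SimilarityModel(B=B, D=np.zeros_like(B), d_min=0, d_max=1), d=1)
        np.testing.assert_allclose(np.abs(emb.Z_hat[:, 0]), z, atol=1e-8)
        np.testing.assert_allclose(emb.Z_hat @ emb.Z_hat.T, B, atol=1e-8)

    def test_all_ones_matrix(self):
        B = np.ones((4, 4))
        emb = embed(SimilarityModel(B=B, D=np.zeros_like(B), d_min=0, d_max=1), d=1)
        # sigma = 4, u = 1/2 * ones  =>  Z = sqrt(4) * 1/2 = 1, positive sign
        np.testing.assert_allclose(emb.Z_hat[:, 0], 1.0, atol=1e-12)

    def test_reconstruction_error_nonincreasing_in_d(self, rng):
        W = rng.standard_normal((8, 8))
        B = W @ W.T
        sim = SimilarityModel(B=B, D=np.zeros_like(B), d_min=0, d_max=1)
        errs = [np.linalg.norm(embed(sim, d=d).Z_hat @ embed(sim, d=d).Z_hat.T - B)
                for d in range(1, 9)]
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-6  # full rank reproduces PSD B

    def test_sign_convention_deterministic(self, rng):
        graphs = correlation_graphs(rng.standard_normal((8, 4, 60)))
        sim = build_similarity(graphs)
        e1, e2 = embed(sim, d=3), embed(sim, d=3)
        np.testing.assert_array_equal(e1.Z_hat, e2.Z_hat)
        for col in e1.Z_hat.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_dimension_out_of_range(self, rng):
        graphs = correlation_graphs(rng.standard_normal((5, 4, 60)))
        with pytest.raises(ValueError, match="out of range"):
            embed(build_similarity(graphs), d=6)


class TestOutOfSample:
    def psd_window_stack(self, rng, n_w=5, n_c=4, w=64):
        """Windows whose B is a triangular kernel: PSD with rank n_w."""
        coords = np.linspace(0.0, 1.0, n_w)
        base = np.eye(n_c)
        E = np.zeros((n_c, n_c))
        E[0, 1] = E[1, 0] = 1.0
        targets = [base + c * 0.45 * E for c in coords]
        return np.stack([windows_with_correlation(C, w, rng) for C in targets])

    def test_training_window_maps_to_its_embedding_row(self, rng):
        X = self.psd_window_stack(rng)
        mapper = TSGTransformer(n_components=5).fit(X)
        B = mapper.similarity_.B
        assert np.linalg.eigvalsh(B).min() > -1e-10  # PSD: rank <= d holds
        for k in range(len(X)):
            np.testing.assert_allclose(out_of_sample(X[k], mapper),
                                       mapper.embedding_[k], atol=1e-6)

    def test_matches_direct_formula(self, rng):
        """Independent recomputation of the weighted-sum mapping."""
        X = rng.standard_normal((6, 4, 80))
        mapper = TSGTransformer(n_components=3).fit(X)
        x_new = rng.standard_normal((4, 80))
        A = np.corrcoef(x_new)
        dists = np.array([np.linalg.norm(A - Ak) for Ak in mapper.graphs_])
        s = 1 - (dists - mapper.similarity_.d_min) / (
            mapper.similarity_.d_max - mapper.similarity_.d_min)
        s = np.clip(s, 0.0, 1.0)
        P = np.linalg.inv(mapper.embedding_.T @ mapper.embedding_) \
            @ mapper.embedding_.T
        expected = sum(s[k] * P[:, k] for k in range(len(X)))
        np.testing.assert_allclose(out_of_sample(x_new, mapper), expected,
                                   atol=1e-8)

    def test_linearity_in_similarity_vector(self, rng):
        X = rng.standard_normal((6, 4, 80))
        mapper = TSGTransformer(n_components=3).fit(X)
        P = mapper.projector_
        v1, v2 = rng.random(6), rng.random(6)
        lhs = (0.3 * v1 + 0.7 * v2) @ P.T
        rhs = 0.3 * (v1 @ P.T) + 0.7 * (v2 @ P.T)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_projector_left_inverse_of_embedding(self, rng):
        X = rng.standard_normal((8, 4, 80))
        mapper = TSGTransformer(n_components=4).fit(X)
        np.testing.assert_allclose(mapper.projector_ @ mapper.embedding_,
                                   np.eye(4), atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        mapper = TSGTransformer(n_components=2).fit(rng.standard_normal((5, 4, 60)))
        with pytest.raises(ValueError, match="channel-count"):
            mapper.transform(correlation_graphs(rng.standard_normal((2, 5, 60))))

    def test_within_class_closer_than_between_class(self, corr_sessions):
        """Held-out windows land near same-class training embeddings."""
        from tsgeeg.experiments import _SessionCache, _stratified_split
        s = corr_sessions[0]
        G = _SessionCache(s).graphs()
        tr, te = _stratified_split(np.arange(s.n_windows), s.labels, 0.8, 3)
        mapper = TSGTransformer(precomputed=True).fit(G[tr])
        Z_te = mapper.transform(G[te])
        Z_tr = mapper.embedding_
        d_within, d_between = [], []
        for z, lab in zip(Z_te, s.labels[te]):
            dist = np.linalg.norm(Z_tr - z, axis=1)
            d_within.append(dist[s.labels[tr] == lab].mean())
            d_between.append(dist[s.labels[tr] != lab].mean())
        assert np.mean(d_within) < np.mean(d_between)

    def test_end_to_end_correlation_effect_separates(self, corr_sessions):
        import tsgeeg as tg
        res = tg.in_session([corr_sessions[0]],
                            tg.ProtocolConfig(feature_set="tsg",
                                              n_replicates=20, seed=2))
        sc = res.records["score"]
        se = max(sc.std(ddof=1) / np.sqrt(len(sc)), 1e-12)
        assert sc.mean() - 0.5 >= 5 * se
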