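"""GraphSAGE primitives against brute-force oracles, plus a gradient check."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rsnsage import (
    BrainGraph,
    LayerParams,
    SageConfig,
    aggregate_mean,
    aggregate_pool,
    forward_layer,
    generate_walk_pairs,
    sample_neighbors,
    train_embeddings,
    unsupervised_loss,
)
from rsnsage.sage import _Trainer, read_embeddings, write_embeddings


def _graph_from_edges(n, edges, feat_dim=None, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    feats = rng.uniform(0.0, 1.0, size=(n, feat_dim or n))
    return BrainGraph(
        n_nodes=n, edges=set(edges), features=feats,
        roi_ids=[f"R{i}" for i in range(n)],
    )


def _random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = {
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    }
    return _graph_from_edges(n, edges, rng_seed=seed)


class TestNeighborSampling:
    def test_single_neighbor_forced(self):
        g = _graph_from_edges(3, {(0, 1)})
        out = sample_neighbors(g, 0, 5, np.random.default_rng(0))
        assert out.tolist() == [1] * 5

    def test_exact_mode_returns_full_neighborhood(self):
        g = _graph_from_edges(5, {(0, 1), (0, 2), (0, 4)})
        out = sample_neighbors(g, 0, 50, np.random.default_rng(0), exact=True)
        assert out.tolist() == [1, 2, 4]

    def test_isolated_node_self_fallback(self):
        g = _graph_from_edges(3, {(0, 1)})
        out = sample_neighbors(g, 2, 4, np.random.default_rng(0))
        assert out.tolist() == [2] * 4

    def test_uniformity_binomial_concentration(self):
        g = _graph_from_edges(4, {(0, 1), (0, 2), (0, 3)})
        out = sample_neighbors(g, 0, 300, np.random.default_rng(1))
        counts = np.bincount(out, minlength=4)[1:]
        assert np.all(np.abs(counts - 100) <= 20)

    def test_unknown_node_errors(self):
        g = _graph_from_edges(3, {(0, 1)})
        with pytest.raises(KeyError):
            sample_neighbors(g, 99, 5, np.random.default_rng(0))


class TestAggregators:
    def test_mean_small_example(self):
        assert aggregate_mean([[1.0, 3.0], [3.0, 5.0]]).tolist() == [2.0, 4.0]

    def test_mean_single_vector_identity(self):
        v = np.array([1.5, -2.0, 0.25])
        assert np.array_equal(aggregate_mean([v]), v)

    def test_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        vs = rng.normal(size=(50, 7))
        oracle = sum(vs[i] for i in range(50)) / 50.0
        assert np.allclose(aggregate_mean(vs), oracle, atol=1e-12)

    def test_pool_identity_transforms_reduce_to_max(self):
        out = aggregate_pool([[1.0, 3.0], [3.0, 5.0]])
        assert out.tolist() == [3.0, 5.0]

    def test_pool_single_neighbor_identity(self):
        v = np.array([0.5, -1.0])
        assert np.array_equal(aggregate_pool([v]), v)

    def test_pool_matches_elementwise_max_oracle(self):
        vs = np.random.default_rng(3).normal(size=(20, 5))
        oracle = np.array([max(vs[i][d] for i in range(20)) for d in range(5)])
        assert np.allclose(aggregate_pool(vs), oracle)

    def test_pool_applies_transform_before_max(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = aggregate_pool([[1.0, 3.0], [4.0, 2.0]], pool_W=w)
        assert out.tolist() == [3.0, 4.0]

    def test_pool_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            aggregate_pool([[1.0, 2.0]], pool_W=np.eye(3))

    def test_empty_neighbor_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_mean(np.empty((0, 3)))


class TestForwardLayer:
    def test_identity_weight_and_normalization(self):
        params = LayerParams(W=np.eye(4), sigma=lambda x: x)
        out = forward_layer([1.0, 0.0], [0.0, 1.0], params)
        assert np.allclose(out, [np.sqrt(0.5), 0.0, 0.0, np.sqrt(0.5)])

    def test_output_is_unit_norm(self):
        rng = np.random.default_rng(4)
        params = LayerParams(W=rng.normal(size=(6, 8)))
        out = forward_layer(rng.normal(size=4), rng.normal(size=4), params)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-6)

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(5, 6))
        h_self, h_neigh = rng.normal(size=3), rng.normal(size=3)
        pre = w @ np.concatenate([h_self, h_neigh])
        act = np.maximum(pre, 0.0)
        oracle = act / np.linalg.norm(act)
        out = forward_layer(h_self, h_neigh, LayerParams(W=w))
        assert np.allclose(out, oracle, atol=1e-12)

    def test_nonfinite_input_errors(self):
        params = LayerParams(W=np.eye(4))
        with pytest.raises(FloatingPointError):
            forward_layer([np.nan, 0.0], [0.0, 1.0], params)

    def test_zero_vector_left_zero(self):
        params = LayerParams(W=np.eye(4))  # ReLU kills all-negative input
        out = forward_layer([-1.0, -1.0], [-1.0, -1.0], params)
        assert np.all(out == 0.0)


class TestWalks:
    def test_path_graph_forced_walk(self):
        g = _graph_from_edges(2, {(0, 1)})
        pairs = generate_walk_pairs(g, 3, 5, np.random.default_rng(0)).pairs
        from_zero = pairs[pairs[:, 0] == 0]
        assert set(map(tuple, from_zero)) == {(0, 1)}
        assert set(map(tuple, pairs[pairs[:, 0] == 1])) == {(1, 0)}

    def test_no_self_pairs(self):
        g = _random_graph(15, 0.3, seed=6)
        pairs = generate_walk_pairs(g, 5, 5, np.random.default_rng(1)).pairs
        assert np.all(pairs[:, 0] != pairs[:, 1])

    def test_triangle_walk_neighbor_frequency(self):
        g = _graph_from_edges(3, {(0, 1), (0, 2), (1, 2)})
        pairs = generate_walk_pairs(g, 2000, 2, np.random.default_rng(2)).pairs
        first_steps = pairs[pairs[:, 0] == 0][:, 1]
        freq = np.mean(first_steps == 1)
        assert freq == pytest.approx(0.5, abs=0.05)

    def test_edgeless_graph_errors(self):
        g = _graph_from_edges(3, set())
        with pytest.raises(ValueError, match="edgeless"):
            generate_walk_pairs(g, 2, 3, np.random.default_rng(0))

    def test_pair_count_on_complete_graph(self):
        # on K_4 every step leaves the current node, so each walk of length 5
        # contributes at most 4 pairs and at least 1
        g = _graph_from_edges(4, {(i, j) for i in range(4) for j in range(i + 1, 4)})
        pairs = generate_walk_pairs(g, 10, 5, np.random.default_rng(3)).pairs
        assert 4 * 10 * 1 <= len(pairs) <= 4 * 10 * 4


class TestLoss:
    def test_orthogonal_vectors_give_two_log_two(self):
        # sigma(0) = 1/2 for both the positive and the single negative term
        z = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
        loss = unsupervised_loss(z, v, [np.array([0.0, 1.0])])
        assert loss == pytest.approx(2.0 * np.log(2.0))

    def test_perfect_separation_limit(self):
        z_u = np.array([100.0, 0.0])
        z_v = np.array([1.0, 0.0])
        neg = np.array([-1.0, 0.0])
        assert unsupervised_loss(z_u, z_v, [neg]) == pytest.approx(0.0, abs=1e-8)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(7)
        z_u, z_v = rng.normal(size=8), rng.normal(size=8)
        negs = rng.normal(size=(5, 8))

        def sigmoid(x):
            return 1.0 / (1.0 + np.exp(-x))

        oracle = -np.log(sigmoid(z_u @ z_v))
        for q in range(5):
            oracle -= np.log(sigmoid(-(z_u @ negs[q])))
        assert unsupervised_loss(z_u, z_v, negs) == pytest.approx(oracle, rel=1e-10)

    @given(
        arrays(float, 4, elements=st.floats(-5, 5)),
        arrays(float, 4, elements=st.floats(-5, 5)),
        arrays(float, (3, 4), elements=st.floats(-5, 5)),
    )
    def test_loss_nonnegative(self, z_u, z_v, negs):
        assert unsupervised_loss(z_u, z_v, negs) >= 0.0

    def test_empty_negatives_error(self):
        with pytest.raises(ValueError):
            unsupervised_loss(np.ones(3), np.ones(3), np.empty((0, 3)))


class TestTrainerInternals:
    def test_exhaustive_mean_matches_brute_force(self):
        """Inference-mode layer-1 output equals the per-node aggregate oracle."""
        g = _random_graph(20, 0.3, seed=8)
        cfg = SageConfig(layer_sizes=(6, 4), fanouts=(5, 3), epochs=1, seed=0)
        trainer = _Trainer(g, cfg, np.random.default_rng(0))
        h, _ = trainer.forward(train=False)
        # brute-force recursion of the same two layers with full neighborhoods
        rng = np.random.default_rng(1)
        h_prev = g.features.astype(float)
        for k in range(2):
            out = []
            for v in range(20):
                nbrs = sample_neighbors(g, v, 99, rng, exact=True)
                agg = aggregate_mean(h_prev[nbrs])
                out.append(
                    forward_layer(h_prev[v], agg, LayerParams(W=trainer.W[k]))
                )
            h_prev = np.array(out)
        assert np.allclose(h, h_prev, atol=1e-10)

    @pytest.mark.parametrize("aggregator", ["mean", "pool"])
    def test_analytic_gradient_matches_finite_differences(self, aggregator):
        g = _random_graph(8, 0.5, seed=9)
        cfg = SageConfig(
            layer_sizes=(5, 3), fanouts=(4, 2), epochs=1, dropout=0.0,
            aggregator=aggregator, seed=0,
        )
        trainer = _Trainer(g, cfg, np.random.default_rng(3))
        u = np.array([0, 1, 2])
        v = np.array([3, 4, 5])
        negs = np.array([[6, 7], [7, 6], [5, 0]])

        def loss_value():
            z, _ = trainer.forward(train=False)
            loss, _ = trainer.batch_loss_grad(z, u, v, negs)
            return loss

        z, caches = trainer.forward(train=False)
        _, dz = trainer.batch_loss_grad(z, u, v, negs)
        grads = trainer.backward(dz, caches)
        params = trainer.params()
        eps = 1e-6
        rng = np.random.default_rng(4)
        for p, grad in zip(params, grads):
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up = loss_value()
                p[idx] = orig - eps
                down = loss_value()
                p[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, abs=5e-5)


class TestTraining:
    def test_same_seed_reproduces_embeddings(self, small_graph):
        cfg = SageConfig(layer_sizes=(12, 6), fanouts=(8, 4), epochs=2, seed=5)
        a = train_embeddings(small_graph, cfg)
        b = train_embeddings(small_graph, cfg)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.epoch_losses, b.epoch_losses)

    def test_different_seeds_differ(self, small_graph):
        cfg_a = SageConfig(layer_sizes=(12, 6), fanouts=(8, 4), epochs=2, seed=5)
        cfg_b = SageConfig(layer_sizes=(12, 6), fanouts=(8, 4), epochs=2, seed=6)
        assert not np.array_equal(
            train_embeddings(small_graph, cfg_a).z,
            train_embeddings(small_graph, cfg_b).z,
        )

    def test_pool_aggregator_trains(self, small_graph):
        cfg = SageConfig(
            layer_sizes=(10, 5), fanouts=(6, 3), epochs=2, aggregator="pool", seed=1
        )
        emb = train_embeddings(small_graph, cfg)
        assert emb.z.shape == (small_graph.n_nodes, 5)
        assert np.all(np.isfinite(emb.z))

    def test_embedding_round_trip(self, tmp_path, small_graph):
        cfg = SageConfig(layer_sizes=(8, 4), fanouts=(5, 3), epochs=1, seed=2)
        emb = train_embeddings(small_graph, cfg)
        path = write_embeddings(emb, tmp_path)
        back = read_embeddings(path)
        assert back.roi_ids == emb.roi_ids
        assert np.allclose(back.z, emb.z, atol=1e-8)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(layer_sizes=(10,), fanouts=(5, 3)),
            dict(dropout=1.0),
            dict(batch_size=0),
            dict(learning_rate=0.0),
            dict(aggregator="lstm"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SageConfig(**kwargs)
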