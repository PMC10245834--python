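import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsig.model import (
    Adam,
    ReduceLROnPlateau,
    TrainingConfig,
    extract_attention,
    focal_loss,
    focal_loss_from_logits,
    pretrain_autoencoders,
    train,
)
from microsig.model._hgt import _backward, _forward, _graph_tensors, _init_params
from tests.conftest import TINY_TRAIN


def _softmax(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = _softmax(rng.standard_normal((50, 6)))
        y = rng.integers(0, 6, size=50)
        ce = -np.mean(np.log(p[np.arange(50), y]))
        assert focal_loss(p, y, gamma=0.0) == pytest.approx(ce, abs=1e-10)

    def test_perfect_prediction_zero_loss(self):
        p = np.eye(3)
        assert focal_loss(p, np.arange(3), gamma=2.0) == 0.0

    def test_hand_evaluated_value(self):
        # p_t = 0.3, gamma = 2 -> 0.49 * (-ln 0.3)
        p = np.array([[0.3, 0.7]])
        assert focal_loss(p, np.array([0]), gamma=2.0) == pytest.approx(
            0.49 * -np.log(0.3), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 5.0))
    def test_never_exceeds_cross_entropy(self, seed, gamma):
        rng = np.random.default_rng(seed)
        p = _softmax(rng.standard_normal((20, 4)))
        y = rng.integers(0, 4, size=20)
        assert focal_loss(p, y, gamma) <= focal_loss(p, y, 0.0) + 1e-12

    def test_logit_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((8, 5))
        y = rng.integers(0, 5, size=8)
        _, dz = focal_loss_from_logits(z, y, gamma=2.0)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (7, 4)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (focal_loss_from_logits(zp, y, 2.0)[0]
                   - focal_loss_from_logits(zm, y, 2.0)[0]) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            focal_loss(np.array([[0.5, 0.2]]), np.array([0]), 2.0)


class TestScheduler:
    def test_frozen_metric_halves_after_exactly_patience_epochs(self):
        opt = Adam({"w": np.zeros(1)}, lr=0.003)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=5)
        sched.step(0.5)  # establishes the best
        lrs = [sched.step(0.5) for _ in range(5)]
        assert lrs[:4] == [0.003] * 4
        assert lrs[4] == pytest.approx(0.0015)

    def test_improvement_resets_counter(self):
        opt = Adam({"w": np.zeros(1)}, lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
        sched.step(0.1)
        sched.step(0.1)
        sched.step(0.1)
        sched.step(0.2)  # improvement
        assert [sched.step(0.2) for _ in range(2)] == [1.0, 1.0]
        assert sched.step(0.2) == 0.5  # third bad epoch after reset


class TestAutoencoder:
    def test_embedding_shape_is_config_dim(self, tiny_graph):
        cfg = TrainingConfig(**TINY_TRAIN)
        pre = pretrain_autoencoders(tiny_graph, cfg)
        assert pre.embeddings.shape == (tiny_graph.n_nodes, cfg.embedding_dim)

    def test_reconstruction_improves_over_training(self, tiny_graph):
        pre = pretrain_autoencoders(tiny_graph, TrainingConfig(**TINY_TRAIN))
        assert pre.rec_trace_species[-1] <= pre.rec_trace_species[0]
        assert pre.rec_trace_samples[-1] <= pre.rec_trace_samples[0]
        # the zero predictor reconstructs standardized data with MSE ~= 1
        assert pre.rec_trace_species[-1] < 1.0
        assert pre.rec_trace_samples[-1] < 1.0

    def test_identical_rows_get_identical_embeddings(self, tiny_graph):
        import copy

        g = copy.copy(tiny_graph)
        feats = tiny_graph.species_features.copy()
        feats[1] = feats[0]
        g.species_features = feats
        pre = pretrain_autoencoders(g, TrainingConfig(**TINY_TRAIN))
        assert np.allclose(pre.embeddings[0], pre.embeddings[1], atol=1e-6)


class TestTrainingConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainingConfig(embedding_dim=250, n_heads=8)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            TrainingConfig(epochs=0)


class TestGraphTransformer:
    def test_manual_gradients_match_finite_differences(self, tiny_graph):
        cfg = TrainingConfig(embedding_dim=12, n_hid=8, n_heads=2, n_layers=2,
                             epochs=1, ae_epochs=1, seed=0)
        gt = _graph_tensors(tiny_graph)
        rng = np.random.default_rng(0)
        params = _init_params(cfg, len(gt.classes), rng)
        X0 = rng.standard_normal((tiny_graph.n_nodes, cfg.embedding_dim))
        labels = gt.labels
        idx = np.arange(labels.size)

        def loss_of(p):
            logits, _, _ = _forward(p, X0, gt, cfg)
            return focal_loss_from_logits(logits[idx], labels, 2.0)[0]

        logits, _, cache = _forward(params, X0, gt, cfg)
        loss, dtrain = focal_loss_from_logits(logits[idx], labels, 2.0)
        dlogits = np.zeros_like(logits)
        dlogits[idx] = dtrain
        grads = _backward(params, gt, cfg, cache, dlogits)

        eps = 1e-6
        checks = [("Wq_1_0", (3, 2)), ("Wk_0_1", (5, 1)), ("Wv_0_0", (0, 4)),
                  ("Wo_1_1", (2, 2)), ("Wrk_0_metabolic", (1, 2, 3)),
                  ("Wrm_1_ab_species_to_sample", (0, 1, 1)),
                  ("mu_0_ab_species_to_sample", (1,)), ("Win_0", (4, 3)),
                  ("bin_1", (2,)), ("Wc", (3, 1)), ("bc", (0,))]
        for name, idx_ in checks:
            p2 = {k: v.copy() for k, v in params.items()}
            p2[name][idx_] += eps
            up = loss_of(p2)
            p2[name][idx_] -= 2 * eps
            down = loss_of(p2)
            num = (up - down) / (2 * eps)
            assert grads[name][idx_] == pytest.approx(num, rel=1e-4, abs=1e-8), name

    def test_seeded_determinism(self, tiny_graph):
        cfg = TrainingConfig(**TINY_TRAIN)
        m1 = train(tiny_graph, cfg)
        m2 = train(tiny_graph, cfg)
        assert m1.loss_trace == m2.loss_trace
        for a1, a2 in zip(m1.attention_layers, m2.attention_layers):
            assert np.array_equal(a1, a2)

    def test_probability_rows_sum_to_one(self, tiny_model):
        p = tiny_model.predict_proba()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_normalized_per_target_per_head(self, tiny_model, tiny_graph):
        for a in tiny_model.attention_layers:
            sums = np.zeros((tiny_graph.n_nodes, a.shape[1]))
            np.add.at(sums, tiny_model.edge_tgt, a)
            has_in = np.zeros(tiny_graph.n_nodes, dtype=bool)
            has_in[tiny_model.edge_tgt] = True
            assert np.allclose(sums[has_in], 1.0, atol=1e-6)

    def test_lr_trace_follows_plateau_schedule(self, tiny_model):
        cfg = tiny_model.config
        lrs = tiny_model.lr_trace
        assert lrs[0] == cfg.learning_rate
        # any reduction must be by exactly lr_factor
        for prev, cur in zip(lrs, lrs[1:]):
            assert cur == pytest.approx(prev) or cur == pytest.approx(prev * cfg.lr_factor)

    def test_fewer_than_two_classes_rejected(self, tiny_graph):
        import copy

        g = copy.copy(tiny_graph)
        g.sample_labels = ["X"] * g.n_samples
        with pytest.raises(ValueError, match="2 cancer types"):
            train(g, TrainingConfig(**TINY_TRAIN))


class TestExtractAttention:
    def test_single_neighbor_sample_gets_full_attention(self, tiny_dataset):
        import pandas as pd

        from microsig import io, preprocess
        from microsig.graphs import assemble_hetero_graph

        # sample S-only: one species present -> softmax over one element
        values = np.array([[1.0, 2.0, 0.0], [0.0, 3.0, 1.0]])
        m = io.AbundanceMatrix([1, 2], ["s1", "s2", "s3"], values)
        norm = preprocess.normalize_tss(m)
        meta = io.SampleMetadata(pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "cancer_type": ["A", "B", "A"]}))
        g = assemble_hetero_graph(norm, meta, [], [])
        cfg = TrainingConfig(embedding_dim=8, n_hid=8, n_heads=2, n_layers=1,
                             epochs=2, ae_epochs=5, seed=0, val_fraction=0.34)
        model = train(g, cfg)
        att = extract_attention(model, g)
        assert att.scores[0, 0] == pytest.approx(1.0, abs=1e-6)  # s1 sees only species 1
        assert att.scores[1, 2] == pytest.approx(1.0, abs=1e-6)  # s3 sees only species 2
        assert att.scores[1, 0] == 0.0  # non-adjacent pair stays zero

    def test_mean_over_heads_matches_direct_indexing(self, tiny_model, tiny_graph):
        att = extract_attention(tiny_model, tiny_graph, layer=-1)
        sl = tiny_model.rel_slices["ab_species_to_sample"]
        a = tiny_model.attention_layers[-1][sl]
        sp = tiny_model.edge_src[sl]
        sa = tiny_model.edge_tgt[sl] - tiny_graph.n_species
        expected = np.zeros_like(att.scores)
        expected[sp, sa] = a.mean(axis=1)
        assert np.allclose(att.scores, expected, atol=0)

    def test_average_layers_is_mean_of_per_layer_matrices(self, tiny_model, tiny_graph):
        per_layer = [extract_attention(tiny_model, tiny_graph, layer=l).scores
                     for l in range(len(tiny_model.attention_layers))]
        avg = extract_attention(tiny_model, tiny_graph, average_layers=True).scores
        assert np.allclose(avg, np.mean(per_layer, axis=0), atol=1e-12)

    def test_layer_out_of_range_rejected(self, tiny_model, tiny_graph):
        with pytest.raises(IndexError, match="out of range"):
            extract_attention(tiny_model, tiny_graph, layer=5)
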