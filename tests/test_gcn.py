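"""Graph network: convolution, TopK pooling, readout, training contracts."""

import numpy as np
import pytest

from szgcn.gcn import (
    ModelConfig,
    TrainConfig,
    _batch_forward,
    _cross_entropy,
    _graph_backward,
    _head_backward,
    init_params,
    predict_proba,
    train,
)
from szgcn.graphs import BrainGraphSample, GraphTypeSpec
from szgcn.nn import graph_conv, normalized_adjacency, readout, topk_pool

SPEC3 = GraphTypeSpec(12, "FBM", "sMRI", 0.5)
SPEC6 = GraphTypeSpec(12, "FBM", "sMRI+fMRI", 0.5)


def _random_adjacency(rng, n, p=0.4):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


def _sample(rng, n=12, f=6, label=0, sid="s0"):
    spec = SPEC6 if f == 6 else SPEC3
    return BrainGraphSample(
        _random_adjacency(rng, n), rng.normal(size=(n, f)), label, sid, spec
    )


def _dense_conv_reference(H, A, W):
    """Independent elementwise evaluation of the propagation rule."""
    n = A.shape[0]
    a_tilde = A + np.eye(n)
    deg = [sum(a_tilde[i, j] for j in range(n)) for i in range(n)]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = a_tilde[i, j] / np.sqrt(deg[i] * deg[j])
    out = S @ H @ W
    return np.where(out > 0, out, 0.0)


class TestGraphConv:
    def test_matches_dense_reference_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d, d2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            A = _random_adjacency(rng, n)
            H = rng.normal(size=(n, d))
            W = rng.normal(size=(d, d2))
            assert np.allclose(
                graph_conv(H, A, W), _dense_conv_reference(H, A, W), atol=1e-6
            )

    def test_edgeless_graph_reduces_to_relu_linear(self, rng):
        H = rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 4))
        assert np.allclose(
            graph_conv(H, np.zeros((5, 5)), W), np.maximum(H @ W, 0.0)
        )

    def test_complete_graph_constant_rows_stay_constant(self, rng):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        H = np.tile(rng.normal(size=3), (n, 1))
        out = graph_conv(H, A, rng.normal(size=(3, 4)))
        assert np.allclose(out, out[0])

    def test_propagation_matrix_symmetric_bounded_spectrum(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            S = normalized_adjacency(_random_adjacency(rng, n))
            assert np.allclose(S, S.T)
            assert np.abs(np.linalg.eigvalsh(S)).max() <= 1.0 + 1e-10


def _brute_force_topk(H, A, p, ratio):
    """Score, sort, slice, gate, induce-subgraph — all by explicit steps."""
    norm = np.sqrt(sum(x * x for x in p))
    y = [sum(H[i, d] * p[d] for d in range(H.shape[1])) / norm
         for i in range(H.shape[0])]
    k = int(np.ceil(ratio * H.shape[0]))
    order = sorted(range(len(y)), key=lambda i: (-y[i], i))[:k]
    Hp = np.array([[H[i, d] * np.tanh(y[i]) for d in range(H.shape[1])]
                   for i in order])
    Ap = np.array([[A[i, j] for j in order] for i in order])
    return Hp, Ap, np.array(order), np.array(y)


class TestTopKPool:
    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d = int(rng.integers(1, 5))
            H = rng.normal(size=(n, d))
            A = _random_adjacency(rng, n)
            p = rng.normal(size=d)
            ratio = float(rng.uniform(0.2, 1.0))
            Hp, Ap, idx, y = topk_pool(H, A, p, ratio)
            Hr, Ar, idxr, yr = _brute_force_topk(H, A, p, ratio)
            assert np.array_equal(idx, idxr)
            assert np.allclose(Hp, Hr)
            assert np.allclose(Ap, Ar)
            assert np.allclose(y, yr)

    def test_single_feature_projection_selects_column_maxima(self, rng):
        H = np.array([[1.0, 9.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0]])
        p = np.array([0.0, 2.0])  # score = column 1
        _, _, idx, _ = topk_pool(H, np.zeros((4, 4)), p, 0.5)
        assert list(idx) == [0, 2]

    def test_all_equal_scores_tie_break_by_index(self):
        H = np.ones((5, 3))
        _, _, idx, _ = topk_pool(H, np.zeros((5, 5)), np.ones(3), 0.6)
        assert list(idx) == [0, 1, 2]

    def test_projection_scale_invariant_scores(self, rng):
        H = rng.normal(size=(6, 4))
        p = rng.normal(size=4)
        _, _, _, y1 = topk_pool(H, np.zeros((6, 6)), p, 0.5)
        _, _, _, y2 = topk_pool(H, np.zeros((6, 6)), 7.3 * p, 0.5)
        assert np.allclose(y1, y2)

    def test_zero_projection_rejected(self, rng):
        with pytest.raises(ValueError, match="non-zero"):
            topk_pool(rng.normal(size=(4, 2)), np.zeros((4, 4)), np.zeros(2), 0.5)


class TestReadout:
    def test_single_node(self):
        H = np.array([[1.0, -2.0, 3.0]])
        assert np.allclose(readout(H), [1.0, -2.0, 3.0, 1.0, -2.0, 3.0])

    def test_permutation_invariance(self, rng):
        H = rng.normal(size=(7, 4))
        perm = rng.permutation(7)
        assert np.allclose(readout(H), readout(H[perm]))

    def test_hand_computed_toy(self):
        H = np.array([[1.0, 4.0], [3.0, 0.0], [2.0, 2.0]])
        assert np.allclose(readout(H), [3.0, 4.0, 2.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            readout(np.zeros((0, 3)))


class TestForward:
    def test_survivor_counts_ceil_chain(self):
        assert ModelConfig().survivor_counts(90) == [72, 58, 47]
        assert ModelConfig().survivor_counts(246) == [197, 158, 127]

    def test_saliency_floor_guard(self):
        ModelConfig().check_saliency_floor(90)
        with pytest.raises(ValueError, match="saliency"):
            ModelConfig(pool_ratio=0.3).check_saliency_floor(90)

    def _tiny_model(self, rng, f=6, hidden=8):
        from szgcn.gcn import TrainedModel

        cfg = ModelConfig(hidden_dim=hidden, dropout=0.0)
        params, bn = init_params(f, cfg, rng)
        return TrainedModel(params, bn, cfg, TrainConfig(), [{"epoch": 0}], 0, f)

    def test_output_length_two_and_deterministic(self, rng):
        from szgcn.gcn import forward

        model = self._tiny_model(rng)
        s = _sample(rng)
        out1, out2 = forward(model, s), forward(model, s)
        assert out1.shape == (2,)
        assert np.array_equal(out1, out2)

    def test_permutation_invariance_tie_free(self, rng):
        from szgcn.gcn import forward

        model = self._tiny_model(rng)
        s = _sample(rng)
        perm = rng.permutation(12)
        permuted = BrainGraphSample(
            s.adjacency[np.ix_(perm, perm)], s.features[perm], s.label, "sp", s.spec
        )
        assert np.allclose(forward(model, s), forward(model, permuted), atol=1e-8)

    def test_predict_proba_is_softmax_of_logits(self, rng):
        from szgcn.gcn import forward

        model = self._tiny_model(rng)
        samples = [_sample(rng, sid=f"s{i}") for i in range(3)]
        proba = predict_proba(model, samples)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.all((proba > 0) & (proba < 1))
        for i, s in enumerate(samples):
            logits = forward(model, s)
            e = np.exp(logits - logits.max())
            assert np.allclose(proba[i], e / e.sum())


class TestGradients:
    @pytest.mark.parametrize("use_bn", [True, False])
    def test_analytic_gradients_match_finite_differences(self, rng, use_bn):
        cfg = ModelConfig(hidden_dim=4, dropout=0.0, use_batchnorm=use_bn)
        samples = [_sample(rng, n=7, f=3, label=i % 2, sid=f"s{i}") for i in range(4)]
        labels = np.array([s.label for s in samples])
        params, bn = init_params(3, cfg, rng)
        for key in params:
            if params[key].ndim:
                params[key] = params[key] * 3.0  # move away from dead ReLUs

        def loss_at(params):
            bn2 = {k: v.copy() for k, v in bn.items()}
            logits, _, _ = _batch_forward(params, bn2, samples, cfg, True, None)
            return _cross_entropy(logits, labels)[0]

        bn2 = {k: v.copy() for k, v in bn.items()}
        logits, gcaches, hcache = _batch_forward(params, bn2, samples, cfg, True, None)
        _, dlogits = _cross_entropy(logits, labels)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dG = _head_backward(params, hcache, dlogits, cfg, grads)
        for i, cache in enumerate(gcaches):
            _graph_backward(params, cache, dG[i], grads)

        eps = 1e-6
        check = np.random.default_rng(0)
        for key, grad in grads.items():
            if use_bn and key == "bf1":
                continue  # bias before batch-norm: true gradient is zero
            flat = grad.ravel()
            picks = check.choice(flat.size, size=min(4, flat.size), replace=False)
            for pos in picks:
                idx = np.unravel_index(pos, grad.shape)
                orig = params[key][idx]
                params[key][idx] = orig + eps
                lp = loss_at(params)
                params[key][idx] = orig - eps
                lm = loss_at(params)
                params[key][idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), key


class TestTraining:
    def _separable_dataset(self, rng, n_subjects=20, n=12):
        """Label carried by feature column 0: trivially learnable."""
        samples = []
        for i in range(n_subjects):
            label = i % 2
            feats = rng.normal(size=(n, 3)) * 0.3
            feats[:, 0] += 2.0 * label - 1.0
            samples.append(
                BrainGraphSample(_random_adjacency(rng, n), feats, label, f"s{i}", SPEC3)
            )
        return samples

    def test_learns_separable_labels(self, rng):
        ds = self._separable_dataset(rng)
        ids = [s.subject_id for s in ds]
        model = train(
            ds, ids,
            ModelConfig(hidden_dim=8, dropout=0.0),
            TrainConfig(learning_rate=1e-3, max_epochs=120, patience=120, seed=0),
        )
        proba = predict_proba(model, ds)[:, 1]
        labels = np.array([s.label for s in ds])
        acc = ((proba >= 0.5).astype(int) == labels).mean()
        assert acc >= 0.9

    def test_training_deterministic(self, rng):
        ds = self._separable_dataset(rng, n_subjects=12)
        ids = [s.subject_id for s in ds]
        cfg_m = ModelConfig(hidden_dim=4)
        cfg_t = TrainConfig(max_epochs=10, patience=10, seed=42)
        m1 = train(ds, ids, cfg_m, cfg_t)
        m2 = train(ds, ids, cfg_m, cfg_t)
        for key in m1.params:
            assert np.array_equal(m1.params[key], m2.params[key]), key
        assert [l["val_loss"] for l in m1.log] == [l["val_loss"] for l in m2.log]

    def test_zero_patience_returns_best_so_far(self, rng):
        ds = self._separable_dataset(rng, n_subjects=12)
        ids = [s.subject_id for s in ds]
        model = train(
            ds, ids, ModelConfig(hidden_dim=4),
            TrainConfig(max_epochs=50, patience=0, seed=1),
        )
        val = [l["val_loss"] for l in model.log]
        # stopped at the first non-improving epoch, best weights kept
        assert model.best_epoch == int(np.argmin(val))
        assert len(val) <= 50
        improving = [val[i] < min(val[:i]) for i in range(1, len(val))]
        if len(val) < 50:
            assert not improving[-1]

    def test_degenerate_class_balance_rejected(self, rng):
        ds = self._separable_dataset(rng, n_subjects=12)
        one_class = [s for s in ds if s.label == 0]
        with pytest.raises(ValueError, match="per class"):
            train(one_class, [s.subject_id for s in one_class])

    def test_log_records_every_epoch(self, rng):
        ds = self._separable_dataset(rng, n_subjects=12)
        ids = [s.subject_id for s in ds]
        model = train(ds, ids, ModelConfig(hidden_dim=4),
                      TrainConfig(max_epochs=7, patience=7, seed=3))
        assert [l["epoch"] for l in model.log] == list(range(7))
        assert all(np.isfinite(l["train_loss"]) for l in model.log)
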