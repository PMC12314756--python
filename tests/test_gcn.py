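import numpy as np
import pytest
import scipy.sparse as sp

from treescreen.gcn import (
    GCNParams,
    TrainConfig,
    classify_nodes,
    detection_loss,
    gcn_forward,
    init_params,
    loss_and_grads,
    predict,
    train_detector,
)
from treescreen.graph import UNLABELED, adjacency, build_semantic_graph


def _two_vertex_setup():
    g = build_semantic_graph(np.array([[1]]))  # one image, one feature
    A_hat = adjacency(g).A_hat
    return g, A_hat


def _fixture_graph():
    """6-vertex bipartite fixture: 3 images x 3 features."""
    Z = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
    labels = np.array([1, 0, 0], dtype=np.int8)
    g = build_semantic_graph(Z, labels=labels)
    return g, adjacency(g).A_hat


class TestForward:
    def test_zero_input_gives_zero_output(self):
        _, A_hat = _two_vertex_setup()
        params = GCNParams(
            conv_weights=[np.ones((3, 2))],
            head_weight=np.ones((2, 2)),
            head_bias=np.zeros(2),
        )
        H = gcn_forward(np.zeros((2, 3)), A_hat, params)
        assert np.all(H == 0)

    def test_hand_computed_single_layer(self):
        """2 vertices, 1 edge, X=[1,2]^T, W=[1]: A_hat swaps and ReLU keeps
        [2,1]^T."""
        _, A_hat = _two_vertex_setup()
        params = GCNParams(
            conv_weights=[np.array([[1.0]])],
            head_weight=np.zeros((2, 1)),
            head_bias=np.zeros(2),
        )
        H = gcn_forward(np.array([[1.0], [2.0]]), A_hat, params)
        assert np.allclose(H, [[2.0], [1.0]])

    def test_default_depth_is_two(self):
        cfg = TrainConfig()
        assert cfg.n_layers == 2
        params = init_params(5, cfg, np.random.default_rng(0))
        assert params.n_layers == 2

    def test_dimension_mismatch_raises(self):
        _, A_hat = _two_vertex_setup()
        params = GCNParams(
            conv_weights=[np.ones((4, 2))],
            head_weight=np.ones((2, 2)),
            head_bias=np.zeros(2),
        )
        with pytest.raises(ValueError):
            gcn_forward(np.zeros((2, 3)), A_hat, params)


class TestClassify:
    def _head(self):
        return GCNParams(
            conv_weights=[],
            head_weight=np.eye(2),
            head_bias=np.zeros(2),
        )

    def test_tie_goes_to_class_zero(self):
        p1, hard = classify_nodes(np.zeros((3, 2)), self._head())
        assert np.allclose(p1, 0.5)
        assert hard.tolist() == [0, 0, 0]

    def test_softmax_arithmetic(self):
        # logits (0, ln 3) -> P(class 1) = 3/4
        H = np.array([[0.0, np.log(3.0)]])
        p1, hard = classify_nodes(H, self._head())
        assert p1[0] == pytest.approx(0.75)
        assert hard[0] == 1

    def test_probabilities_normalized(self, rng):
        H = rng.normal(size=(20, 2))
        params = self._head()
        logits = H @ params.head_weight.T + params.head_bias
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        p1, _ = classify_nodes(H, params)
        assert np.allclose(p1, probs[:, 1])
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            classify_nodes(np.array([[np.inf, 0.0]]), self._head())


class TestDetectionLoss:
    def test_unit_weight_is_plain_bce(self, rng):
        y = rng.integers(0, 2, 30)
        p = rng.uniform(0.05, 0.95, 30)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert detection_loss(p, y, w_c=1.0) == pytest.approx(expected)

    def test_positive_term_weighting(self):
        # single positive at p=0.5, w_c=7 -> 7 log 2
        assert detection_loss(
            np.array([0.5]), np.array([1]), w_c=7.0
        ) == pytest.approx(7 * np.log(2))

    def test_perfect_prediction_near_zero(self):
        y = np.array([1, 0, 1])
        p = np.array([1.0, 0.0, 1.0])
        assert detection_loss(p, y, w_c=7.0) < 1e-9

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            detection_loss(np.array([]), np.array([]), w_c=7.0)

    def test_weight_scales_only_positive_term(self, rng):
        """Doubling w_c adds exactly the positive-term mass once more."""
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.05, 0.95, 50)
        l1 = detection_loss(p, y, w_c=1.0)
        l2 = detection_loss(p, y, w_c=2.0)
        pos_mass = -np.mean(y * np.log(p))
        assert l2 - l1 == pytest.approx(pos_mass)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Full-model gradient check on the 6-vertex fixture (<1e-4 rel)."""
        g, A_hat = _fixture_graph()
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        cfg = TrainConfig(hidden_dims=(3,), n_layers=2)
        params = init_params(4, cfg, rng)
        train_idx = np.array([0, 1, 2])
        y = np.array([1, 0, 0])
        _, grads = loss_and_grads(X, A_hat, params, train_idx, y, w_c=7.0)
        flat = params.flat()
        eps = 1e-6
        for arr, grad in zip(flat, grads):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_and_grads(X, A_hat, params, train_idx, y, 7.0)[0]
                arr[idx] = orig - eps
                lm = loss_and_grads(X, A_hat, params, train_idx, y, 7.0)[0]
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grad[idx]), 1e-8)
                assert abs(grad[idx] - fd) / denom < 1e-4


class TestStructure:
    def test_layer1_image_rows_depend_only_on_features(self):
        """Without self-loops, one hop on a bipartite graph means image
        representations aggregate feature vertices only."""
        g, A_hat = _fixture_graph()
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        params = GCNParams(
            conv_weights=[rng.normal(size=(4, 3))],
            head_weight=rng.normal(size=(2, 3)),
            head_bias=np.zeros(2),
        )
        H1 = gcn_forward(X, A_hat, params)
        X_zeroed = X.copy()
        X_zeroed[:3] = 0.0  # zero all image rows
        H1_zeroed = gcn_forward(X_zeroed, A_hat, params)
        assert np.allclose(H1[:3], H1_zeroed[:3])

    def test_prediction_equivariant_to_image_permutation(self):
        """Permuting image rows permutes predictions identically."""
        rng = np.random.default_rng(2)
        Z = (rng.random((8, 5)) < 0.4).astype(int)
        labels = np.zeros(8, dtype=np.int8)
        labels[:2] = 1
        g = build_semantic_graph(Z, labels=labels)
        X = rng.normal(size=(13, 6))
        cfg = TrainConfig(hidden_dims=(4,), epochs=30, seed=5)
        train_mask = np.ones(8, dtype=bool)
        params, _ = train_detector(g, X, train_mask, cfg)
        p1, _ = predict(g, X, params)

        perm = rng.permutation(8)
        Zp = Z[perm]
        gp = build_semantic_graph(Zp, labels=labels[perm])
        Xp = np.vstack([X[:8][perm], X[8:]])
        p1p, _ = predict(gp, Xp, params)
        assert np.allclose(p1p, p1[perm], atol=1e-10)


class TestTraining:
    def _training_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        # planted: images with feature 0 are positive
        Z = np.zeros((20, 6), dtype=int)
        Z[:, 1:] = rng.random((20, 5)) < 0.3
        Z[:6, 0] = 1
        labels = np.zeros(20, dtype=np.int8)
        labels[:6] = 1
        g = build_semantic_graph(Z, labels=labels)
        X = rng.normal(size=(26, 8))
        return g, X, labels

    def test_loss_trace_decreases_after_smoothing(self):
        g, X, _ = self._training_setup()
        cfg = TrainConfig(hidden_dims=(8,), epochs=120, seed=1)
        _, trace = train_detector(g, X, np.ones(20, dtype=bool), cfg)
        smooth = np.convolve(trace, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_deterministic_given_seed(self):
        g, X, _ = self._training_setup()
        cfg = TrainConfig(hidden_dims=(4,), epochs=40, seed=3)
        mask = np.ones(20, dtype=bool)
        pa, _ = train_detector(g, X, mask, cfg)
        pb, _ = train_detector(g, X, mask, cfg)
        for a, b in zip(pa.flat(), pb.flat()):
            assert np.array_equal(a, b)

    def test_fits_separable_training_data(self):
        g, X, labels = self._training_setup()
        cfg = TrainConfig(hidden_dims=(8,), epochs=200, seed=2)
        params, _ = train_detector(g, X, np.ones(20, dtype=bool), cfg)
        _, hard = predict(g, X, params)
        assert (hard == labels).mean() >= 0.9

    def test_empty_mask_rejected(self):
        g, X, _ = self._training_setup()
        with pytest.raises(ValueError):
            train_detector(g, X, np.zeros(20, dtype=bool), TrainConfig())

    def test_unlabeled_training_vertex_rejected(self):
        g, X, _ = self._training_setup()
        g.labels[:] = UNLABELED
        with pytest.raises(ValueError):
            train_detector(g, X, np.ones(20, dtype=bool), TrainConfig())
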