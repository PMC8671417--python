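import math

import numpy as np
import pytest

from subnet_attn import (
    AttentionModel,
    RepresentationTensor,
    SampleLabels,
    TrainConfig,
    attention_forward,
    certainty,
    decide,
    loss_and_grad,
    predict,
    train,
)


def _rep(probs, sample_ids=None, class_set=None):
    probs = np.asarray(probs, dtype=float)
    n, T, k = probs.shape
    return RepresentationTensor(
        sample_ids or [f"S{i}" for i in range(n)],
        [f"N_{t}" for t in range(T)],
        class_set or [f"C{j}" for j in range(k)],
        probs,
        probs.copy(),
    )


class TestCertainty:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], math.log(0.5)),
            ([1.0, 0.0], 0.0),
            ([0.9, 0.1], 0.9 * math.log(0.9) + 0.1 * math.log(0.1)),
        ],
    )
    def test_negative_entropy_values(self, p, expected):
        rep = _rep([[p]])
        assert certainty(rep)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_always_nonpositive(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=(20, 3))
        assert (certainty(_rep(p)) <= 1e-15).all()


class TestAttentionForward:
    def test_zero_weights_give_uniform_attention(self):
        C = np.array([[-0.3, -0.7, -0.1]])
        H = attention_forward(np.zeros((3, 3)), C)
        np.testing.assert_allclose(H, np.full((1, 3), 1 / 3))

    def test_softmax_arithmetic(self):
        # W C' = (ln 2, 0) -> H = (2/3, 1/3)
        C = np.array([[1.0, 0.0]])
        W = np.array([[math.log(2.0), 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(attention_forward(W, C), [[2 / 3, 1 / 3]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(7, 4))
        W = rng.normal(size=(4, 4))
        np.testing.assert_allclose(attention_forward(W, C).sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_forward(np.zeros((3, 3)), np.zeros((2, 4)))


class TestDecide:
    def test_one_hot_attention_selects_subnetwork(self):
        rep = _rep([[[0.2, 0.8], [0.7, 0.3]]])
        H = np.array([[0.0, 1.0]])
        result = decide(H, rep)
        np.testing.assert_allclose(result.d[0], [0.7, 0.3])

    def test_symmetric_example(self):
        rep = _rep([[[1.0, 0.0], [0.0, 1.0]]])
        result = decide(np.array([[0.5, 0.5]]), rep)
        np.testing.assert_allclose(result.d[0], [0.5, 0.5])
        np.testing.assert_allclose(result.f[0], [0.5, 0.5])

    def test_f_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(3), size=(10, 5))
        rep = _rep(p)
        H = rng.dirichlet(np.ones(5), size=10)
        result = decide(H, rep)
        np.testing.assert_allclose(result.f.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        rep = _rep(np.full((2, 3, 2), 0.5))
        with pytest.raises(ValueError):
            decide(np.full((2, 4), 0.25), rep)


class TestGradients:
    @pytest.mark.parametrize("loss", ["cross_entropy", "squared_hinge", "mape"])
    def test_analytic_matches_finite_differences(self, loss):
        """Central finite differences agree with the analytic dL/dW to 1e-5."""
        rng = np.random.default_rng(3)
        n, T, k = 6, 3, 2
        P = rng.dirichlet(np.ones(k), size=(n, T))
        C = np.where(P > 0, P * np.log(P), 0.0).sum(axis=2)
        Y = np.eye(k)[rng.integers(k, size=n)]
        W = rng.normal(scale=0.5, size=(T, T))
        _, grad = loss_and_grad(W, C, P, Y, loss)
        eps = 1e-6
        num = np.zeros_like(W)
        for i in range(T):
            for j in range(T):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                lp, _ = loss_and_grad(Wp, C, P, Y, loss)
                lm, _ = loss_and_grad(Wm, C, P, Y, loss)
                num[i, j] = (lp - lm) / (2 * eps)
        # atol for O(1) gradients (CE, hinge); rtol covers MAPE, whose eps-floored
        # zero targets inflate gradient magnitudes far above 1
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-5)


def _planted_dataset(n=200, T=4, seed=0):
    """One informative subnetwork whose distribution matches the labels."""
    rng = np.random.default_rng(seed)
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    probs = np.empty((n, T, 2))
    for m, lab in enumerate(labels):
        good = 0.9 if lab == "B" else 0.1
        probs[m, 0] = [1 - good, good]
        for t in range(1, T):
            u = rng.uniform(0.35, 0.65)
            probs[m, t] = [u, 1 - u]
    ids = [f"S{i:03d}" for i in range(n)]
    return _rep(probs, sample_ids=ids, class_set=["A", "B"]), SampleLabels(ids, labels)


class TestTrain:
    def test_recovers_informative_subnetwork(self):
        rep, labels = _planted_dataset()
        model = train(rep, labels, TrainConfig(seed=5))
        _, H = predict(model, rep)
        mean_attention = H.mean(axis=0)
        assert np.argmax(mean_attention) == 0

    def test_deterministic_given_seed(self):
        rep, labels = _planted_dataset()
        cfg = TrainConfig(seed=9, epochs=50)
        w1 = train(rep, labels, cfg).W
        w2 = train(rep, labels, cfg).W
        np.testing.assert_array_equal(w1, w2)

    def test_single_class_rejected(self):
        rep, labels = _planted_dataset(n=20)
        mono = SampleLabels(labels.sample_ids, ["A"] * 20)
        with pytest.raises(ValueError):
            train(rep, mono)

    def test_instance_wise_attention(self):
        """Samples with different certainty profiles get different attention."""
        rep, labels = _planted_dataset(n=50, seed=2)
        model = train(rep, labels, TrainConfig(seed=1, epochs=100))
        _, H = predict(model, rep)
        assert np.std(H, axis=0).max() > 1e-6


class TestPredict:
    def test_uniform_representation_gives_uniform_decision(self):
        probs = np.full((3, 4, 2), 0.5)
        rep = _rep(probs)
        model = AttentionModel(
            np.zeros((4, 4)), rep.subnetwork_ids, rep.class_set, TrainConfig()
        )
        result, H = predict(model, rep)
        np.testing.assert_allclose(result.f, 0.5)
        np.testing.assert_allclose(H, 0.25)

    def test_save_load_round_trip(self, tmp_path):
        rep, labels = _planted_dataset(n=30, seed=4)
        model = train(rep, labels, TrainConfig(seed=2, epochs=30))
        path = tmp_path / "model.json"
        model.save(str(path))
        back = AttentionModel.load(str(path))
        np.testing.assert_allclose(back.W, model.W)
        assert back.subnetwork_ids == model.subnetwork_ids
        r1, h1 = predict(model, rep)
        r2, h2 = predict(back, rep)
        np.testing.assert_allclose(r1.f, r2.f)
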