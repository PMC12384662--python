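"""Unit and property tests for the capsule-network core: squash,
routing-by-agreement (against an independent loop oracle), margin loss,
architecture shapes, and end-to-end differentiability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microcaps.autograd import Adam
from microcaps.capsnet import (
    MarginLossParams,
    MicroCapsNet,
    ModelConfig,
    class_probabilities,
    dynamic_routing,
    margin_loss,
    predict_class,
    squash,
)


# -- squash -------------------------------------------------------------------


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_allclose(squash(np.zeros(4)), np.zeros(4), atol=1e-7)

    @pytest.mark.parametrize(
        "vec, expected_norm",
        [(np.array([1.0, 0.0]), 0.5), (np.array([3.0, 0.0]), 0.9)],
    )
    def test_known_norms(self, vec, expected_norm):
        out = squash(vec)
        assert np.linalg.norm(out) == pytest.approx(expected_norm, abs=1e-7)

    def test_unit_direction_scaled(self):
        out = squash(np.array([3.0, 0.0]))
        np.testing.assert_allclose(out, [0.9, 0.0], atol=1e-7)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            squash(np.array([np.inf, 0.0]))

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_norm_below_one_and_direction_preserved(self, values):
        s = np.array(values)
        out = squash(s)
        assert np.linalg.norm(out) < 1.0
        norm = np.linalg.norm(s)
        if norm > 1e-6:
            cos = out @ s / (np.linalg.norm(out) * norm)
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_output_norm_increasing_in_input_norm(self):
        direction = np.array([0.6, 0.8])
        norms = [np.linalg.norm(squash(k * direction)) for k in np.linspace(0.1, 10, 40)]
        assert np.all(np.diff(norms) > 0)


# -- routing ------------------------------------------------------------------


def routing_oracle(u_hat, r):
    """Independent straight-loop transcription of routing-by-agreement."""
    n, k, d = u_hat.shape
    b = np.zeros((n, k))
    v = np.zeros((k, d))
    for it in range(r):
        c = np.zeros_like(b)
        for i in range(n):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        for j in range(k):
            s = np.zeros(d)
            for i in range(n):
                s += c[i, j] * u_hat[i, j]
            nrm2 = (s**2).sum()
            v[j] = (nrm2 / (1 + nrm2)) * s / np.sqrt(nrm2 + 1e-16)
        if it < r - 1:
            for i in range(n):
                for j in range(k):
                    b[i, j] += u_hat[i, j] @ v[j]
    return v, c


class TestDynamicRouting:
    def test_single_iteration_uniform_coupling(self):
        # zero logits -> c_ij = 1/K for every pair, so s_j = (1/K) sum_i u_hat_ij
        u_hat = np.random.default_rng(0).normal(size=(4, 2, 3))
        v, state = dynamic_routing(u_hat, r=1, return_state=True)
        np.testing.assert_allclose(state["c"], 0.5)
        expected = squash(0.5 * u_hat.sum(axis=0))
        np.testing.assert_allclose(v, expected, atol=1e-10)

    def test_identical_predictions_keep_direction(self):
        # when every primary capsule predicts the same vector, the weighted
        # sum is a positive multiple of it at every iteration count
        rng = np.random.default_rng(3)
        one = rng.normal(size=(2, 3))
        u_hat = np.tile(one, (5, 1, 1))
        np.testing.assert_allclose(
            dynamic_routing(u_hat, r=1), squash(2.5 * one), atol=1e-10
        )
        for r in (2, 4):
            v = dynamic_routing(u_hat, r=r)
            for j in range(2):
                cos = v[j] @ one[j] / (
                    np.linalg.norm(v[j]) * np.linalg.norm(one[j])
                )
                assert cos == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        k = rng.integers(2, 4)
        d = rng.integers(2, 5)
        r = rng.integers(1, 5)
        u_hat = rng.normal(size=(n, k, d))
        v, state = dynamic_routing(u_hat, r=int(r), return_state=True)
        v_ref, c_ref = routing_oracle(u_hat, int(r))
        np.testing.assert_allclose(v, v_ref, atol=1e-6)
        np.testing.assert_allclose(state["c"], c_ref, atol=1e-6)

    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_coupling_coefficients_normalized(self, r):
        u_hat = np.random.default_rng(7).normal(size=(6, 3, 4))
        _, state = dynamic_routing(u_hat, r=r, return_state=True)
        np.testing.assert_allclose(state["c"].sum(axis=1), 1.0, atol=1e-6)

    def test_rejects_zero_iterations(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((2, 2, 2)), r=0)


# -- class probabilities and margin loss --------------------------------------


class TestClassProbabilities:
    def test_lengths_of_axis_aligned_capsules(self):
        v = np.zeros((2, 16))
        v[0, 0], v[1, 0] = 0.9, 0.1
        lengths = class_probabilities(v)
        np.testing.assert_allclose(lengths, [0.9, 0.1])
        assert predict_class(lengths) == 0

    def test_all_zero_ties_break_low(self):
        lengths = class_probabilities(np.zeros((3, 16)))
        np.testing.assert_allclose(lengths, 0.0)
        assert predict_class(lengths) == 0


class TestMarginLoss:
    def test_zero_at_margins(self):
        _, total = margin_loss(np.array([[0.1, 0.9]]), [1])
        assert total == 0.0

    def test_perfect_prediction_zero(self):
        _, total = margin_loss(np.array([[1.0, 0.0, 0.0]]), [0])
        assert total == 0.0

    def test_hand_computed_value(self):
        # true class at 0.5: (0.9-0.5)^2 = 0.16; other at 0.5: 0.5*(0.5-0.1)^2 = 0.08
        per_sample, total = margin_loss(np.array([[0.5, 0.5]]), [0])
        assert total == pytest.approx(0.24, abs=1e-12)
        assert per_sample[0] == pytest.approx(0.24, abs=1e-12)

    def test_batch_mean(self):
        lengths = np.array([[0.5, 0.5], [0.1, 0.9]])
        _, total = margin_loss(lengths, [0, 1])
        assert total == pytest.approx(0.12, abs=1e-12)

    def test_out_of_range_lengths_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(np.array([[1.2, 0.0]]), [0])

    @given(
        st.integers(0, 10**6),
        st.integers(2, 4),
    )
    @settings(deadline=None, max_examples=50)
    def test_nonnegative_and_zero_set(self, seed, k):
        rng = np.random.default_rng(seed)
        lengths = rng.uniform(0, 1, size=(3, k))
        labels = rng.integers(0, k, size=3)
        per_sample, total = margin_loss(lengths, labels)
        assert np.all(per_sample >= 0)
        p = MarginLossParams()
        for row, label, loss_val in zip(lengths, labels, per_sample):
            others_ok = all(
                row[j] <= p.m_minus for j in range(k) if j != label
            )
            expect_zero = row[label] >= p.m_plus and others_ok
            assert (loss_val == 0.0) == expect_zero

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=0.1, m_minus=0.9)


# -- architecture shapes ------------------------------------------------------


class TestArchitecture:
    def test_reference_layout_shapes(self):
        """(19,18,1) -> (19,18,8) -> (13,12,8) -> 312 primary capsules of
        dim 4 -> (K,16) label capsules -> K probabilities."""
        cfg = ModelConfig(input_hw=(19, 18), n_classes=2)
        model = MicroCapsNet(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(1, 19, 18, 1))
        from microcaps.autograd import Tensor

        feats1 = model.feature_extract(Tensor(x))
        assert feats1.shape == (1, 13, 12, 8)
        assert cfg.feature_hw == (13, 12)
        assert cfg.n_primary == 312
        u = model.to_primary_capsules(feats1)
        assert u.shape == (1, 312, 4)
        v = model.route(u)
        assert v.shape == (1, 2, 16)
        lengths, _ = model.forward(x)
        assert lengths.shape == (1, 2)

    def test_conv1_preserves_spatial_size(self):
        from microcaps.autograd import Tensor, conv2d, relu

        cfg = ModelConfig(input_hw=(19, 18), n_classes=2)
        model = MicroCapsNet(cfg, seed=0)
        x = Tensor(np.zeros((2, 19, 18, 1)))
        h = relu(conv2d(x, model.conv1_w, model.conv1_b, padding="same"))
        assert h.shape == (2, 19, 18, 8)

    def test_ucistyle_layout_shapes(self):
        cfg = ModelConfig(input_hw=(15, 12), n_classes=2)
        assert cfg.feature_hw == (9, 6)
        assert cfg.n_primary == 9 * 6 * 8 // 4

    def test_minimal_input_after_two_valid_convs(self):
        cfg = ModelConfig(input_hw=(7, 7), n_classes=2)
        assert cfg.feature_hw == (1, 1)
        assert cfg.n_primary == 2

    def test_three_class_output(self):
        cfg = ModelConfig(input_hw=(15, 12), n_classes=3)
        model = MicroCapsNet(cfg, seed=0)
        lengths, _ = model.forward(np.zeros((2, 15, 12)))
        assert lengths.shape == (2, 3)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_hw=(5, 5), n_classes=2)

    def test_all_zero_features_give_zero_capsules(self):
        cfg = ModelConfig(input_hw=(7, 7), n_classes=2)
        model = MicroCapsNet(cfg, seed=0)
        from microcaps.autograd import Tensor

        u = model.to_primary_capsules(Tensor(np.zeros((1, 1, 1, 8))))
        np.testing.assert_allclose(u.data, 0.0, atol=1e-7)

    def test_prediction_tensor_matches_loop(self):
        """u_hat[i,j] = u[i] @ W[i,j], checked against an explicit loop."""
        cfg = ModelConfig(input_hw=(7, 7), n_classes=2)
        model = MicroCapsNet(cfg, seed=5)
        rng = np.random.default_rng(0)
        u = rng.normal(size=(1, cfg.n_primary, cfg.primary_caps_dim))
        from microcaps.autograd import Tensor, einsum

        u_hat = einsum("bip,ijpq->bijq", Tensor(u), model.routing_w).data
        for i in range(cfg.n_primary):
            for j in range(cfg.n_classes):
                np.testing.assert_allclose(
                    u_hat[0, i, j], u[0, i] @ model.routing_w.data[i, j], atol=1e-12
                )


def hand_parameter_count(input_hw=(19, 18), k=2):
    """Independent layer-by-layer arithmetic for the trainable size."""
    conv1 = 4 * 4 * 1 * 8 + 8
    conv2 = 2 * (4 * 4 * 8 * 8 + 8)
    h, w = input_hw[0] - 6, input_hw[1] - 6
    n_primary = h * w * 8 // 4
    routing = n_primary * k * 4 * 16
    return conv1 + conv2 + routing


@pytest.mark.parametrize("hw,k", [((19, 18), 2), ((15, 12), 3)])
def test_parameter_count_matches_hand_count(hw, k):
    model = MicroCapsNet(ModelConfig(input_hw=hw, n_classes=k), seed=0)
    assert model.n_parameters() == hand_parameter_count(hw, k)


# -- end-to-end training behaviour -------------------------------------------


class TestTrainingStep:
    def test_forward_is_deterministic(self):
        cfg = ModelConfig(input_hw=(15, 12), n_classes=2)
        model = MicroCapsNet(cfg, seed=42)
        x = np.random.default_rng(0).normal(size=(4, 15, 12))
        a, _ = model.forward(x)
        b, _ = model.forward(x)
        np.testing.assert_array_equal(a.data, b.data)

    def test_one_adam_step_decreases_loss(self):
        cfg = ModelConfig(input_hw=(15, 12), n_classes=2)
        model = MicroCapsNet(cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 15, 12))
        y = rng.integers(0, 2, size=8)
        opt = Adam(model.params, lr=5e-4)
        _, loss0 = model.forward(x, y)
        opt.zero_grad()
        loss0.backward()
        opt.step()
        _, loss1 = model.forward(x, y)
        assert float(loss1.data) < float(loss0.data)

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(input_hw=(8, 8), n_classes=2)
        model = MicroCapsNet(cfg, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 8, 8))
        y = np.array([0, 1])
        _, loss = model.forward(x, y)
        loss.backward()
        eps = 1e-6
        for param in (model.conv1_w, model.conv2b_w, model.routing_w):
            idx = np.unravel_index(np.argmax(np.abs(param.grad)), param.grad.shape)
            analytic = param.grad[idx]
            orig = param.data[idx]
            param.data[idx] = orig + eps
            up = float(model.forward(x, y)[1].data)
            param.data[idx] = orig - eps
            down = float(model.forward(x, y)[1].data)
            param.data[idx] = orig
            assert analytic == pytest.approx((up - down) / (2 * eps), rel=1e-4)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = ModelConfig(input_hw=(15, 12), n_classes=2)
        model = MicroCapsNet(cfg, seed=9)
        x = np.random.default_rng(0).normal(size=(3, 15, 12))
        before, _ = model.forward(x)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = MicroCapsNet.load(path)
        after, _ = loaded.forward(x)
        np.testing.assert_array_equal(before.data, after.data)
        assert loaded.config.input_hw == (15, 12)
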