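"""Fusion head: dual pooling, channel attention, gradient scaling."""

import numpy as np
import pytest
from scipy.special import expit

from stnet import nn
from stnet.fusion import (
    FusionHead,
    apply_attention,
    channel_attention,
    global_dual_pool,
    gradient_scale,
)

from conftest import finite_difference

rng = np.random.default_rng(21)


class TestGlobalDualPool:
    def test_constant_channel(self):
        Z = np.full((1, 3, 4, 4), 2.0)
        np.testing.assert_allclose(global_dual_pool(Z).data, 2.0)

    def test_hand_evaluated_mean_max_average(self):
        Z = np.array([1.0, 2.0, 3.0, 6.0]).reshape(1, 1, 2, 2)
        assert global_dual_pool(Z).data.reshape(()) == pytest.approx(4.5)

    def test_degenerate_1x1_map(self):
        Z = rng.normal(size=(1, 5, 1, 1))
        np.testing.assert_allclose(global_dual_pool(Z).data,
                                   Z.reshape(1, 5))

    def test_between_mean_and_max(self):
        Z = rng.normal(size=(2, 6, 5, 5))
        g = global_dual_pool(Z).data
        mean, mx = Z.mean(axis=(2, 3)), Z.max(axis=(2, 3))
        assert (g >= mean - 1e-12).all() and (g <= mx + 1e-12).all()

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            global_dual_pool(np.zeros((1, 3, 0, 4)))


class TestChannelAttention:
    def test_zero_weights_fixed_point_half(self):
        g = rng.normal(size=(4,))
        w = channel_attention(g, np.zeros((4, 2)), np.zeros((2, 4)))
        np.testing.assert_allclose(w.data, 0.5)

    def test_outputs_strictly_in_unit_interval(self):
        for _ in range(10):
            g = rng.normal(size=(8,)) * 10
            w1, w2 = rng.normal(size=(8, 2)), rng.normal(size=(2, 8))
            w = channel_attention(g, w1, w2).data
            assert ((w > 0) & (w < 1)).all()

    def test_identity_weights_double_logistic(self):
        w = channel_attention(np.zeros(2), np.eye(2), np.eye(2)).data
        np.testing.assert_allclose(w, expit(expit(0.0)), rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            channel_attention(np.zeros(4), np.zeros((3, 2)), np.zeros((2, 4)))


class TestApplyAttention:
    def test_identity_and_annihilator_weights(self):
        Z = rng.normal(size=(3, 4, 4))
        np.testing.assert_array_equal(apply_attention(Z, np.ones(3)).data, Z)
        np.testing.assert_array_equal(apply_attention(Z, np.zeros(3)).data,
                                      np.zeros_like(Z))

    def test_per_channel_scaling_elementwise(self):
        Z = rng.normal(size=(2, 5, 5))
        w = np.array([0.5, 0.25])
        out = apply_attention(Z, w).data
        np.testing.assert_allclose(out[0], 0.5 * Z[0])
        np.testing.assert_allclose(out[1], 0.25 * Z[1])

    def test_attention_is_elementwise_contraction(self):
        """|Z'| <= |Z| because every attention weight lies in (0, 1)."""
        Z = rng.normal(size=(2, 8, 4, 4))
        g = global_dual_pool(Z)
        w = channel_attention(g, rng.normal(size=(8, 2)),
                              rng.normal(size=(2, 8)))
        out = apply_attention(Z, w).data
        assert (np.abs(out) <= np.abs(Z) + 1e-15).all()

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_attention(np.zeros((3, 4, 4)), np.ones(2))


class TestGradientScale:
    def test_forward_is_identity(self):
        x = rng.normal(size=(2, 3, 4, 4))
        for factor in (0.1, 0.5, 1.0, 7.3):
            np.testing.assert_array_equal(gradient_scale(x, factor).data, x)

    def test_hand_differentiated_half_factor(self):
        x = nn.Parameter(np.array([1.0, 2.0]))
        (gradient_scale(x, 0.5) ** 2).sum().backward()
        np.testing.assert_allclose(x.grad, [1.0, 2.0])  # halved (2, 4)

    @pytest.mark.parametrize("factor", [0.1, 0.5, 1.0])
    def test_scaled_gradient_matches_finite_differences(self, factor):
        x = nn.Parameter(rng.normal(size=(5,)))
        coef = rng.normal(size=(5,))

        def loss():
            return ((gradient_scale(x, factor) * coef).sigmoid() ** 2).sum()

        loss().backward()
        baseline = finite_difference(lambda: float(loss().data), x.data,
                                     eps=1e-3)
        np.testing.assert_allclose(x.grad, factor * baseline, rtol=1e-2)

    def test_factor_one_is_neutral(self):
        x1 = nn.Parameter(np.array([0.3, -0.7]))
        x2 = nn.Parameter(np.array([0.3, -0.7]))
        (gradient_scale(x1, 1.0).sigmoid().sum()).backward()
        (x2.sigmoid().sum()).backward()
        np.testing.assert_allclose(x1.grad, x2.grad, rtol=1e-12)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            gradient_scale(np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            FusionHead(4, 4, grad_scale=-1.0)


class TestFusionHead:
    def test_zero_classifier_weights_give_half(self):
        head = FusionHead(4, 4, reduction_ratio=2, seed=0)
        head.classifier.weight.data[:] = 0.0
        head.classifier.bias.data[:] = 0.0
        p = head(rng.normal(size=(3, 4, 2, 2)), rng.normal(size=(3, 4, 2, 2)))
        np.testing.assert_allclose(p.data, 0.5)

    def test_scores_in_open_unit_interval(self):
        head = FusionHead(4, 4, reduction_ratio=2, seed=1)
        p = head(rng.normal(size=(5, 4, 3, 3)) * 10,
                 rng.normal(size=(5, 4, 3, 3)) * 10).data
        assert ((p > 0) & (p < 1)).all()

    def test_geometry_mismatch_rejected(self):
        head = FusionHead(4, 4, seed=0)
        with pytest.raises(ValueError):
            head(rng.normal(size=(1, 4, 2, 2)), rng.normal(size=(1, 4, 3, 3)))

    def test_zeroed_shape_attention_makes_p_shape_invariant(self):
        """Suppressing all shape channels (attention ablation) must make the
        score depend on the texture features only."""
        head = FusionHead(4, 4, reduction_ratio=2, seed=2)
        tex = rng.normal(size=(2, 4, 3, 3))
        shp_a = rng.normal(size=(2, 4, 3, 3))
        shp_b = rng.normal(size=(2, 4, 3, 3))

        class Ablated(FusionHead):
            def attention_weights(self, fused):
                # injected weights: pass texture channels, null shape channels
                gate = np.concatenate([np.ones(4), np.zeros(4)])
                return nn.Tensor(gate)

        abl = Ablated(4, 4, reduction_ratio=2, seed=2)
        # a raw head must be sensitive to the shape input...
        assert not np.allclose(head(tex, shp_a).data, head(tex, shp_b).data)
        # ...the ablated one must not
        np.testing.assert_allclose(abl(tex, shp_a).data, abl(tex, shp_b).data,
                                   atol=1e-12)

    def test_attention_selects_the_informative_stream(self):
        """Trained on features where only the shape channels carry the label
        signal, the attention gate weights shape channels above texture
        channels (channel selection, directional and seeded)."""
        from stnet.nn.optim import RMSprop
        from stnet.objectives import cross_entropy

        r = np.random.default_rng(0)
        N, C, H = 64, 8, 4
        labels = (np.arange(N) % 2).astype(float)
        tex = r.normal(size=(N, C, H, H))  # pure noise
        shp = r.normal(size=(N, C, H, H)) + 2.0 * labels[:, None, None, None]
        head = FusionHead(C, C, reduction_ratio=2, grad_scale=1.0, seed=0)
        opt = RMSprop(head.parameters(), lr=5e-3)
        for _ in range(150):
            loss = cross_entropy(labels, head(tex, shp), reduce=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
        fused = nn.cat([nn.Tensor(tex), nn.Tensor(shp)], axis=1)
        w = head.attention_weights(fused).data
        assert float(loss.data) < 0.1  # the head actually learned the task
        assert w[..., C:].mean() > w[..., :C].mean()
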