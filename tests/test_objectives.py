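"""Loss closed forms, reductions and the parameter-group isolation contract."""

import numpy as np
import pytest

from stnet import nn
from stnet.model import STNet
from stnet.objectives import (
    AsymLossParams,
    JointLossWeights,
    asymmetric_loss,
    cross_entropy,
    joint_loss,
    shape_loss,
    transfer_probability,
)

rng = np.random.default_rng(5)


def scalar_asymmetric_oracle(y, p, gp, gm, phi, eps=1e-7):
    """Independent scalar evaluation of the asymmetric loss."""
    from math import log
    p = min(max(p, eps), 1 - eps)
    pt = max(p - phi, 0.0)
    return -y * (1 - p) ** gp * log(p) - (1 - y) * pt ** gm * log(1 - p)


class TestCrossEntropy:
    def test_hand_values(self):
        assert cross_entropy(1, 0.5) == pytest.approx(np.log(2), rel=1e-12)
        assert cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_between_classes(self):
        for p in np.linspace(0.01, 0.99, 23):
            assert cross_entropy(1, p) == pytest.approx(cross_entropy(0, 1 - p))

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(cross_entropy(1, 0.0))
        assert np.isfinite(cross_entropy(0, 1.0))


class TestTransferProbability:
    def test_easy_negative_discarded(self):
        assert transfer_probability(0.03, 0.05) == 0.0

    def test_zero_cutoff_is_identity(self):
        p = rng.random(10)
        np.testing.assert_allclose(transfer_probability(p, 0.0), p)

    def test_shift(self):
        assert transfer_probability(0.50, 0.05) == pytest.approx(0.45)


class TestAsymmetricLoss:
    def test_reduces_to_cross_entropy(self):
        params = AsymLossParams(0.0, 0.0, 0.0)
        for y in (0, 1):
            for p in np.linspace(0.01, 0.99, 21):
                assert asymmetric_loss(y, p, params) == pytest.approx(
                    cross_entropy(y, p), rel=1e-12)

    def test_scalar_oracle_value(self):
        params = AsymLossParams(1.0, 3.0, 0.05)
        got = asymmetric_loss(0, 0.5, params)
        assert got == pytest.approx(0.45 ** 3 * np.log(2), rel=1e-9)
        assert got == pytest.approx(0.06316, abs=5e-6)

    def test_matches_oracle_on_grid(self):
        grid = [(y, p, gp, gm, phi)
                for y in (0, 1)
                for p in (0.02, 0.3, 0.5, 0.8, 0.99)
                for (gp, gm) in ((0, 0), (1, 1), (1, 3), (2, 4))
                for phi in (0.0, 0.05, 0.2)]
        for y, p, gp, gm, phi in grid:
            got = asymmetric_loss(y, p, AsymLossParams(gp, gm, phi))
            want = scalar_asymmetric_oracle(y, p, gp, gm, phi)
            assert got == pytest.approx(want, abs=1e-9), (y, p, gp, gm, phi)

    def test_negative_branch_zero_below_cutoff(self):
        params = AsymLossParams(1.0, 3.0, 0.05)
        for p in (0.0, 0.01, 0.05):
            assert asymmetric_loss(0, p, params) == 0.0

    def test_monotone_damping_in_gamma_minus(self):
        for p in np.arange(0.2, 0.95, 0.1):
            losses = [asymmetric_loss(0, p, AsymLossParams(0.0, gm, 0.05))
                      for gm in (0, 1, 2, 3, 4)]
            assert all(a >= b - 1e-15 for a, b in zip(losses, losses[1:]))

    def test_never_exceeds_cross_entropy(self):
        for y in (0, 1):
            for p in np.linspace(0.01, 0.99, 25):
                for gp, gm in ((0, 1), (1, 3), (2, 2)):
                    al = asymmetric_loss(y, p, AsymLossParams(gp, gm, 0.05))
                    assert al <= cross_entropy(y, p) + 1e-12

    def test_batch_mean_reduction(self):
        y = np.array([1.0, 0.0, 1.0])
        p = np.array([0.9, 0.2, 0.6])
        params = AsymLossParams(1.0, 3.0, 0.05)
        per_sample = [asymmetric_loss(yi, pi, params) for yi, pi in zip(y, p)]
        got = asymmetric_loss(y, p, params, reduce=True)
        assert got == pytest.approx(np.mean(per_sample), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AsymLossParams(3.0, 1.0, 0.05)  # positives damped harder
        with pytest.raises(ValueError):
            AsymLossParams(1.0, 3.0, 1.0)
        with pytest.raises(ValueError):
            JointLossWeights(0.0, 0.0)


class TestShapeLoss:
    def test_perfect_prediction(self):
        m = (rng.random((8, 8)) > 0.5).astype(float)
        assert shape_loss(m, m) == 0.0

    def test_constant_half_versus_ones(self):
        assert shape_loss(np.full((4, 4), 0.5), np.ones((4, 4))) == \
            pytest.approx(0.25)

    def test_invariant_to_joint_permutation(self):
        mp, mt = rng.random((5, 5)), (rng.random((5, 5)) > 0.5).astype(float)
        perm = rng.permutation(25)
        assert shape_loss(mp, mt) == pytest.approx(
            shape_loss(mp.ravel()[perm], mt.ravel()[perm]))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shape_loss(np.zeros((4, 4)), np.zeros((5, 5)))


def _tiny_model_batch(seed=0):
    model = STNet(depth="tiny", seed=seed)
    r = np.random.default_rng(seed)
    images = r.normal(size=(4, 3, 64, 64)) * 0.1 + 0.5
    labels = np.array([1.0, 0.0, 1.0, 0.0])
    masks = (r.random((4, 64, 64)) > 0.5).astype(float)
    return model, images, labels, masks


def _grads(model, images, labels, masks, avail, beta, alpha=0.1):
    model.fusion.grad_scale = alpha
    model.zero_grad()
    out = model(images)
    mask_pred = out.mask_pred.reshape(4, 64, 64)
    total, _, _ = joint_loss(out.p, labels, mask_pred, masks, avail,
                             weights=JointLossWeights(alpha=alpha, beta=beta))
    total.backward()
    return {name: (None if p.grad is None else p.grad.copy())
            for name, p in model.named_parameters()}


class TestJointObjective:
    def test_no_masks_in_batch_zeroes_decoder_gradients(self):
        model, images, labels, masks = _tiny_model_batch()
        grads = _grads(model, images, labels, masks,
                       avail=np.zeros(4, dtype=bool), beta=1.0)
        for name, g in grads.items():
            if name.startswith("decoder"):
                assert g is None or not np.any(g), name

    def test_beta_zero_zeroes_decoder_gradients(self):
        model, images, labels, masks = _tiny_model_batch()
        grads = _grads(model, images, labels, masks,
                       avail=np.ones(4, dtype=bool), beta=0.0)
        for name, g in grads.items():
            if name.startswith("decoder"):
                assert g is None or not np.any(g), name

    def test_texture_encoder_gradients_invariant_to_beta(self):
        model, images, labels, masks = _tiny_model_batch()
        avail = np.ones(4, dtype=bool)
        g0 = _grads(model, images, labels, masks, avail, beta=0.0)
        g1 = _grads(model, images, labels, masks, avail, beta=1.0)
        for name in g0:
            if name.startswith("texture_encoder"):
                np.testing.assert_allclose(g0[name], g1[name], rtol=1e-10,
                                           err_msg=name)

    def test_shape_encoder_classification_gradient_linear_in_alpha(self):
        """With the shape loss off, gradients entering the shape encoder are
        proportional to the gradient-scale factor alpha."""
        model, images, labels, masks = _tiny_model_batch()
        avail = np.zeros(4, dtype=bool)
        g_half = _grads(model, images, labels, masks, avail, beta=1.0,
                        alpha=0.5)
        g_full = _grads(model, images, labels, masks, avail, beta=1.0,
                        alpha=1.0)
        checked = 0
        for name in g_half:
            if name.startswith("shape_encoder") and g_half[name] is not None:
                denom = np.abs(g_full[name]).max()
                if denom < 1e-12:
                    continue
                np.testing.assert_allclose(g_half[name], 0.5 * g_full[name],
                                           atol=1e-4 * denom, err_msg=name)
                checked += 1
        assert checked > 0

    def test_mask_selection_averages_over_masked_samples_only(self):
        model, images, labels, masks = _tiny_model_batch()
        avail = np.array([True, False, True, False])
        model.eval()
        out = model(images)
        mask_pred = out.mask_pred.reshape(4, 64, 64)
        _, _, l_shp = joint_loss(out.p, labels, mask_pred, masks, avail)
        manual = np.mean([(mask_pred.data[i] - masks[i]) ** 2
                          for i in (0, 2)])
        assert l_shp == pytest.approx(manual, rel=1e-12)
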