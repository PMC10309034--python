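"""Shape stream: bilinear sampling, deformable convolution, encoder-decoder."""

import numpy as np
import pytest

from stnet import nn
from stnet.nn import functional as F
from stnet.shape import (
    ShapeDecoder,
    ShapeEncoder,
    bilinear_sample,
    deformable_conv,
)

rng = np.random.default_rng(13)


class TestBilinearSample:
    def test_exact_at_every_grid_node(self):
        x = rng.normal(size=(6, 7))
        for i in range(6):
            for j in range(7):
                assert bilinear_sample(x, (i, j)) == pytest.approx(x[i, j])

    def test_hand_evaluated_midpoint(self):
        x = np.array([[0.0, 1.0], [2.0, 3.0]])
        assert bilinear_sample(x, (0.5, 0.5)) == pytest.approx(1.5)

    def test_out_of_bounds_reads_zero(self):
        x = rng.normal(size=(4, 4))
        assert bilinear_sample(x, (-10.0, -10.0)) == 0.0
        assert bilinear_sample(x, (100.0, 2.0)) == 0.0

    def test_edge_blend_with_zero_padding(self):
        x = np.ones((3, 3))
        # halfway off the top edge: blends 1.0 with the zero exterior
        assert bilinear_sample(x, (-0.5, 1.0)) == pytest.approx(0.5)


class TestDeformableConv:
    def test_zero_offsets_reduce_to_standard_conv(self):
        for _ in range(50):
            C, Co = rng.integers(1, 9), rng.integers(1, 9)
            H = int(rng.integers(5, 9))
            x = rng.normal(size=(1, C, H, H))
            w = rng.normal(size=(Co, C, 3, 3))
            off = np.zeros((1, 18, H, H))
            got = deformable_conv(x, w, off, stride=1, padding=1).data
            want = F.conv2d(nn.Tensor(x), nn.Tensor(w), stride=1, padding=1).data
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-12)

    def test_all_ones_valid_position_sums_taps(self):
        x = np.ones((1, 1, 3, 3))
        w = np.ones((1, 1, 3, 3))
        off = np.zeros((1, 18, 1, 1))
        out = deformable_conv(x, w, off, stride=1, padding=0).data
        assert out.reshape(()) == pytest.approx(9.0)

    def test_integer_offsets_equal_shifted_convolution(self):
        """Offsetting every tap by one column equals convolving the
        column-shifted input (away from boundary effects)."""
        x = rng.normal(size=(1, 2, 8, 8))
        w = rng.normal(size=(3, 2, 3, 3))
        off = np.zeros((1, 18, 8, 8))
        off[:, 1::2] = 1.0  # (row, col) pairs: shift every tap by +1 column
        got = deformable_conv(x, w, off, stride=1, padding=1).data
        shifted = np.roll(x, -1, axis=3)
        want = F.conv2d(nn.Tensor(shifted), nn.Tensor(w), stride=1,
                        padding=1).data
        # away from the columns where zero padding and np.roll wrap-around
        # disagree about the out-of-bounds values
        interior = (slice(None), slice(None), slice(None), slice(1, 6))
        np.testing.assert_allclose(got[interior], want[interior], rtol=1e-6,
                                   atol=1e-10)

    def test_offset_channel_mismatch_rejected(self):
        x = rng.normal(size=(1, 2, 5, 5))
        w = rng.normal(size=(3, 2, 3, 3))
        with pytest.raises(ValueError):
            deformable_conv(x, w, np.zeros((1, 10, 5, 5)), padding=1)


class TestShapeEncoder:
    def test_tiny_geometry_matches_texture_stream(self):
        enc = ShapeEncoder("tiny", seed=0).eval()
        out = enc(rng.normal(size=(2, 3, 64, 64)))
        assert out.shape == (2, 64, 8, 8)

    def test_resnet50_variant_produces_7x7x2048(self):
        enc = ShapeEncoder(50, seed=0).eval()
        out = enc(rng.normal(size=(1, 3, 224, 224)) * 0.1)
        assert out.shape == (1, 2048, 7, 7)

    def test_zero_offset_init_equals_plain_backbone(self):
        """Offset layers start at zero, so the freshly built encoder equals a
        standard convolution network with the same weights."""
        enc = ShapeEncoder("tiny", deformable_stages=[1], seed=4).eval()
        for m in enc.modules():
            if isinstance(m, nn.DeformableConv2d):
                assert np.all(m.offset_conv.weight.data == 0)
        x = rng.normal(size=(1, 3, 64, 64))
        got = enc(x).data

        plain = ShapeEncoder("tiny", deformable_stages=[], seed=4).eval()
        state = {k: v for k, v in enc.state_dict().items()
                 if "offset_conv" not in k}
        plain.load_state_dict(state)
        np.testing.assert_allclose(got, plain(x).data, rtol=1e-6, atol=1e-9)

    def test_determinism_under_fixed_weights(self):
        enc = ShapeEncoder("tiny", seed=1).eval()
        x = rng.normal(size=(1, 3, 64, 64))
        np.testing.assert_array_equal(enc(x).data, enc(x).data)


class TestShapeDecoder:
    def test_upsamples_to_input_resolution_in_unit_range(self):
        dec = ShapeDecoder(64, widths=(32, 16, 8), seed=0).eval()
        feat = rng.normal(size=(2, 64, 8, 8))
        mask = dec(feat)
        assert mask.shape == (2, 1, 64, 64)
        assert (mask.data >= 0).all() and (mask.data <= 1).all()

    def test_zero_head_weights_give_constant_half(self):
        dec = ShapeDecoder(64, widths=(32, 16, 8), seed=0).eval()
        dec.head.weight.data[:] = 0.0
        dec.head.bias.data[:] = 0.0
        mask = dec(rng.normal(size=(1, 64, 8, 8)))
        np.testing.assert_allclose(mask.data, 0.5)

    def test_geometry_mismatch_rejected(self):
        dec = ShapeDecoder(64, widths=(32, 16, 8), seed=0)
        with pytest.raises(ValueError):
            dec(rng.normal(size=(1, 32, 8, 8)))

    def test_decoder_consumes_only_the_deepest_feature(self):
        """Zeroing the deepest feature map makes the predicted mask
        input-independent: with no encoder-decoder shortcuts, all information
        flows through that single bottleneck."""
        enc = ShapeEncoder("tiny", seed=0).eval()
        dec = ShapeDecoder(64, widths=(32, 16, 8), seed=0).eval()
        img_a = rng.normal(size=(1, 3, 64, 64))
        img_b = rng.normal(size=(1, 3, 64, 64))
        feat_a, feat_b = enc(img_a), enc(img_b)
        ablated_a = dec(nn.Tensor(np.zeros_like(feat_a.data)))
        ablated_b = dec(nn.Tensor(np.zeros_like(feat_b.data)))
        np.testing.assert_array_equal(ablated_a.data, ablated_b.data)

    def test_gradient_reaches_encoder_first_layer(self):
        """Segmentation loss on the decoder output backpropagates into the
        encoder stem (no accidental detachment along the path)."""
        enc = ShapeEncoder("tiny", seed=0)
        dec = ShapeDecoder(64, widths=(32, 16, 8), seed=0)
        x = rng.normal(size=(1, 3, 64, 64)) * 0.1 + 0.5
        loss = (dec(enc(x)) ** 2).mean()
        loss.backward()
        stem_conv = enc.encoder.stem.layers[0]
        assert stem_conv.weight.grad is not None
        assert np.abs(stem_conv.weight.grad).max() > 0
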