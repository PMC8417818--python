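"""Architecture contracts of the feed-forward and recurrent networks."""

import numpy as np
import pytest

import elastonet as en
from elastonet import nn
from elastonet._autodiff import Tensor
from elastonet.networks import Encoder, tiny_config, reference_config


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestConvLSTMCell:
    def test_zero_weights_zero_state(self):
        """sigma(0) = 0.5 and tanh(0) = 0 force i=f=o=0.5, c=h=0."""
        cell = nn.ConvLSTMCell(3, 2)
        for p in cell.parameters():
            p.data[...] = 0.0
        x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 6, 6)))
        h0, c0 = cell.init_state((6, 6))
        h, c = cell(x, h0, c0)
        assert np.allclose(c.data, 0)
        assert np.allclose(h.data, 0)

    def test_zero_weights_nonzero_cell_state(self, rng):
        """With zero weights: c_t = 0.5*c_{t-1}, h_t = 0.5*tanh(0.5*c)."""
        cell = nn.ConvLSTMCell(3, 2)
        for p in cell.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 3, 6, 6)))
        c_prev = Tensor(rng.normal(size=(1, 2, 6, 6)))
        h_prev = Tensor(np.zeros((1, 2, 6, 6)))
        h, c = cell(x, h_prev, c_prev)
        assert np.allclose(c.data, 0.5 * c_prev.data, atol=1e-6)
        assert np.allclose(h.data, 0.5 * np.tanh(0.5 * c_prev.data),
                           atol=1e-6)

    def test_matches_scalar_hand_evaluation(self, rng):
        """1x1 kernels on a 1x1 grid: the six gate equations reduce to
        scalars and are evaluated by hand."""
        cell = nn.ConvLSTMCell(1, 1, kernel=1)
        wx = rng.normal(size=4)
        wh = rng.normal(size=4)
        b = rng.normal(size=4)
        cell.w_x.data = wx.reshape(4, 1, 1, 1).astype(np.float32)
        cell.w_h.data = wh.reshape(4, 1, 1, 1).astype(np.float32)
        cell.bias.data = b.astype(np.float32)
        x_v, h_v, c_v = 0.7, -0.4, 0.9
        x = Tensor(np.full((1, 1, 1, 1), x_v, dtype=np.float32))
        h_prev = Tensor(np.full((1, 1, 1, 1), h_v, dtype=np.float32))
        c_prev = Tensor(np.full((1, 1, 1, 1), c_v, dtype=np.float32))
        h, c = cell(x, h_prev, c_prev)
        i = _sigmoid(x_v * wx[0] + h_v * wh[0] + b[0])
        f = _sigmoid(x_v * wx[1] + h_v * wh[1] + b[1])
        o = _sigmoid(x_v * wx[2] + h_v * wh[2] + b[2])
        c_tilde = np.tanh(x_v * wx[3] + h_v * wh[3] + b[3])
        c_exp = c_v * f + i * c_tilde
        h_exp = o * np.tanh(c_exp)
        assert abs(c.item() - c_exp) < 1e-6
        assert abs(h.item() - h_exp) < 1e-6

    def test_cell_state_growth_bound(self, rng):
        """|c_t| <= |c_{t-1}| + 1 elementwise since |i * c_tilde| <= 1."""
        cell = nn.ConvLSTMCell(2, 3, rng=rng)
        x = Tensor(rng.normal(scale=3.0, size=(1, 2, 8, 8)))
        c_prev = Tensor(rng.normal(scale=2.0, size=(1, 3, 8, 8)))
        h_prev = Tensor(rng.normal(size=(1, 3, 8, 8)))
        _, c = cell(x, h_prev, c_prev)
        assert (np.abs(c.data) <= np.abs(c_prev.data) + 1 + 1e-6).all()

    def test_shape_mismatch_raises(self, rng):
        cell = nn.ConvLSTMCell(2, 3)
        x = Tensor(rng.normal(size=(1, 2, 8, 8)))
        h0, c0 = cell.init_state((6, 6))
        with pytest.raises(ValueError):
            cell(x, h0, c0)


class TestEncoder:
    def test_pyramid_shapes(self, rng):
        enc = Encoder(tiny_config("usenet"), np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 2, 64, 48)).astype(np.float32))
        skips, bott = enc(x)
        assert [s.shape[-2:] for s in skips] == \
            [(64, 48), (32, 24), (16, 12), (8, 6)]
        assert bott.shape[-2:] == (4, 3)

    def test_zero_input_stays_finite(self):
        enc = Encoder(tiny_config("usenet"), np.random.default_rng(0))
        skips, bott = enc(Tensor(np.zeros((1, 2, 32, 32), np.float32)))
        assert np.isfinite(bott.data).all()

    def test_residual_path_with_zero_conv_weights(self, rng):
        """Zero conv/BN-offset weights leave only the projected input."""
        block = nn.ResNetBlock(2, 4, rng=np.random.default_rng(0))
        block.conv1.weight.data[...] = 0
        block.conv2.weight.data[...] = 0
        x = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        out = block(x)
        proj = block.proj(x)
        assert np.allclose(out.data, proj.data, atol=1e-6)

    def test_non_divisible_dims_rejected(self):
        enc = Encoder(tiny_config("usenet"), np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 2, 30, 32), np.float32)))


class TestUSENet:
    def test_output_shape_contract(self, rng):
        model = en.build_network(tiny_config("usenet"), seed=0)
        out = model.forward_pair(rng.normal(size=(64, 48)),
                                 rng.normal(size=(64, 48)))
        assert out.shape == (2, 64, 48)

    def test_zero_heads_give_identity_transform(self, rng):
        """Freshly initialised displacement heads are zero, so the
        network starts from the identity transform."""
        model = en.build_network(tiny_config("usenet"), seed=1)
        out = model.forward_pair(rng.normal(size=(32, 32)),
                                 rng.normal(size=(32, 32)))
        assert np.allclose(out.data, 0.0)

    def test_translation_covariance(self, rng):
        """Shifting both inputs by a pool-compatible amount shifts the
        output field by the same amount (interior pixels).

        Only the fine-scale heads are randomised: with zero-padded
        convolutions the coarsest (1/16-resolution) pathway is global —
        every output pixel sees an image border — so exact covariance
        can only be expected of the fine-resolution pathway."""
        model = en.build_network(tiny_config("usenet"), seed=0)
        r = np.random.default_rng(5)
        for head in model.heads[-2:]:
            head.weight.data = r.normal(
                scale=0.01, size=head.weight.shape).astype(np.float32)
        pre = rng.normal(size=(128, 128))
        post = rng.normal(size=(128, 128))
        base = model.forward_pair(pre, post).data
        k = 16
        shifted = model.forward_pair(np.roll(pre, k, axis=0),
                                     np.roll(post, k, axis=0)).data
        # circular shift vs zero-padded convs: compare inside the
        # receptive-field margin (~50 rows for the 4-level encoder)
        dev = np.abs(np.roll(base, k, axis=1) - shifted)[:, 56:104, 56:104]
        assert dev.max() < 0.1

    def test_padding_of_non_divisible_inputs(self, rng):
        model = en.build_network(tiny_config("usenet"), seed=0)
        out = model.forward_pair(rng.normal(size=(50, 40)),
                                 rng.normal(size=(50, 40)))
        assert out.shape == (2, 50, 40)


class TestReUSENet:
    def test_sequence_gives_n_minus_one_fields(self, rng):
        model = en.build_network(tiny_config("reusenet"), seed=0)
        frames = [rng.normal(size=(32, 32)) for _ in range(5)]
        fields, state = model.forward_sequence(frames)
        assert len(fields) == 4
        assert all(f.shape == (2, 32, 32) for f in fields)
        assert len(state) == 5

    def test_recurrence_state_dependence(self, rng):
        """Feeding the same pair twice produces different outputs unless
        the state is reset: the hidden state carries information."""
        model = en.build_network(tiny_config("reusenet"), seed=0)
        r = np.random.default_rng(6)
        for head in model.heads:
            head.weight.data = r.normal(
                scale=0.05, size=head.weight.shape).astype(np.float32)
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        fields, _ = model.forward_sequence([a, b, b])  # pairs (a,b), (b,b)
        out1, out2 = fields[0].data, fields[1].data
        state0 = model.init_state((32, 32))
        fresh, _ = model.forward_step(b, b, state0)
        assert not np.array_equal(out2, fresh.data)

    def test_zeroed_state_degrades_to_feedforward(self, rng):
        model = en.build_network(tiny_config("reusenet"), seed=0)
        frames = [rng.normal(size=(32, 32)) for _ in range(4)]
        state = model.init_state((32, 32))
        for t in range(1, 4):
            field, _ = model.forward_step(frames[t - 1], frames[t], state)
            assert np.isfinite(field.data).all()
            assert field.shape == (2, 32, 32)

    def test_short_sequence_rejected(self, rng):
        model = en.build_network(tiny_config("reusenet"), seed=0)
        with pytest.raises(ValueError):
            model.forward_sequence([rng.normal(size=(32, 32))])


class TestParameterCounts:
    def test_single_conv_arithmetic(self):
        conv = nn.Conv2d(2, 16, 3)
        assert conv.weight.size + conv.bias.size == 2 * 16 * 9 + 16 == 304

    def test_reference_usenet_count(self):
        count = en.count_parameters(reference_config("usenet"))
        assert abs(count / 1e6 - 0.8) <= 0.1 * 0.8

    def test_reference_reusenet_count(self):
        count = en.count_parameters(reference_config("reusenet"))
        assert abs(count / 1e6 - 1.5) <= 0.1 * 1.5

    def test_recurrent_decoder_roughly_doubles_the_network(self):
        u = en.count_parameters(reference_config("usenet"))
        r = en.count_parameters(reference_config("reusenet"))
        assert r > u


class TestCheckpoints:
    def test_round_trip(self, tmp_path, rng):
        model = en.build_network(tiny_config("reusenet"), seed=0)
        r = np.random.default_rng(9)
        for p in model.parameters():
            p.data = r.normal(scale=0.1, size=p.shape).astype(np.float32)
        path = tmp_path / "model.npz"
        en.save_checkpoint(path, model, extra={"note": "test"})
        loaded, extra = en.load_checkpoint(path)
        assert extra["note"] == "test"
        for (n1, p1), (n2, p2) in zip(model.named_parameters(),
                                      loaded.named_parameters()):
            assert n1 == n2
            assert np.array_equal(p1.data, p2.data)
        frames = [rng.normal(size=(32, 32)) for _ in range(3)]
        f1, _ = model.forward_sequence(frames)
        f2, _ = loaded.forward_sequence(frames)
        assert np.allclose(f1[0].data, f2[0].data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            en.NetworkConfig(encoder_channels=(8, 16)).validate()
        with pytest.raises(ValueError):
            en.NetworkConfig(variant="other").validate()
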