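"""Decoder architecture, residual identities, gradients, and contracts."""

import numpy as np
import pytest

from tcsem.coding import (VideoBlock, encode, generate_masks,
                          normalize_measurement)
from tcsem.errors import ConfigurationError, StateError
from tcsem.network import (NetConfig, ReconstructionNet, ResidualInput,
                           backward_residual_input, build_cnn_input,
                           forward_residual_input)


def _tiny_net(b=2, c=8, seed=0, window=None, dtype=np.float32):
    return ReconstructionNet(NetConfig(b=b, base_channels=c, seed=seed,
                                       attention_window=window), dtype=dtype)


def _coded_scene(b=3, n=8, seed=5, constant=None):
    rng = np.random.default_rng(seed)
    frames = (np.full((b, n, n), constant, dtype=np.float32) if constant
              else rng.uniform(10, 200, (b, n, n)).astype(np.float32))
    masks = generate_masks(b, n, n, seed=seed, guarantee_coverage=True)
    video = VideoBlock(frames=frames)
    m = encode(video, masks)
    return video, masks, m, normalize_measurement(m, masks)


class TestBuildCnnInput:
    def test_channel_count_is_b_plus_one(self):
        _, masks, _, nm = _coded_scene(b=2)
        assert build_cnn_input(nm, masks).shape[0] == 3

    def test_constant_scene_channels(self):
        _, masks, _, nm = _coded_scene(b=3, constant=40.0)
        stack = build_cnn_input(nm, masks)
        np.testing.assert_allclose(stack[0], 40.0, rtol=1e-6)
        for k in range(3):
            np.testing.assert_allclose(stack[k + 1], 40.0 * masks.masks[k],
                                       rtol=1e-6)

    def test_worked_example_channels(self, worked_example):
        _, masks, _, nm = worked_example
        stack = build_cnn_input(nm, masks)
        np.testing.assert_allclose(stack[0], [[1, 6], [5, 4]])
        np.testing.assert_allclose(stack[1], [[1, 0], [5, 4]])
        np.testing.assert_allclose(stack[2], [[0, 6], [5, 0]])


class TestResidualIdentities:
    def test_forward_residual_constant_scene_exact(self):
        _, masks, m, nm = _coded_scene(b=3, constant=25.0)
        for k in range(1, 4):
            priors = np.full((k - 1, 8, 8), 25.0, dtype=np.float32)
            ri = forward_residual_input(k, m, nm, masks, priors)
            np.testing.assert_allclose(ri.residual, 25.0 * masks.masks[k - 1],
                                       rtol=1e-4)
            np.testing.assert_allclose(ri.ybar, nm.ybar)

    def test_forward_residual_worked_example(self, worked_example):
        _, masks, m, nm = worked_example
        ri = forward_residual_input(1, m, nm, masks, np.empty((0, 2, 2)))
        np.testing.assert_allclose(ri.residual, [[1, 0], [5, 4]])

    def test_forward_residual_last_frame_with_perfect_priors(self):
        video, masks, m, nm = _coded_scene(b=4)
        ri = forward_residual_input(4, m, nm, masks, video.frames[:3])
        np.testing.assert_allclose(ri.residual, masks.masks[3] * video.frames[3],
                                   rtol=1e-4, atol=1e-2)

    def test_backward_residual_perfect_estimates_every_k(self):
        video, masks, m, nm = _coded_scene(b=4)
        for k in range(1, 5):
            ri = backward_residual_input(k, m, nm, masks, video.frames)
            np.testing.assert_allclose(
                ri.residual, masks.masks[k - 1] * video.frames[k - 1],
                rtol=1e-4, atol=1e-2)

    def test_backward_residual_worked_example(self, worked_example):
        _, masks, m, nm = worked_example
        ri = backward_residual_input(2, m, nm, masks,
                                     np.stack([nm.ybar, nm.ybar]))
        np.testing.assert_allclose(ri.residual, [[0, 6], [5, 0]])

    def test_backward_residual_zero_estimates_gives_y(self):
        _, masks, m, nm = _coded_scene(b=3)
        ri = backward_residual_input(2, m, nm, masks, np.zeros((3, 8, 8)))
        np.testing.assert_allclose(ri.residual, m.y, rtol=1e-6)

    def test_wrong_prior_count_rejected(self):
        _, masks, m, nm = _coded_scene(b=3)
        with pytest.raises(StateError):
            forward_residual_input(2, m, nm, masks, np.zeros((3, 8, 8)))
        with pytest.raises(StateError):
            backward_residual_input(1, m, nm, masks, np.zeros((2, 8, 8)))


class TestArchitectureCensus:
    def test_first_frame_cnn_census_is_twelve_units(self):
        net = _tiny_net()
        census = net.cnn.layer_census()
        assert census == [("four_layer_cnn", 4), ("residual_block", 3),
                          ("self_attention", 1), ("four_layer_cnn", 4)]
        assert sum(n for _, n in census) == 12

    def test_parameter_count_matches_closed_form(self):
        b, c, k = 4, 16, 3
        net = ReconstructionNet(NetConfig(b=b, base_channels=c, seed=0))
        conv = lambda ci, co: ci * co * k * k + co
        one_by_one = lambda ci, co: ci * co + co
        cnn = (conv(b + 1, c) + 3 * conv(c, c)        # first 4-layer stage
               + 2 * conv(c, c)                       # residual block
               + 4 * one_by_one(c, c)                 # attention q/k/v/proj
               + 3 * conv(c, c) + conv(c, 1))         # second 4-layer stage
        cell = (conv(1, c) + conv(c, c)               # first-part sub-CNN
                + conv(2, c) + conv(c, c)             # residual-input sub-CNN
                + 2 * conv(c, c)                      # hidden sub-CNN
                + conv(3 * c, c)                      # fusion
                + 4 * conv(c, c)                      # two residual blocks
                + conv(c, c) + conv(c, 1))            # output sub-CNN
        assert net.n_params() == cnn + 2 * cell

    def test_forward_backward_cells_structurally_identical_but_disjoint(self):
        net = _tiny_net()
        f = {p.name.removeprefix("fwd."): p for p in net.fcell.params()}
        b = {p.name.removeprefix("bwd."): p for p in net.bcell.params()}
        assert set(f) == set(b)
        for name in f:
            assert f[name].data.shape == b[name].data.shape
            assert not np.shares_memory(f[name].data, b[name].data)

    def test_weight_config_mismatch_rejected(self):
        net = _tiny_net(b=2)
        other = _tiny_net(b=3)
        with pytest.raises(ConfigurationError):
            net.load_state_dict(other.state_dict())


class TestCnnFirstFrame:
    def test_deterministic_given_fixed_weights(self):
        net = _tiny_net()
        _, masks, _, nm = _coded_scene(b=2)
        stack = build_cnn_input(nm, masks)
        np.testing.assert_array_equal(net.cnn_first_frame(stack),
                                      net.cnn_first_frame(stack))

    def test_zero_input_zero_final_layer_gives_zero(self):
        net = _tiny_net()
        out = net.cnn_first_frame(np.zeros((3, 8, 8), dtype=np.float32))
        np.testing.assert_array_equal(out, 0.0)

    def test_channel_count_enforced(self):
        net = _tiny_net(b=2)
        with pytest.raises(ConfigurationError):
            net.cnn_first_frame(np.zeros((5, 8, 8)))


class TestRnnCell:
    def test_deterministic_and_hidden_shape(self):
        net = _tiny_net(b=2, c=8)
        rng = np.random.default_rng(0)
        first = rng.random((6, 6)).astype(np.float32)
        ri = ResidualInput(xbb=rng.random((2, 6, 6)).astype(np.float32))
        hidden = np.zeros((8, 6, 6), dtype=np.float32)
        f1, h1 = net.rnn_cell(first, ri, hidden)
        f2, h2 = net.rnn_cell(first, ri, hidden)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(h1, h2)
        assert f1.shape == (6, 6)
        assert h1.shape == (8, 6, 6)

    def test_hidden_shape_mismatch_rejected(self):
        net = _tiny_net(b=2, c=8)
        ri = ResidualInput(xbb=np.zeros((2, 6, 6), dtype=np.float32))
        with pytest.raises(ConfigurationError):
            net.rnn_cell(np.zeros((6, 6)), ri, np.zeros((4, 6, 6)))

    def test_gradients_match_finite_differences(self):
        """Every weight tensor carries gradient, verified on a 4x4 instance."""
        net = _tiny_net(b=3, c=8, seed=3, dtype=np.float64)
        rng = np.random.default_rng(5)
        yb = rng.random((2, 4, 4))
        ym = yb * 1.3
        cm = (rng.random((3, 4, 4)) < 0.5).astype(np.float64)
        tgt = rng.random((2, 3, 4, 4))
        # move off the zero-init point so the output heads are generic
        out = net._forward_batch(yb, ym, cm, keep_cache=True)
        net.zero_grad()
        net._backward_batch(out, 2 * (out["xf"] - tgt), 2 * (out["xb"] - tgt))
        for p in net.params():
            p.data += 0.01 * np.sign(p.grad) + 1e-3

        def total_loss():
            o = net._forward_batch(yb, ym, cm, keep_cache=False)
            return float(np.sum((o["xf"] - tgt) ** 2)
                         + 0.7 * np.sum((o["xb"] - tgt) ** 2))

        out = net._forward_batch(yb, ym, cm, keep_cache=True)
        net.zero_grad()
        net._backward_batch(out, 2 * (out["xf"] - tgt),
                            1.4 * (out["xb"] - tgt))
        check = np.random.default_rng(1)
        params = net.params()
        assert all(np.any(p.grad != 0) for p in params), \
            "some weight tensor receives no gradient"
        for pi in check.choice(len(params), size=10, replace=False):
            par = params[pi]
            idx = tuple(check.integers(0, s) for s in par.data.shape)
            eps = 1e-6
            orig = par.data[idx]
            par.data[idx] = orig + eps
            lp = total_loss()
            par.data[idx] = orig - eps
            lm = total_loss()
            par.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert par.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestReconstruct:
    def test_output_contract_and_determinism(self):
        net = _tiny_net(b=3, c=8, window=None)
        video, masks, m, _ = _coded_scene(b=3, n=16)
        out1, state = net.reconstruct(m, masks)
        out2, _ = net.reconstruct(m, masks)
        assert out1.frames.shape == (3, 16, 16)
        np.testing.assert_array_equal(out1.frames, out2.frames)
        assert state.forward_hidden.shape == (3, 8, 16, 16)
        np.testing.assert_array_equal(state.forward_hidden[0], 0.0)

    def test_b_mismatch_rejected(self):
        net = _tiny_net(b=2)
        _, masks, m, _ = _coded_scene(b=3)
        with pytest.raises(ConfigurationError):
            net.reconstruct(m, masks)

    def test_state_dict_roundtrip_preserves_output(self):
        net = _tiny_net(b=2, c=8, seed=1)
        _, masks, m, _ = _coded_scene(b=2)
        ref, _ = net.reconstruct(m, masks)
        clone = _tiny_net(b=2, c=8, seed=99)
        clone.load_state_dict(net.state_dict())
        got, _ = clone.reconstruct(m, masks)
        np.testing.assert_array_equal(ref.frames, got.frames)
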