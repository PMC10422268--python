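import numpy as np
import pytest

from cropseg import nn
from cropseg.attnseg import (CBAM, AttentionSegNet, ChannelAttention,
                             NetworkConfig, SpatialAttention, build_a2segnet,
                             load_checkpoint, save_checkpoint)
from cropseg.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestChannelAttention:
    def test_zero_weights_gate_half(self, rng):
        ca = ChannelAttention(4, reduction=2)
        ca.fc0.weight.data[:] = 0
        ca.fc1.weight.data[:] = 0
        x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        gate = ca.gate(Tensor(x)).data
        np.testing.assert_allclose(gate, 0.5, atol=1e-7)
        np.testing.assert_allclose(ca(Tensor(x)).data, 0.5 * x, atol=1e-6)

    def test_spatial_permutation_invariance(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        perm = rng.permutation(36)
        xp = x.reshape(1, 4, -1)[:, :, perm].reshape(1, 4, 6, 6)
        np.testing.assert_allclose(ca.gate(Tensor(x)).data,
                                   ca.gate(Tensor(xp)).data, atol=1e-6)

    def test_hand_computed_gate_scalar_oracle(self, rng):
        # 2x2x4 feature map, r=2, hand-set weights: evaluate the gate formula
        # sigmoid(W1 relu(W0 a) + W1 relu(W0 m)) with explicit loops
        ca = ChannelAttention(4, reduction=2)
        W0 = np.arange(8, dtype=np.float32).reshape(4, 2) * 0.1 - 0.3
        W1 = np.arange(8, dtype=np.float32).reshape(2, 4) * 0.05 - 0.1
        ca.fc0.weight.data = W0.copy()
        ca.fc1.weight.data = W1.copy()
        x = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
        avg = np.array([x[0, c].mean() for c in range(4)])
        mx = np.array([x[0, c].max() for c in range(4)])
        ref = np.zeros(4)
        for vec in (avg, mx):
            h = np.maximum(vec @ W0, 0.0)
            ref += h @ W1
        ref = _sigmoid(ref)
        gate = ca.gate(Tensor(x)).data[0, :, 0, 0]
        np.testing.assert_allclose(gate, ref, atol=1e-5)

    def test_channel_mismatch_raises(self, rng):
        ca = ChannelAttention(4)
        with pytest.raises(ValueError):
            ca(Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32)))

    def test_bottleneck_floor(self):
        ca = ChannelAttention(4, reduction=8)
        assert ca.fc0.weight.shape == (4, 1)


class TestSpatialAttention:
    def test_zero_kernel_gate_half(self, rng):
        sa = SpatialAttention()
        sa.conv.weight.data[:] = 0
        sa.conv.bias.data[:] = 0
        x = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(sa.gate(Tensor(x)).data, 0.5, atol=1e-7)

    def test_channel_permutation_invariance(self, rng):
        sa = SpatialAttention(rng=rng)
        x = rng.normal(size=(1, 5, 8, 8)).astype(np.float32)
        xp = x[:, rng.permutation(5)]
        np.testing.assert_allclose(sa.gate(Tensor(x)).data,
                                   sa.gate(Tensor(xp)).data, atol=1e-6)

    def test_gate_vs_naive_convolution_loop(self, rng):
        # 9x9x3 input: channel mean/max pooling + 7x7 conv + sigmoid,
        # against a direct 4-loop evaluation
        sa = SpatialAttention(rng=rng)
        x = rng.normal(size=(1, 3, 9, 9)).astype(np.float32)
        gate = sa.gate(Tensor(x)).data[0, 0]
        pooled = np.stack([x[0].mean(axis=0), x[0].max(axis=0)])
        w, b = sa.conv.weight.data, sa.conv.bias.data
        pp = np.pad(pooled, ((0, 0), (3, 3), (3, 3)))
        ref = np.zeros((9, 9))
        for r in range(9):
            for c in range(9):
                acc = b[0]
                for ch in range(2):
                    for i in range(7):
                        for j in range(7):
                            acc += pp[ch, r + i, c + j] * w[0, ch, i, j]
                ref[r, c] = _sigmoid(acc)
        np.testing.assert_allclose(gate, ref, atol=1e-5)

    def test_kernel_size_fixed_at_7(self):
        with pytest.raises(ValueError):
            SpatialAttention(kernel_size=5)


class TestCBAM:
    @pytest.mark.parametrize("shape", [(1, 4, 8, 8), (2, 6, 5, 7), (1, 3, 12, 4)])
    def test_shape_conservation(self, shape, rng):
        cbam = CBAM(shape[1], reduction=2, rng=rng)
        x = rng.normal(size=shape).astype(np.float32)
        assert cbam(Tensor(x)).data.shape == shape

    def test_gates_strictly_in_unit_interval(self, rng):
        cbam = CBAM(6, reduction=2, rng=rng)
        x = rng.normal(size=(2, 6, 8, 8)).astype(np.float32)
        cg = cbam.channel.gate(Tensor(x)).data
        sg = cbam.spatial.gate(Tensor(x)).data
        for g in (cg, sg):
            assert (g > 0).all() and (g < 1).all()

    def test_identity_limit_with_saturated_gates(self, rng):
        # positive input + large positive MLP/conv weights drive both
        # sigmoids to ~1, so CBAM approaches the identity
        cbam = CBAM(4, reduction=2)
        cbam.channel.fc0.weight.data[:] = 1.0
        cbam.channel.fc1.weight.data[:] = 100.0
        cbam.spatial.conv.weight.data[:] = 0
        cbam.spatial.conv.bias.data[:] = 100.0
        x = np.abs(rng.normal(size=(1, 4, 6, 6))).astype(np.float32) + 0.5
        out = cbam(Tensor(x)).data
        np.testing.assert_allclose(out, x, rtol=1e-3, atol=1e-3)

    def test_channel_then_spatial_order_matters(self, rng):
        cbam = CBAM(4, reduction=2, rng=rng)
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        forward = cbam(Tensor(x)).data
        # reversed composition: spatial first, then channel
        reversed_out = cbam.channel(cbam.spatial(Tensor(x))).data
        assert not np.allclose(forward, reversed_out, atol=1e-6)

    def test_matches_explicit_composition(self, rng):
        cbam = CBAM(4, reduction=2, rng=rng)
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        fc = nn.mul(Tensor(x), cbam.channel.gate(Tensor(x)))
        expected = nn.mul(fc, cbam.spatial.gate(fc)).data
        np.testing.assert_allclose(cbam(Tensor(x)).data, expected, atol=1e-6)


@pytest.fixture(scope="module")
def small_net():
    return AttentionSegNet(NetworkConfig.scaled(0.125, input_size=64, seed=0))


class TestNetwork:

    def test_output_is_probability_simplex(self, small_net, rng):
        x = rng.normal(size=(2, 8, 64, 64)).astype(np.float32)
        probs = small_net.predict_proba(x)
        assert probs.shape == (2, 3, 64, 64)
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_shape_conservation_any_multiple_of_32(self, small_net, rng):
        for size in (32, 96):
            x = rng.normal(size=(1, 8, size, size)).astype(np.float32)
            assert small_net.predict_proba(x).shape == (1, 3, size, size)

    def test_indivisible_input_rejected(self, small_net, rng):
        with pytest.raises(ValueError):
            small_net.predict_proba(rng.normal(size=(1, 8, 50, 50)).astype(np.float32))

    def test_channel_mismatch_rejected(self, small_net, rng):
        with pytest.raises(ValueError):
            small_net.predict_proba(rng.normal(size=(1, 5, 64, 64)).astype(np.float32))

    def test_duplicated_tile_identical_outputs(self, small_net, rng):
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        batch = np.concatenate([x, x])
        probs = small_net.predict_proba(batch)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_fixed_init_seed_reproducible(self, rng):
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        a = AttentionSegNet(NetworkConfig.scaled(0.25, input_size=64, seed=3))
        b = AttentionSegNet(NetworkConfig.scaled(0.25, input_size=64, seed=3))
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_scaled_concat_arithmetic(self, small_net, rng):
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        small_net.predict_proba(x)
        tr = small_net.last_trace
        cc = small_net.cfg.concat_channels()
        for i in range(5):
            assert tr[f"decoder{i + 1}_concat"][1] == cc[i]

    def test_attention_false_removes_cbam_params(self):
        with_a = AttentionSegNet(NetworkConfig.scaled(0.125, attention=True))
        without = AttentionSegNet(NetworkConfig.scaled(0.125, attention=False))
        assert with_a.num_parameters() > without.num_parameters()

    def test_plain_baseline_without_skips(self, rng):
        # SegNet-style variant: no attention, no skip concatenations
        cfg = NetworkConfig.scaled(0.125, input_size=64, attention=False,
                                   skip_connections=False, seed=0)
        net = AttentionSegNet(cfg)
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (1, 3, 64, 64)
        assert "decoder1_concat" not in net.last_trace
        skipped = AttentionSegNet(NetworkConfig.scaled(
            0.125, input_size=64, attention=False, seed=0))
        assert net.num_parameters() < skipped.num_parameters()

    def test_parameter_count_stability_full_width(self):
        # frozen against architecture drift
        net = build_a2segnet(NetworkConfig())
        assert net.num_parameters() == 27_901_729

    def test_flip_equivariance_with_symmetrized_kernels(self, rng):
        # horizontally symmetrize every conv kernel; the full network then
        # commutes with horizontal flips (zero same-padding is symmetric)
        net = AttentionSegNet(NetworkConfig.scaled(0.125, input_size=64, seed=1))
        for _, p in net.named_parameters():
            if p.data.ndim == 4:
                p.data = 0.5 * (p.data + p.data[:, :, :, ::-1])
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        flipped = net.predict_proba(x[:, :, :, ::-1].copy())
        straight = net.predict_proba(x)
        np.testing.assert_allclose(flipped[:, :, :, ::-1], straight, atol=1e-4)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = AttentionSegNet(NetworkConfig.scaled(0.125, input_size=64, seed=2))
        save_checkpoint(net, tmp_path / "model.npz")
        clone = load_checkpoint(tmp_path / "model.npz")
        x = rng.normal(size=(1, 8, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x), clone.predict_proba(x))

    def test_summary_lists_stages(self):
        net = AttentionSegNet(NetworkConfig.scaled(0.125, input_size=32))
        text = net.summary()
        assert "encoder_output" in text and "decoder5_concat" in text


class TestConfig:
    def test_default_concat_channels_match_printed(self):
        assert NetworkConfig().concat_channels() == (1024, 768, 384, 192, 256)

    def test_five_stages_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(encoder_widths=(64, 128)).validate()

    def test_input_size_multiple_of_32(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100).validate()

    def test_json_round_trip(self):
        cfg = NetworkConfig.scaled(0.5, seed=11)
        clone = NetworkConfig.from_json(cfg.to_json())
        assert clone == cfg


def test_network_gradients_flow_everywhere(rng):
    # one training step must produce a gradient for every parameter
    net = AttentionSegNet(NetworkConfig.scaled(0.125, input_size=32, seed=0))
    x = rng.normal(size=(2, 8, 32, 32)).astype(np.float32)
    y = rng.integers(0, 3, size=(2, 32, 32))
    logits = net.forward(Tensor(x))
    loss, _ = nn.softmax_cross_entropy(logits, y)
    loss.backward()
    missing = [name for name, p in net.named_parameters() if p.grad is None]
    assert not missing, f"parameters without gradient: {missing[:5]}"
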