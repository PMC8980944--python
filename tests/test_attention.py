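"""Oracle and contract tests for the spatial/channel attention modules."""

import numpy as np
import pytest

from strokeseg.attention import (ChannelAttention, CrossSpatialAttention,
                                 SpatialGate, channel_attention_apply,
                                 channel_attention_weights,
                                 cross_spatial_attention, spatial_attention_map)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_spatial_map(f, kernel, bias):
    """Straight-line channel-pool -> 3x3 zero-padded conv -> sigmoid."""
    C, H, W = f.shape
    pooled = np.stack([f.mean(axis=0), f.max(axis=0)])  # (2, H, W)
    padded = np.pad(pooled, ((0, 0), (1, 1), (1, 1)))
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = np.sum(padded[:, i:i + 3, j:j + 3] * kernel) + bias
    return _sigmoid(out)[None]


@pytest.fixture()
def gate(rng):
    return SpatialGate(rng)


def test_spatial_map_shape_independent_of_channels(rng, gate):
    for C in (1, 8, 17):
        f = rng.random((C, 16, 16), dtype=np.float32)
        m = spatial_attention_map(f, gate)
        assert m.shape == (1, 16, 16)
        assert 0 < m.data.min() and m.data.max() < 1


def test_spatial_map_zero_parameters_gives_half(rng, gate):
    gate.conv.weight.data[:] = 0.0
    gate.conv.bias.data[:] = 0.0
    m = spatial_attention_map(np.full((4, 6, 6), 0.3, dtype=np.float32), gate)
    assert np.allclose(m.data, 0.5, atol=1e-6)


def test_spatial_map_matches_straight_line_oracle(rng, gate):
    f = rng.random((2, 3, 3), dtype=np.float32)
    m = spatial_attention_map(f, gate)
    expected = oracle_spatial_map(f, gate.conv.weight.data[0], gate.conv.bias.data[0])
    assert np.allclose(m.data, expected, rtol=1e-5, atol=1e-6)


def test_cross_attention_symmetric_for_equal_inputs(rng):
    csam = CrossSpatialAttention(rng)
    csam.gate_dec.load_state_dict(csam.gate_enc.state_dict())
    f = rng.random((5, 8, 8), dtype=np.float32)
    out = cross_spatial_attention(f, f, csam)
    assert out.shape == (10, 8, 8)
    assert np.allclose(out.data[:5], out.data[5:], atol=1e-6)


def test_cross_attention_annihilates_zero_features(rng):
    csam = CrossSpatialAttention(rng)
    z = np.zeros((3, 8, 8), dtype=np.float32)
    out = cross_spatial_attention(z, z, csam)
    assert np.allclose(out.data, 0.0)


def test_cross_attention_matches_formula_oracle(rng):
    csam = CrossSpatialAttention(rng)
    fe = rng.random((3, 5, 5), dtype=np.float32)
    fd = rng.random((3, 5, 5), dtype=np.float32)
    out = cross_spatial_attention(fe, fd, csam)
    m_e = oracle_spatial_map(fe, csam.gate_enc.conv.weight.data[0],
                             csam.gate_enc.conv.bias.data[0])
    m_d = oracle_spatial_map(fd, csam.gate_dec.conv.weight.data[0],
                             csam.gate_dec.conv.bias.data[0])
    expected = np.concatenate([m_e * fd + fd, m_d * fe + fe], axis=0)
    assert np.allclose(out.data, expected, rtol=1e-5, atol=1e-6)


def test_cross_attention_rejects_shape_mismatch(rng):
    csam = CrossSpatialAttention(rng)
    with pytest.raises(ValueError, match="shape"):
        cross_spatial_attention(np.zeros((3, 8, 8), dtype=np.float32),
                                np.zeros((3, 4, 4), dtype=np.float32), csam)


def test_channel_weights_match_mlp_oracle(rng):
    cam = ChannelAttention(4, reduction=1, rng=rng)
    ss = rng.random((4, 2, 2), dtype=np.float32)
    w = channel_attention_weights(ss, cam)
    assert w.shape == (4,)

    def mlp(v):
        h = np.maximum(v @ cam.fc1.weight.data + cam.fc1.bias.data, 0.0)
        return h @ cam.fc2.weight.data + cam.fc2.bias.data

    avg, mx = ss.mean(axis=(1, 2)), ss.max(axis=(1, 2))
    expected = _sigmoid(mlp(avg) + mlp(mx))
    assert np.allclose(w.data, expected, rtol=1e-5, atol=1e-6)


def test_channel_weights_zeroed_mlp_gives_half(rng):
    cam = ChannelAttention(8, reduction=2, rng=rng)
    for p in cam.parameters():
        p.data[:] = 0.0
    w = channel_attention_weights(rng.random((8, 3, 3), dtype=np.float32), cam)
    assert np.allclose(w.data, 0.5)


def test_channel_weights_hidden_size_floors_at_four(rng):
    cam = ChannelAttention(8, reduction=16, rng=rng)
    assert cam.fc1.weight.shape == (8, 4)


def test_channel_apply_identity_zero_and_scaling(rng):
    ss = rng.random((2, 3, 3), dtype=np.float32)
    assert np.allclose(channel_attention_apply(ss, np.ones(2)).data, ss)
    assert np.allclose(channel_attention_apply(ss, np.zeros(2)).data, 0.0)
    halved = channel_attention_apply(ss, np.array([0.5, 1.0]))
    assert np.allclose(halved.data[0], 0.5 * ss[0])
    assert np.allclose(halved.data[1], ss[1])


def test_channel_apply_rejects_length_mismatch(rng):
    with pytest.raises(ValueError, match="length"):
        channel_attention_apply(rng.random((3, 2, 2), dtype=np.float32), np.ones(5))
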