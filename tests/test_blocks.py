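"""Block-level contracts: brute-force oracles, residual identities,
shape preservation, and gate/softmax behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcunet import nn
from gcunet.blocks import (BlockConfig, CAGPModule, CGRBlock, ConfigurationError,
                           ContextGate, DecoderBlock, GCABlock, GatingParams,
                           MRPBlock, RCAModule, context_gate)
from gcunet.nn.core import Tensor


def _t(a):
    return Tensor(np.asarray(a, dtype=np.float64))


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


# -- context gate ----------------------------------------------------------


def test_context_gate_zero_params_halves_input(rng):
    x = rng.standard_normal((4, 5, 5))
    params = GatingParams(np.zeros((4, 4)), np.zeros(4))
    np.testing.assert_allclose(context_gate(x, params), 0.5 * x, rtol=1e-12)


def test_context_gate_saturates_to_identity(rng):
    x = rng.standard_normal((3, 4, 4))
    params = GatingParams(np.zeros((3, 3)), np.full(3, 1e3))
    np.testing.assert_allclose(context_gate(x, params), x, rtol=1e-9)


def test_context_gate_matches_elementwise_oracle(rng):
    c, h, w = 4, 5, 5
    x = rng.standard_normal((c, h, w))
    params = GatingParams(rng.standard_normal((c, c)), rng.standard_normal(c))
    out = context_gate(x, params)
    # brute force: loop over every pixel and channel
    expected = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            for o in range(c):
                z = sum(params.weight[o, cc] * x[cc, i, j] for cc in range(c))
                z += params.bias[o]
                expected[o, i, j] = x[o, i, j] / (1.0 + np.exp(-z))
    np.testing.assert_allclose(out, expected, rtol=1e-10)


def test_context_gate_shape_mismatch_raises(rng):
    params = GatingParams(np.zeros((3, 3)), np.zeros(3))
    with pytest.raises(ConfigurationError):
        context_gate(rng.standard_normal((4, 2, 2)), params)


def test_context_gate_module_gates_in_open_interval(rng):
    gate_mod = ContextGate(4, rng)
    x = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
    gates = nn.sigmoid(gate_mod.conv(x)).data
    assert np.all(gates > 0.0) and np.all(gates < 1.0)


# -- CGR block -------------------------------------------------------------


def test_cgr_zero_weights_triples_input(rng):
    block = CGRBlock(3, rng).astype(np.float64)
    _zero_params(block)
    x = rng.standard_normal((1, 3, 6, 6))
    out = block(_t(x)).data
    np.testing.assert_allclose(out, 3.0 * x, rtol=1e-10)


def test_cgr_shape_preserved_odd_dims(rng):
    block = CGRBlock(32, rng, kernel_sizes=(3, 5, 7, 9))
    x = Tensor(rng.standard_normal((1, 32, 17, 23)).astype(np.float32))
    assert block(x).shape == (1, 32, 17, 23)


def test_cgr_even_kernel_rejected(rng):
    with pytest.raises(ConfigurationError):
        CGRBlock(4, rng, kernel_sizes=(3, 4))
    with pytest.raises(ConfigurationError):
        BlockConfig(channels=4, cgr_kernel_sizes=(2,))


def test_cgr_gradient_reaches_all_paths(rng):
    """Finite-difference oracle: d(sum(out))/d(theta) for one weight of each
    path matches central differences, and none of them is zero."""
    block = CGRBlock(2, rng, kernel_sizes=(3, 5, 7, 9)).astype(np.float64)
    x = rng.standard_normal((1, 2, 4, 4))
    out = block(_t(x)).sum()
    out.backward()
    eps = 1e-6
    for i in range(4):
        conv = getattr(block, f"conv{i}a")
        analytic = conv.weight.grad[0, 0, 0, 0]
        w = conv.weight.data
        w[0, 0, 0, 0] += eps
        fp = block(_t(x)).data.sum()
        w[0, 0, 0, 0] -= 2 * eps
        fm = block(_t(x)).data.sum()
        w[0, 0, 0, 0] += eps
        numeric = (fp - fm) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-9)
        # the path as a whole must receive gradient (single entries may be
        # zeroed by the ReLU on a tiny input)
        assert np.abs(conv.weight.grad).max() > 0.0
        assert np.abs(getattr(block, f"conv{i}b").weight.grad).max() > 0.0


# -- GCA block -------------------------------------------------------------


def test_gca_zero_final_conv_is_identity(rng):
    block = GCABlock(16, rng)  # expand conv is zero-initialized
    x = Tensor(rng.standard_normal((2, 16, 6, 6)).astype(np.float32))
    np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)


def test_gca_constant_input_context_equals_value(rng):
    block = GCABlock(16, rng).astype(np.float64)
    v = rng.standard_normal(16)
    x = np.broadcast_to(v[None, :, None, None], (1, 16, 5, 7)).copy()
    ctx = block.context(_t(x)).data[0, :, 0, 0]
    np.testing.assert_allclose(ctx, v, rtol=1e-10)


def test_gca_attention_sums_to_one(rng):
    block = GCABlock(16, rng)
    x = Tensor(rng.standard_normal((3, 16, 6, 9)).astype(np.float32))
    attn = block.attention(x).data
    np.testing.assert_allclose(attn.sum(axis=(2, 3)), 1.0, atol=1e-5)


def test_gca_context_matches_loop_oracle(rng):
    block = GCABlock(16, rng).astype(np.float64)
    x = rng.standard_normal((1, 16, 6, 6))
    ctx = block.context(_t(x)).data[0, :, 0, 0]
    # explicit loops: 1x1 conv scores -> softmax -> weighted sum
    w = block.score.weight.data[0, :, 0, 0]
    b = block.score.bias.data[0]
    scores = np.array([[w @ x[0, :, i, j] + b for j in range(6)] for i in range(6)])
    e = np.exp(scores - scores.max())
    attn = e / e.sum()
    expected = np.zeros(16)
    for i in range(6):
        for j in range(6):
            expected += attn[i, j] * x[0, :, i, j]
    np.testing.assert_allclose(ctx, expected, rtol=1e-8)


def test_gca_indivisible_channels_rejected(rng):
    with pytest.raises(ConfigurationError):
        GCABlock(10, rng, ratio=16)
    with pytest.raises(ConfigurationError):
        BlockConfig(channels=10, gca_bottleneck_ratio=16)


# -- MRP block -------------------------------------------------------------


def test_mrp_adds_four_channels(rng):
    block = MRPBlock(64, rng)
    x = Tensor(rng.standard_normal((1, 64, 32, 32)).astype(np.float32))
    assert block(x).shape == (1, 68, 32, 32)


def test_mrp_constant_input_identity_convs(rng):
    block = MRPBlock(1, rng).astype(np.float64)
    for i in range(4):
        conv = getattr(block, f"reduce{i}")
        conv.weight.data[...] = 1.0
        conv.bias.data[...] = 0.0
    x = np.full((1, 1, 14, 14), 3.25)
    out = block(_t(x)).data
    np.testing.assert_allclose(out, 3.25, rtol=1e-12)


def test_mrp_pooled_values_match_window_max_oracle(rng):
    x = rng.standard_normal((1, 4, 8, 8))
    for p in (2, 3, 5, 7):
        pooled = nn.max_pool2d(_t(x), p).data
        ho, wo = 8 // p, 8 // p
        for i in range(ho):
            for j in range(wo):
                win = x[:, :, p * i : p * (i + 1), p * j : p * (j + 1)]
                np.testing.assert_allclose(pooled[:, :, i, j], win.max(axis=(2, 3)))


def test_mrp_input_smaller_than_window_raises(rng):
    block = MRPBlock(4, rng)
    with pytest.raises(ValueError, match="smaller than largest pool window"):
        block(Tensor(np.zeros((1, 4, 5, 5), dtype=np.float32)))


# -- CAGP module -----------------------------------------------------------


def test_cagp_output_channels_match_decoder_entry(rng):
    module = CAGPModule(32, 48, rng)
    x = Tensor(rng.standard_normal((1, 32, 8, 8)).astype(np.float32))
    assert module(x).shape == (1, 48, 8, 8)


def test_cagp_finite_at_zero_params(rng):
    module = CAGPModule(16, 16, rng)
    _zero_params(module)
    x = Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
    out = module(x).data
    assert np.all(np.isfinite(out))


def test_cagp_deterministic_across_builds():
    x = np.random.default_rng(0).standard_normal((1, 16, 8, 8)).astype(np.float32)
    outs = []
    for _ in range(2):
        module = CAGPModule(16, 24, np.random.default_rng(99))
        outs.append(module(Tensor(x)).data)
    np.testing.assert_array_equal(outs[0], outs[1])


# -- decoder / RCA ---------------------------------------------------------


def test_decoder_doubles_spatial(rng):
    block = DecoderBlock(256, 128, 64, rng)
    x = Tensor(rng.standard_normal((1, 256, 16, 16)).astype(np.float32))
    skip = Tensor(rng.standard_normal((1, 128, 32, 32)).astype(np.float32))
    assert block(x, skip).shape == (1, 64, 32, 32)


def test_decoder_misaligned_skip_names_both_shapes(rng):
    block = DecoderBlock(8, 8, 8, rng)
    x = Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32))
    skip = Tensor(np.zeros((1, 8, 31, 32), dtype=np.float32))
    with pytest.raises(ValueError, match=r"31x32.*16x16"):
        block(x, skip)


def test_decoder_chain_8_to_64(rng):
    x = Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
    for size in (16, 32, 64):
        block = DecoderBlock(16, 4, 16, rng)
        skip = Tensor(rng.standard_normal((1, 4, size, size)).astype(np.float32))
        x = block(x, skip)
        assert x.shape[2:] == (size, size)


def test_rca_zero_convs_is_identity(rng):
    block = RCAModule(8, rng)  # projections are zero-initialized
    x = Tensor(rng.standard_normal((2, 8, 12, 12)).astype(np.float32))
    np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)


def test_rca_constant_input_pooling_constant(rng):
    x = np.full((1, 3, 12, 12), -1.5)
    for b in (1, 2, 3, 6):
        pooled = nn.adaptive_avg_pool2d(_t(x), b).data
        np.testing.assert_allclose(pooled, -1.5, rtol=1e-12)


def test_rca_bin1_path_is_global_mean(rng):
    block = RCAModule(4, rng, bins=(1,)).astype(np.float64)
    block.proj0.weight.data[...] = np.eye(4)[:, :, None, None]
    block.proj0.bias.data[...] = 0.0
    x = rng.standard_normal((1, 4, 9, 9))
    out = block(_t(x)).data
    expected = x + x.mean(axis=(2, 3), keepdims=True)
    np.testing.assert_allclose(out, expected, rtol=1e-10)


def test_rca_too_small_input_raises(rng):
    block = RCAModule(4, rng)
    with pytest.raises(ValueError, match="smaller than largest pyramid bin"):
        block(Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32)))


# -- shape-preservation property ------------------------------------------


@settings(max_examples=15, deadline=None)
@given(h=st.integers(1, 12), w=st.integers(1, 12), c=st.sampled_from([4, 8]))
def test_shape_preserving_blocks_property(h, w, c):
    rng = np.random.default_rng(h * 100 + w * 10 + c)
    x = Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32))
    cgr = CGRBlock(c, rng, kernel_sizes=(3, 5))
    assert cgr(x).shape == x.shape
    gca = GCABlock(c, rng, ratio=4)
    assert gca(x).shape == x.shape
    params = GatingParams(rng.standard_normal((c, c)), rng.standard_normal(c))
    assert context_gate(x.data, params).shape == x.data.shape
    rca = RCAModule(c, rng, bins=(1, 2), clip_to_input=True)
    assert rca(x).shape == x.shape


def test_block_config_defaults():
    cfg = BlockConfig(channels=64)
    assert cfg.cgr_kernel_sizes == (3, 5, 7, 9)
    assert cfg.mrp_pool_sizes == (2, 3, 5, 7)
    assert cfg.gca_bottleneck_ratio == 16
    assert cfg.rca_pyramid_bins == (1, 2, 3, 6)
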