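"""Model-zoo tests: block equations against independent NumPy oracles,
unrolling semantics, parameter accounting, and head swapping."""

import numpy as np
import pytest

from revis import nn
from revis.models import (
    BBlock,
    CTBlock,
    ModelSpec,
    RTBlock,
    aggregate_top_down,
    build_model,
    canonical_variant,
    conv_norm_relu,
    count_parameters,
    process_top_down,
    swap_head,
    tiny_spec,
    unroll,
)
from revis.nn import Linear, Tensor


# ---------------------------------------------------------------------------
# Independent oracles (naive loops, no revis.nn machinery)
# ---------------------------------------------------------------------------


def naive_conv(x, w, stride=1, pad=0):
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    y = np.zeros((n, o, ho, wo))
    for ni in range(n):
        for oi in range(o):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[ni, :, i * stride:i * stride + kh,
                               j * stride:j * stride + kw]
                    y[ni, oi, i, j] = (patch * w[oi]).sum()
    return y


def naive_group_norm(x, gamma, beta, groups, eps=1e-5):
    n, c, h, w = x.shape
    g = min(groups, c)
    while c % g:
        g -= 1
    xg = x.reshape(n, g, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
    xn = ((xg - mu) / np.sqrt(var + eps)).reshape(n, c, h, w)
    return xn * gamma + beta


def naive_cnr(x, w, gamma, beta, stride, pad, groups=32):
    return np.maximum(naive_group_norm(naive_conv(x, w, stride, pad),
                                       gamma, beta, groups), 0.0)


# ---------------------------------------------------------------------------
# Functional pieces
# ---------------------------------------------------------------------------


def test_conv_norm_relu_matches_oracle(rng):
    x = rng.standard_normal((1, 2, 4, 4))
    block = RTBlock(2, 4, kernel=3, stride=1, rng=rng)
    y = conv_norm_relu(Tensor(x), block.conv_ff.w, block.norm)
    expected = naive_cnr(x, block.conv_ff.w.data, block.norm.gamma.data,
                         block.norm.beta.data, 1, 1)
    assert np.allclose(y.data, expected, atol=1e-10)
    assert y.data.min() >= 0.0
    zero = conv_norm_relu(Tensor(np.zeros_like(x)), block.conv_ff.w, block.norm)
    assert np.allclose(zero.data, 0.0)


def test_process_top_down(rng):
    # constant map stays constant after pooling and channel averaging
    m = Tensor(np.full((1, 3, 4, 4), 2.5))
    x = Tensor(np.zeros((1, 2, 2, 2)))
    out = process_top_down(m, x)
    assert out.shape == (1, 1, 2, 2)
    assert np.allclose(out.data, 2.5)
    # identity pooling when sizes already match: plain channel mean
    m2 = Tensor(rng.standard_normal((1, 3, 2, 2)))
    assert np.allclose(process_top_down(m2, x).data,
                       m2.data.mean(axis=1, keepdims=True))
    # 2x2 -> 1x1: arithmetic mean of all entries
    m3 = Tensor(rng.standard_normal((1, 5, 2, 2)))
    x1 = Tensor(np.zeros((1, 2, 1, 1)))
    assert np.allclose(process_top_down(m3, x1).data.ravel(), m3.data.mean())


def test_aggregate_top_down(rng):
    x = Tensor(np.zeros((2, 3, 4, 4)))
    empty = aggregate_top_down([], x)
    assert empty.shape == (2, 1, 4, 4) and np.all(empty.data == 0)
    c1 = Tensor(np.full((2, 2, 4, 4), 1.5))
    c2 = Tensor(np.full((2, 2, 8, 8), -2.0))
    out = aggregate_top_down([c1, c2], x)
    assert out.shape == (2, 2, 4, 4)
    assert np.allclose(out.data[:, 0], 1.5)
    assert np.allclose(out.data[:, 1], -2.0)


# ---------------------------------------------------------------------------
# Block forward passes vs oracles
# ---------------------------------------------------------------------------


def test_ct_block_matches_equations(rng):
    block = CTBlock(2, 4, n_higher=2, kernel=3, stride=1, rng=rng)
    x = rng.standard_normal((1, 2, 4, 4))
    m1 = rng.standard_normal((1, 4, 4, 4))
    m2 = rng.standard_normal((1, 4, 2, 2))
    y, state, _ = block(Tensor(x), None, [Tensor(m1), Tensor(m2)])

    ff = naive_cnr(x, block.conv_ff.w.data, block.norm_ff.gamma.data,
                   block.norm_ff.beta.data, 1, 1)
    # M: pool each higher map to x's size, channel-average, concat
    m2_up = np.zeros((1, 4, 4, 4))
    for i in range(4):
        for j in range(4):
            m2_up[0, :, i, j] = m2[0, :, i * 2 // 4, j * 2 // 4]
    M = np.concatenate([m1.mean(axis=1, keepdims=True),
                        m2_up.mean(axis=1, keepdims=True)], axis=1)
    td = naive_cnr(M, block.conv_td.w.data, block.norm_td.gamma.data,
                   block.norm_td.beta.data, 1, 1)
    z = np.concatenate([ff, td], axis=1)
    expected = naive_cnr(z, block.conv_out.w.data, block.norm_out.gamma.data,
                         block.norm_out.beta.data, 1, 1)
    assert np.allclose(y.data, expected, atol=1e-8)
    assert y.shape == ff.shape


def test_ct_block_zero_topdown_first_pass(rng):
    """With no higher-level output yet (M = 0), the top-down branch is inert
    and the block output is fully determined by the feedforward branch."""
    block = CTBlock(2, 4, n_higher=2, kernel=3, stride=1, rng=rng)
    x = rng.standard_normal((1, 2, 4, 4))
    y_none, _, _ = block(Tensor(x), None, None)
    y_empty, _, _ = block(Tensor(x), None, [])
    assert np.allclose(y_none.data, y_empty.data)


def test_clt_block_state_equals_output(rng):
    block = CTBlock(2, 4, n_higher=1, kernel=3, stride=1, lateral=True,
                    rng=rng)
    x = rng.standard_normal((1, 2, 4, 4))
    y0, s0, _ = block(Tensor(x), None, None)
    assert s0 is y0  # s_t = y_t
    m = Tensor(rng.standard_normal((1, 4, 4, 4)))
    y1, s1, _ = block(Tensor(x), s0, [m])
    assert s1 is y1
    assert not np.allclose(y0.data, y1.data)


def test_clt_block_matches_equations(rng):
    block = CTBlock(1, 2, n_higher=1, kernel=3, stride=1, lateral=True,
                    rng=rng)
    x = rng.standard_normal((1, 1, 3, 3))
    s = rng.standard_normal((1, 2, 3, 3))
    m = rng.standard_normal((1, 2, 3, 3))
    y, _, _ = block(Tensor(x), Tensor(s), [Tensor(m)])
    ff = naive_cnr(x, block.conv_ff.w.data, block.norm_ff.gamma.data,
                   block.norm_ff.beta.data, 1, 1)
    rr = naive_cnr(s, block.conv_rr.w.data, block.norm_rr.gamma.data,
                   block.norm_rr.beta.data, 1, 0)
    assert rr.shape == s.shape  # 1x1 stride-1 lateral conv keeps shape
    M = m.mean(axis=1, keepdims=True)
    td = naive_cnr(M, block.conv_td.w.data, block.norm_td.gamma.data,
                   block.norm_td.beta.data, 1, 1)
    z = np.concatenate([ff, rr, td], axis=1)
    expected = naive_cnr(z, block.conv_out.w.data, block.norm_out.gamma.data,
                         block.norm_out.beta.data, 1, 1)
    assert np.allclose(y.data, expected, atol=1e-8)


def test_lateral_block_zero_state_is_feedforward(rng):
    block = RTBlock(2, 3, kernel=3, stride=2, rng=rng)
    x = rng.standard_normal((1, 2, 6, 6))
    y_none, s, _ = block(Tensor(x), None, None)
    y_zero, _, _ = block(Tensor(x), Tensor(np.zeros(s.shape)), None)
    assert np.allclose(y_none.data, y_zero.data, atol=1e-12)
    # two timesteps differ once the state contributes
    y_next, _, _ = block(Tensor(x), s, None)
    assert not np.allclose(y_none.data, y_next.data)


def test_lateral_branch_is_linear(rng):
    """The lateral path is a convolution, hence additive pre-nonlinearity."""
    block = BBlock(2, 3, lateral=True, rng=rng)
    a = rng.standard_normal((1, 3, 6, 6))
    b = rng.standard_normal((1, 3, 6, 6))
    za = nn.conv2d(Tensor(a), block.conv_lat.w, 1, 1).data
    zb = nn.conv2d(Tensor(b), block.conv_lat.w, 1, 1).data
    zab = nn.conv2d(Tensor(a + b), block.conv_lat.w, 1, 1).data
    assert np.allclose(zab, za + zb, atol=1e-9)


def test_b_block_additive_combination(rng):
    block = BBlock(2, 3, higher_c=4, lateral=True, rng=rng)
    x = rng.standard_normal((1, 2, 8, 8))
    out_ff, state, _ = block(Tensor(x), None, None)
    # zero recurrent inputs reproduce the pure feedforward output
    zero_s = Tensor(np.zeros(state.shape))
    zero_h = Tensor(np.zeros((1, 4, 4, 4)))
    out_zero, _, _ = block(Tensor(x), zero_s, [zero_h])
    assert np.allclose(out_ff.data, out_zero.data, atol=1e-12)
    # transposed conv doubles the higher map's spatial size
    h = rng.standard_normal((1, 4, 4, 4))
    td = block.conv_td(Tensor(h))
    assert td.shape == (1, 3, 8, 8)
    # oracle check of the transposed convolution itself
    w = block.conv_td.w.data
    expected = np.zeros((1, 3, 8, 8))
    for ci in range(4):
        for i in range(4):
            for j in range(4):
                for ki in range(4):
                    for kj in range(4):
                        oi, oj = i * 2 + ki - 1, j * 2 + kj - 1
                        if 0 <= oi < 8 and 0 <= oj < 8:
                            expected[0, :, oi, oj] += h[0, ci, i, j] * w[ci, :, ki, kj]
    assert np.allclose(td.data, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# Whole-model behaviour
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("variant", ["VGG11", "C", "B", "CD", "BD", "CS"])
def test_feedforward_models_are_timestep_invariant(variant, rng):
    spec = tiny_spec(variant, timesteps=3)
    model = build_model(spec)
    x = rng.standard_normal((1, 3, spec.resolved_input_size,
                             spec.resolved_input_size))
    trace = unroll(model, x, 3)
    assert trace.logits.shape[0] == 3
    assert np.allclose(trace.logits[0], trace.logits[1])
    assert np.allclose(trace.logits[0], trace.logits[2])


@pytest.mark.parametrize("variant", ["CLT", "CT", "CL", "BLT", "BT", "BL"])
def test_recurrent_first_pass_equals_feedforward_skeleton(variant, rng):
    spec = tiny_spec(variant, timesteps=3)
    model = build_model(spec)
    x = rng.standard_normal((1, 3, spec.resolved_input_size,
                             spec.resolved_input_size))
    trace = unroll(model, x, 3)
    # first pass: zero states and no top-down input by construction
    with nn.no_grad():
        out, _, _ = model.forward_pass(Tensor(x), [None] * len(model.blocks),
                                       [None] * len(model.blocks))
    assert np.allclose(trace.logits[0], out.data, atol=1e-12)
    # later passes diverge for generic weights
    assert not np.allclose(trace.logits[0], trace.logits[-1])


def test_shape_conservation_across_timesteps(rng):
    spec = tiny_spec("CLT", timesteps=3)
    model = build_model(spec)
    x = Tensor(rng.standard_normal((1, 3, spec.resolved_input_size,
                                    spec.resolved_input_size)))
    states = [None] * len(model.blocks)
    srcs = [None] * len(model.blocks)
    shapes = []
    with nn.no_grad():
        for _ in range(3):
            out, states, srcs = model.forward_pass(x, states, srcs)
            shapes.append([s.shape for s in srcs])
    assert shapes[0] == shapes[1] == shapes[2]


def test_structural_diff_c_vs_cv1v1():
    a = build_model(tiny_spec("C"))
    b = build_model(tiny_spec("C-V1V1"))
    names_a = {n for n, _ in a.named_parameters()}
    names_b = {n for n, _ in b.named_parameters()}
    only_b = names_b - names_a
    assert only_b and all(n.startswith("V1.") for n in only_b)
    shared_non_v1 = {n for n in names_a & names_b if not n.startswith("V1.")}
    sa, sb = dict(a.named_parameters()), dict(b.named_parameters())
    assert all(sa[n].shape == sb[n].shape for n in shared_non_v1)


def test_parameter_count_orderings():
    counts = {v: count_parameters(build_model(
        ModelSpec(v, n_classes=8, width_scale=0.25)))
        for v in ["C", "CS", "B", "BLT"]}
    assert counts["C"] < counts["CS"]
    assert counts["B"] < counts["BLT"]


def test_count_parameters_linear_oracle(rng):
    layer = Linear(512, 8, rng=rng)
    assert sum(p.data.size for p in layer.parameters()) == 512 * 8 + 8
    m = build_model(tiny_spec("B"))
    assert count_parameters(m) == count_parameters(m)


def test_swap_head(rng):
    model = build_model(tiny_spec("C", n_classes=1000))
    before = {k: v.copy() for k, v in model.state_dict().items()
              if not k.startswith("decoder.")}
    head_in = model.decoder.head.w.shape[0]
    swap_head(model, 8, seed=1)
    assert model.decoder.head.w.shape == (head_in, 8)
    assert sum(p.data.size for p in model.decoder.head.parameters()) \
        == head_in * 8 + 8
    swap_head(model, 1000, seed=2)
    after = {k: v for k, v in model.state_dict().items()
             if not k.startswith("decoder.")}
    assert all(np.array_equal(before[k], after[k]) for k in before)


@pytest.mark.parametrize("variant", ["CLT", "BLT"])
def test_gradient_reaches_every_parameter(variant, rng):
    """No dead branches: a one-step loss after T=3 passes sends nonzero
    gradient into every weight set (ff, lateral, top-down, out, norms)."""
    spec = tiny_spec(variant, timesteps=3)
    model = build_model(spec).train()
    x = Tensor(rng.standard_normal((2, 3, spec.resolved_input_size,
                                    spec.resolved_input_size)))
    states = [None] * len(model.blocks)
    srcs = [None] * len(model.blocks)
    for _ in range(3):
        out, states, srcs = model.forward_pass(x, states, srcs)
    loss = nn.cross_entropy(out, np.array([0, 1]))
    loss.backward()
    dead = [n for n, p in model.named_parameters()
            if p.grad is None or np.abs(p.grad).max() == 0]
    assert dead == []


def test_variant_name_normalisation():
    assert canonical_variant("c v1-v1") == "C-V1V1"
    assert canonical_variant("blt") == "BLT"
    with pytest.raises(Exception):
        canonical_variant("XYZ")
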