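"""SE / non-local / deformed non-local blocks against brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest

from dnlseg.attention import (DNLBlock, NonLocalBlock, SEBlock,
                              dnl_apply, dnl_attention, fg_product_op_counts,
                              fit_reduction, nl_apply, nl_attention, se_apply)

from oracles import (dnl_oracle_from_block, nl_attention_oracle,
                     nl_oracle_from_block, se_oracle)

TOL = 1e-5


def _zero_biases(module):
    for name, p in module.named_parameters():
        if name.endswith("bias") or name.endswith("beta"):
            p.data = np.zeros_like(p.data)


# ----------------------------------------------------------------- SE block

def test_se_zero_input_stays_zero(rng):
    block = SEBlock(4, 2, rng=rng)
    _zero_biases(block)
    out = se_apply(np.zeros((4, 2, 2)), block)
    assert np.all(out == 0)


def test_se_zero_weights_gate_half(rng):
    block = SEBlock(4, 2, rng=rng)
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    x = rng.normal(size=(4, 3, 3))
    assert np.allclose(se_apply(x, block), 0.5 * x)


def test_se_matches_loop_oracle(rng):
    block = SEBlock(4, 2, rng=rng)
    x = rng.normal(size=(4, 3, 3))
    expected = se_oracle(x, block.fc1.weight.data, block.fc1.bias.data,
                         block.fc2.weight.data, block.fc2.bias.data)
    assert np.allclose(se_apply(x, block), expected, atol=TOL)


def test_se_shape_and_reduction_validation(rng):
    with pytest.raises(ValueError, match="does not divide"):
        SEBlock(6, 4, rng=rng)
    block = SEBlock(4, 2, rng=rng)
    with pytest.raises(ValueError, match="channels"):
        se_apply(np.zeros((3, 2, 2)), block)


def test_fit_reduction_picks_largest_divisor():
    assert fit_reduction(8, 16) == 8
    assert fit_reduction(12, 8) == 6
    assert fit_reduction(7, 3) == 1


# ---------------------------------------------------------------- NL block

def test_nl_single_position_reduces_to_linear_chain(rng):
    block = NonLocalBlock(3, rng=rng, bias=False)
    x = rng.normal(size=(3, 1, 1))
    wg = block.g.weight.data[:, :, 0, 0]
    wz = block.wz.weight.data[:, :, 0, 0]
    expected = wz @ (wg @ x[:, 0, 0]) + x[:, 0, 0]
    assert np.allclose(nl_apply(x, block)[:, 0, 0], expected, atol=TOL)


def test_nl_constant_input_gives_uniform_attention(rng):
    block = NonLocalBlock(3, rng=rng)
    x = np.ones((3, 3, 4)) * np.array([0.3, -1.2, 2.0])[:, None, None]
    attn = nl_attention(x, block)
    assert np.allclose(attn, 1.0 / 12, atol=1e-9)
    out = nl_apply(x, block)
    # every spatial position carries the same output vector
    assert np.allclose(out, out[:, :1, :1], atol=1e-9)


def test_nl_zero_embeddings_give_uniform_attention(rng):
    block = NonLocalBlock(2, rng=rng)
    block.theta.weight.data = np.zeros_like(block.theta.weight.data)
    block.phi.weight.data = np.zeros_like(block.phi.weight.data)
    attn = nl_attention(rng.normal(size=(2, 2, 2)), block)
    assert np.allclose(attn, 0.25)


@pytest.mark.parametrize("similarity", ["embedded_gaussian", "dot_product"])
def test_nl_matches_pairwise_oracle(rng, similarity):
    block = NonLocalBlock(3, similarity=similarity, rng=rng)
    x = rng.uniform(-1, 1, size=(3, 4, 4))
    assert np.allclose(nl_apply(x, block), nl_oracle_from_block(x, block),
                       atol=TOL)


def test_nl_attention_matches_direct_evaluation(rng):
    block = NonLocalBlock(2, rng=rng)
    x = np.arange(8).reshape(2, 2, 2).astype(float) / 4.0
    expected = nl_attention_oracle(
        x, block.theta.weight.data, block.theta.bias.data,
        block.phi.weight.data, block.phi.bias.data, block.similarity)
    assert np.allclose(nl_attention(x, block), expected, atol=TOL)


def test_nl_attention_rows_stochastic(rng):
    block = NonLocalBlock(3, rng=rng)
    attn = nl_attention(rng.normal(size=(3, 4, 3)), block)
    assert attn.shape == (12, 12)
    assert np.all(attn >= 0)
    assert np.allclose(attn.sum(axis=1), 1.0, atol=1e-6)


def test_nl_dot_product_normalised_by_position_count(rng):
    block = NonLocalBlock(2, similarity="dot_product", rng=rng)
    x = rng.normal(size=(2, 2, 3))
    expected = nl_attention_oracle(
        x, block.theta.weight.data, block.theta.bias.data,
        block.phi.weight.data, block.phi.bias.data, "dot_product")
    assert np.allclose(nl_attention(x, block), expected, atol=TOL)


def test_nl_residual_identity_with_zero_wz(rng):
    block = NonLocalBlock(3, rng=rng)
    block.wz.weight.data = np.zeros_like(block.wz.weight.data)
    block.wz.bias.data = np.zeros_like(block.wz.bias.data)
    x = rng.normal(size=(3, 3, 3))
    assert np.array_equal(nl_apply(x, block), x)


def test_nl_rejects_non_finite_input(rng):
    block = NonLocalBlock(2, rng=rng)
    x = np.zeros((2, 2, 2))
    x[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        nl_apply(x, block)


# --------------------------------------------------------------- DNL block

def test_dnl_attention_is_channel_by_channel(rng):
    block = DNLBlock(8, inner_channels=8, rate=2, se_reduction=2, rng=rng)
    x = rng.normal(size=(8, 4, 4))
    attn = dnl_attention(x, block)
    assert attn.shape == (8, 8)          # C̄ x C̄, not (HW) x (HW)
    assert np.all(attn >= 0)
    assert np.allclose(attn.sum(axis=1), 1.0, atol=1e-6)


def test_dnl_matches_per_equation_oracle(rng):
    block = DNLBlock(4, inner_channels=4, rate=2, se_reduction=2, rng=rng)
    x = rng.uniform(-1, 1, size=(4, 3, 3))
    assert np.allclose(dnl_apply(x, block), dnl_oracle_from_block(x, block),
                       atol=TOL)


def test_dnl_oracle_agreement_without_gate(rng):
    block = DNLBlock(4, rate=4, se_reduction=4, gate="none", rng=rng)
    x = rng.uniform(-1, 1, size=(4, 2, 5))
    assert np.allclose(dnl_apply(x, block), dnl_oracle_from_block(x, block),
                       atol=TOL)


def test_dnl_residual_identity_with_zero_channel_weights(rng):
    block = DNLBlock(4, rate=2, se_reduction=2, gate="none", rng=rng)
    block.expand.weight.data = np.zeros_like(block.expand.weight.data)
    block.expand.bias.data = np.zeros_like(block.expand.bias.data)
    x = rng.normal(size=(4, 3, 3))
    assert np.array_equal(dnl_apply(x, block), x)


def test_dnl_spatial_permutation_equivariance(rng):
    block = DNLBlock(4, rate=2, se_reduction=2, rng=rng)
    x = rng.normal(size=(4, 2, 3))
    perm = rng.permutation(6)
    xp = x.reshape(4, 6)[:, perm].reshape(4, 2, 3)
    out = dnl_apply(x, block).reshape(4, 6)
    outp = dnl_apply(xp, block).reshape(4, 6)
    assert np.allclose(out[:, perm], outp, atol=1e-9)


def test_dnl_rejects_bad_rate(rng):
    with pytest.raises(ValueError, match="rate"):
        DNLBlock(4, inner_channels=4, rate=3, rng=rng)


# ------------------------------------------------------------- complexity

def test_fg_product_op_counts_examples():
    r = fg_product_op_counts(8, 4, 4)
    assert (r.nl_fg_macs, r.dnl_fg_macs, r.ratio) == (2048, 1024, Fraction(2))
    assert fg_product_op_counts(16, 4, 4).ratio == 1     # C̄ == HW break-even
    assert fg_product_op_counts(16, 96, 96).ratio == Fraction(9216, 16) == 576


def test_fg_product_ratio_exact_on_exhaustive_grid():
    for cbar in range(1, 9):
        for h in range(1, 9):
            for w in range(1, 9):
                r = fg_product_op_counts(cbar, h, w)
                assert r.ratio == Fraction(h * w, cbar)
                assert r.nl_fg_macs == cbar * (h * w) ** 2
                assert r.dnl_fg_macs == h * w * cbar ** 2


def test_fg_product_rejects_degenerate_dims():
    with pytest.raises(ValueError):
        fg_product_op_counts(0, 4, 4)
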