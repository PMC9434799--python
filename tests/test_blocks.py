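"""Behavioral oracles for the residual, attention and dilated blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmunet import autodiff as ad
from mmunet.autodiff import Tensor
from mmunet.blocks import (
    DilatedConvBlock,
    HybridAttention,
    PlainDoubleConv,
    ResidualConv,
    _channel_pools,
)

RNG = lambda s=0: np.random.default_rng(s)


def zero_block(block):
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    return block


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


# -- residual convolution --------------------------------------------------


def test_residual_conv_zero_main_branch_is_identity_shortcut():
    rc = ResidualConv(2, 2, rng=RNG(0))
    zero_block(rc)
    rc.bn1.gamma.data[:] = 1.0  # zero_block also cleared the BN scales
    rc.bn2.gamma.data[:] = 1.0
    # identity 1x1 shortcut
    rc.shortcut.weight.data[:] = np.eye(2)[:, :, None, None]
    x = np.abs(RNG(1).normal(size=(1, 2, 6, 6))).astype(np.float32)
    out = rc(Tensor(x)).data
    np.testing.assert_allclose(out, x, atol=1e-6)


@pytest.mark.parametrize("in_ch,out_ch,h,w", [(1, 3, 4, 4), (3, 2, 8, 6), (2, 2, 16, 16)])
def test_residual_conv_shape_contract(in_ch, out_ch, h, w):
    rc = ResidualConv(in_ch, out_ch, rng=RNG(2))
    out = rc(Tensor(RNG(3).normal(size=(2, in_ch, h, w)).astype(np.float32)))
    assert out.shape == (2, out_ch, h, w)


def test_residual_conv_channel_mismatch_raises():
    rc = ResidualConv(2, 3, rng=RNG(4))
    with pytest.raises(ValueError, match="2 input channels"):
        rc(Tensor(np.zeros((1, 5, 4, 4), dtype=np.float32)))


# -- channel attention -----------------------------------------------------


def test_channel_mask_zero_weights_is_half():
    hab = zero_block(HybridAttention(3, rng=RNG(5)))
    mask = hab.channel_mask(Tensor(RNG(6).normal(size=(2, 3, 5, 5)).astype(np.float32)))
    np.testing.assert_allclose(mask.data, 0.5, atol=1e-7)


def test_channel_pools_on_constant_channel():
    x = np.zeros((1, 2, 4, 4), dtype=np.float32)
    x[0, 0] = 3.25  # constant channel: GAP = GMP = c and range = 0
    x[0, 1] = RNG(7).normal(size=(4, 4))
    gap, gmp, grp = _channel_pools(Tensor(x))
    assert gap.data[0, 0] == pytest.approx(3.25)
    assert gmp.data[0, 0] == pytest.approx(3.25)
    assert grp.data[0, 0] == pytest.approx(0.0)


def test_channel_mask_matches_hand_oracle_with_identity_mlp():
    """With an identity MLP the mask is sigmoid(GAP + GMP + GRP) per channel."""
    hab = HybridAttention(2, rng=RNG(8))
    for fc in (hab.fc1, hab.fc2):
        fc.weight.data = np.eye(2, dtype=np.float32)
        fc.bias.data[:] = 0.0
    x = np.abs(RNG(9).normal(size=(1, 2, 2, 2))).astype(np.float32)  # >= 0: ReLU transparent
    got = hab.channel_mask(Tensor(x)).data[0]
    gap = x[0].mean(axis=(1, 2))
    gmp = x[0].max(axis=(1, 2))
    grp = gmp - x[0].min(axis=(1, 2))
    np.testing.assert_allclose(got, sigmoid(gap + gmp + grp), atol=1e-6)


# -- spatial attention -----------------------------------------------------


def test_spatial_mask_zero_weights_is_half_and_shape():
    hab = zero_block(HybridAttention(4, rng=RNG(10)))
    f = Tensor(RNG(11).normal(size=(2, 4, 9, 7)).astype(np.float32))
    mask = hab.spatial_mask(f)
    assert mask.shape == (2, 1, 9, 7)
    np.testing.assert_allclose(mask.data, 0.5, atol=1e-7)


def test_spatial_mask_matches_loop_conv_oracle():
    hab = HybridAttention(1, rng=RNG(12))
    kernel = RNG(13).normal(size=(1, 3, 7, 7)).astype(np.float32)
    hab.spatial_conv.weight.data = kernel
    hab.spatial_conv.bias.data[:] = 0.25
    x = RNG(14).normal(size=(1, 1, 8, 8)).astype(np.float32)
    got = hab.spatial_mask(Tensor(x)).data[0, 0]

    pooled = np.stack([x[0].mean(axis=0), x[0].max(axis=0), np.zeros((8, 8))])  # range of 1 ch = 0
    padded = np.pad(pooled, ((0, 0), (3, 3), (3, 3)))
    want = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            want[i, j] = (padded[:, i : i + 7, j : j + 7] * kernel[0]).sum() + 0.25
    np.testing.assert_allclose(got, sigmoid(want), atol=1e-5)


# -- hybrid attention block ------------------------------------------------


def test_hab_zero_weights_quarters_the_input():
    hab = zero_block(HybridAttention(3, rng=RNG(15)))
    x = RNG(16).normal(size=(2, 3, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(hab(Tensor(x)).data, 0.25 * x, atol=1e-6)


@pytest.mark.parametrize("order", ["channel_first", "spatial_first", "parallel"])
def test_hab_strictly_attenuates(order):
    hab = HybridAttention(3, order=order, rng=RNG(17))
    x = RNG(18).normal(size=(1, 3, 5, 5)).astype(np.float32)
    x[x == 0] = 0.1
    out = hab(Tensor(x)).data
    assert (np.abs(out) < np.abs(x)).all()


def test_hab_channel_first_equals_manual_composition():
    hab = HybridAttention(3, rng=RNG(19))
    x = Tensor(RNG(20).normal(size=(2, 3, 6, 6)).astype(np.float32))
    got = hab(x).data
    g = (x * hab.channel_mask(x).reshape(2, 3, 1, 1))
    want = (g * hab.spatial_mask(g)).data
    np.testing.assert_allclose(got, want, atol=1e-7)


def test_hab_unknown_order_rejected():
    with pytest.raises(ValueError, match="unknown attention order"):
        HybridAttention(3, order="diagonal", rng=RNG(21))


# -- dilated convolution block --------------------------------------------


@pytest.mark.parametrize("c,h,w", [(1, 5, 5), (3, 8, 6), (2, 3, 3)])
def test_dcb_preserves_shape(c, h, w):
    dcb = DilatedConvBlock(c, rng=RNG(22))
    x = Tensor(RNG(23).normal(size=(2, c, h, w)).astype(np.float32))
    assert dcb(x).shape == (2, c, h, w)


def test_dcb_zero_weights_outputs_reduce_bias():
    dcb = zero_block(DilatedConvBlock(2, rng=RNG(24)))
    dcb.reduce.bias.data[:] = [1.5, -0.5]
    out = dcb(Tensor(RNG(25).normal(size=(1, 2, 4, 4)).astype(np.float32))).data
    np.testing.assert_allclose(out[0, 0], 1.5, atol=1e-6)
    np.testing.assert_allclose(out[0, 1], -0.5, atol=1e-6)


def _impulse_response_support(branch_index: int) -> np.ndarray:
    """Route one branch of a 1-channel DCB through the reducer, hit it with
    a centered impulse, and return the boolean support of the response."""
    dcb = zero_block(DilatedConvBlock(1, rng=RNG(26)))
    for conv in (dcb.branch1, dcb.branch2, dcb.branch3, dcb.branch4a, dcb.branch4b):
        conv.weight.data[:] = 1.0
    dcb.reduce.weight.data[0, branch_index, 0, 0] = 1.0
    x = np.zeros((1, 1, 13, 13), dtype=np.float32)
    x[0, 0, 6, 6] = 1.0
    return np.abs(dcb(Tensor(x)).data[0, 0]) > 1e-8


def test_dcb_dilation3_branch_support_is_7x7():
    support = _impulse_response_support(2)
    ys, xs = np.where(support)
    assert (ys.min(), ys.max(), xs.min(), xs.max()) == (3, 9, 3, 9)
    # dilation-3 3x3 kernel: 9 taps spread over a 7x7 envelope
    assert support.sum() == 9


def test_dcb_stacked_dilation2_branch_support_is_9x9():
    support = _impulse_response_support(3)
    ys, xs = np.where(support)
    assert (ys.min(), ys.max(), xs.min(), xs.max()) == (2, 10, 2, 10)
    # two stacked dilation-2 kernels: taps on the even lattice of a 9x9 envelope
    assert support.sum() == 25


def test_dcb_gap_branch_broadcasts_mean():
    dcb = zero_block(DilatedConvBlock(1, rng=RNG(27)))
    dcb.reduce.weight.data[0, 4, 0, 0] = 1.0  # select the pooling branch
    x = RNG(28).normal(size=(1, 1, 6, 6)).astype(np.float32)
    out = dcb(Tensor(x)).data[0, 0]
    np.testing.assert_allclose(out, x.mean(), atol=1e-6)


# -- shared properties -----------------------------------------------------


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    c=st.integers(1, 4),
    h=st.sampled_from([2, 4, 6, 8]),
    w=st.sampled_from([2, 4, 6, 8]),
    seed=st.integers(0, 50),
)
def test_blocks_preserve_spatial_size_and_masks_in_unit_interval(c, h, w, seed):
    rng = RNG(seed)
    # moderate amplitude keeps the sigmoid masks away from float32 saturation
    x = Tensor((0.2 * rng.normal(size=(1, c, h, w))).astype(np.float32))
    hab = HybridAttention(c, rng=rng)
    dcb = DilatedConvBlock(c, rng=rng)
    rc = ResidualConv(c, c + 1, rng=rng)
    assert hab(x).shape == x.shape
    assert dcb(x).shape == x.shape
    assert rc(x).shape == (1, c + 1, h, w)
    cm = hab.channel_mask(x).data
    sm = hab.spatial_mask(x).data
    assert ((cm > 0) & (cm < 1)).all()
    assert ((sm > 0) & (sm < 1)).all()
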