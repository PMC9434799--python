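"""Assembly, shape contracts, variants and parameter accounting."""

import numpy as np
import pytest

from mmunet import autodiff as ad
from mmunet.network import (
    NetworkConfig,
    build,
    make_variant,
    parameter_budget_m,
)
from mmunet.nn import Conv2d


def tiny(variant="full", **kw):
    kw.setdefault("base_channels", 2)
    kw.setdefault("input_size", 16)
    kw.setdefault("seed", 5)
    return build(make_variant(variant, **kw))


def test_output_shape_matches_input_shape():
    net = tiny("full", input_size=32)
    x = np.random.default_rng(0).normal(size=(2, 4, 32, 32)).astype(np.float32)
    out = net.forward(x)
    assert out.shape == (2, 4, 32, 32)
    assert np.isfinite(out.data).all()


def test_fully_convolutional_across_sizes():
    net = tiny("baseline", input_size=16)
    for size in (16, 32):
        x = np.zeros((1, 4, size, size), dtype=np.float32)
        assert net.forward(x).shape == (1, 4, size, size)


def test_wrong_modality_count_raises():
    net = tiny()
    with pytest.raises(ValueError, match=r"\(N, 4, H, W\)"):
        net.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))


def test_indivisible_size_raises():
    net = tiny()
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 4, 24, 24), dtype=np.float32))


def test_batch_permutation_equivariance_in_eval_mode():
    net = tiny("full")
    net.set_train(False)
    x = np.random.default_rng(1).normal(size=(3, 4, 16, 16)).astype(np.float32)
    perm = [2, 0, 1]
    np.testing.assert_allclose(
        net.forward(x).data[perm], net.forward(x[perm]).data, atol=1e-5
    )


def test_hab_order_irrelevant_when_blocks_disabled():
    x = np.random.default_rng(2).normal(size=(1, 4, 16, 16)).astype(np.float32)
    outs = []
    for order in ("channel_first", "spatial_first", "parallel"):
        net = build(
            make_variant("baseline", base_channels=2, input_size=16, seed=7, hab_order=order)
        )
        net.set_train(False)
        outs.append(net.forward(x).data)
    np.testing.assert_array_equal(outs[0], outs[1])
    np.testing.assert_array_equal(outs[0], outs[2])


def test_forward_equals_manual_stage_composition():
    """The wired forward pass equals composing encoder/decoder pieces by hand."""
    net = tiny("full")
    net.set_train(False)
    x = np.random.default_rng(3).normal(size=(1, 4, 16, 16)).astype(np.float32)
    want = net.forward(x).data

    t = ad.Tensor(x)
    skips, bottoms = [], []
    for m, enc in enumerate(net.encoders):
        s, bottom = enc(t[:, m : m + 1])
        skips.append(s)
        bottoms.append(bottom)
    h = net.bottleneck(ad.concat(bottoms, axis=1))
    for i, s in enumerate(reversed(range(net.config.depth))):
        up = net.deconvs[i](h)
        h = net.dec_convs[i](ad.concat([up] + [sk[s] for sk in skips], axis=1)) + up
    got = net.head(h).data
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_make_variant_switches():
    base = make_variant("baseline")
    assert not base.hab_enabled and not base.dcb_enabled
    full = make_variant("full")
    assert full.hab_enabled and full.dcb_enabled
    assert full.hab_order == "channel_first" and full.dcb_position == "after_stage2"
    assert make_variant("dcb_after_stage4").dcb_position == "after_stage4"
    assert make_variant("spatial_first").hab_order == "spatial_first"
    assert make_variant("parallel_attention").hab_order == "parallel"
    with pytest.raises(ValueError, match="baseline, dcb_only"):
        make_variant("resnet")


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(input_size=100)
    with pytest.raises(ValueError, match="hab_order"):
        NetworkConfig(hab_order="sideways")
    with pytest.raises(ValueError, match="dcb_position"):
        NetworkConfig(dcb_position="after_stage3")
    cfg = NetworkConfig()
    assert cfg.stage_channels == (32, 64, 128, 256)


def test_single_1x1_conv_has_two_parameters():
    conv = Conv2d(1, 1, 1, pad=0, rng=np.random.default_rng(0))
    assert conv.count_parameters() == 2


def test_parameter_count_ordering_across_variants():
    counts = {
        name: build(make_variant(name, base_channels=4, input_size=16)).count_parameters()
        for name in ("baseline", "dcb_only", "hab_only", "full")
    }
    assert counts["full"] > counts["dcb_only"] > counts["baseline"]
    assert counts["full"] > counts["hab_only"] > counts["baseline"]


def test_summary_reports_stage_shapes():
    net = tiny("full", base_channels=2, input_size=16)
    text = net.summary()
    assert "4@16*16*2" in text
    assert "Multimodal fusion    1*1*64" in text
    assert "16*16*4" in text


def test_weights_round_trip(tmp_path):
    net = tiny("full")
    net.set_train(False)
    x = np.random.default_rng(4).normal(size=(1, 4, 16, 16)).astype(np.float32)
    want = net.forward(x).data
    path = tmp_path / "w.npz"
    net.save_weights(path)
    other = tiny("full", seed=123)  # different init
    other.set_train(False)
    other.load_weights(path)
    np.testing.assert_array_equal(other.forward(x).data, want)


def test_parameter_budget_helper_matches_count():
    cfg = make_variant("baseline", base_channels=2, input_size=16)
    assert parameter_budget_m(cfg) == pytest.approx(build(cfg).count_parameters() / 1e6)
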