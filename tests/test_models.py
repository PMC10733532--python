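"""Architecture contracts: blocks, gates, fusion, builds and checkpoints."""

import numpy as np
import pytest

from naunet.models import (AttentionGate, AttentionUNet, ConvBlock,
                           ModelConfig, NAUNet, NeighborFuse, UNetPlusPlus,
                           UpConv, attention_gate, build_model,
                           load_checkpoint, save_checkpoint)
from naunet.nn import autograd as ag
from naunet.nn.modules import BatchNorm2d, Conv2d
from naunet.nn.optim import Adam

from conftest import TINY_SCHEDULE


def layer_walk_params(module):
    """Independent parameter oracle: k^2*c_in*c_out + c_out per convolution
    (with bias), 2*c per batch normalization, summed over the module tree."""
    total = 0
    for m in module.modules():
        if isinstance(m, Conv2d):
            total += m.kernel_size ** 2 * m.in_channels * m.out_channels
            if m.bias is not None:
                total += m.out_channels
        elif isinstance(m, BatchNorm2d):
            total += 2 * m.channels
    return total


# -- blocks ----------------------------------------------------------------

@pytest.mark.parametrize("cin,cout,hw", [(3, 64, 64), (64, 128, 32)])
def test_conv_block_preserves_spatial_dims(rng, cin, cout, hw):
    block = ConvBlock(cin, cout, rng=rng)
    x = rng.normal(size=(1, cin, hw, hw)).astype(np.float32)
    assert block(ag.Tensor(x)).shape == (1, cout, hw, hw)


def test_conv_block_parameter_count_closed_form(rng):
    # two 3x3 convs + two BNs for 3 -> 64: (3*3*3*64+64) + (3*3*64*64+64) + 2*(2*64)
    assert ConvBlock(3, 64, rng=rng).num_parameters() == 38976


def test_conv_block_rejects_bad_channels(rng):
    with pytest.raises(ValueError):
        ConvBlock(3, 0, rng=rng)


def test_up_conv_doubles_spatial_dims(rng):
    up = UpConv(128, 64, rng=rng)
    x = rng.normal(size=(1, 128, 16, 16)).astype(np.float32)
    assert up(ag.Tensor(x)).shape == (1, 64, 32, 32)


def test_neighbor_fuse_channel_arithmetic(rng):
    fuse = NeighborFuse(64, rng=rng).eval()
    deep = rng.normal(size=(1, 128, 8, 8)).astype(np.float32)
    shallow = rng.normal(size=(1, 64, 16, 16)).astype(np.float32)
    out = fuse(ag.Tensor(deep), ag.Tensor(shallow))
    assert out.shape == (1, 128, 16, 16)
    # concatenation order is [transformed deep, shallow]
    np.testing.assert_array_equal(out.data[:, 64:], shallow)


def test_neighbor_fuse_rejects_mismatched_inputs(rng):
    fuse = NeighborFuse(64, rng=rng)
    deep = ag.Tensor(np.zeros((1, 192, 8, 8), dtype=np.float32))
    shallow = ag.Tensor(np.zeros((1, 64, 16, 16), dtype=np.float32))
    with pytest.raises(ValueError) as err:
        fuse(deep, shallow)
    assert "192" in str(err.value) and "64" in str(err.value)


# -- attention gate --------------------------------------------------------

def _identity_gate(kernel=1):
    """Gate with all conv weights 1, biases 0 and identity batch norms."""
    gate = AttentionGate(1, 1, 1, kernel=kernel).eval()
    for m in gate.modules():
        if isinstance(m, Conv2d):
            m.weight.data[:] = 1.0
            m.bias.data[:] = 0.0
    return gate


def test_attention_gate_hand_computed_single_pixel():
    """e'=2, d=3, unit weights: q=ReLU(5), alpha=sigmoid(5), d'=alpha*3."""
    gate = _identity_gate()
    e = ag.Tensor(np.full((1, 1, 1, 1), 2.0, dtype=np.float32))
    d = ag.Tensor(np.full((1, 1, 1, 1), 3.0, dtype=np.float32))
    out = attention_gate(e, d, gate)
    alpha = 1.0 / (1.0 + np.exp(-5.0))
    assert alpha == pytest.approx(0.99331, abs=1e-5)
    assert out.data.item() == pytest.approx(2.97992, abs=1e-5)


def test_attention_gate_saturation_limits(rng):
    """Large +/- psi bias forces identity / zero gating."""
    d = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    e = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    for bias, expect in [(40.0, d), (-40.0, np.zeros_like(d))]:
        gate = AttentionGate(8, 4, 2, kernel=3, rng=rng).eval()
        gate.psi.bias.data[:] = bias
        gate.psi.weight.data[:] = 0.0
        out = gate(ag.Tensor(e), ag.Tensor(d))
        np.testing.assert_allclose(out.data, expect, atol=1e-6)


def test_attention_gate_alpha_in_unit_interval_and_contracts(rng):
    gate = AttentionGate(8, 4, 2, kernel=3, rng=rng).eval()
    e = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
    d = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
    out = gate(ag.Tensor(e), ag.Tensor(d))
    alpha = gate.last_alpha.data
    assert np.all((alpha > 0) & (alpha < 1))
    assert np.all(np.abs(out.data) <= np.abs(d) + 1e-7)


def test_attention_gate_spatial_mismatch_raises(rng):
    gate = AttentionGate(4, 4, 2, rng=rng)
    with pytest.raises(ValueError, match="spatial"):
        gate(ag.Tensor(np.zeros((1, 4, 8, 8))), ag.Tensor(np.zeros((1, 4, 4, 4))))


# -- whole networks --------------------------------------------------------

def _count_gates(model):
    return sum(isinstance(m, AttentionGate) for m in model.modules())


@pytest.mark.parametrize("variant,cls", [("nau_net", NAUNet),
                                         ("attention_unet", AttentionUNet),
                                         ("unet_pp", UNetPlusPlus)])
def test_build_model_variants_and_shape_preservation(variant, cls):
    cfg = ModelConfig(variant=variant, channel_schedule=TINY_SCHEDULE, seed=3)
    model = build_model(cfg)
    assert isinstance(model, cls)
    x = np.random.default_rng(0).normal(size=(1, 3, 48, 64)).astype(np.float32)
    y = model.eval()(x)
    assert y.shape == (1, 1, 48, 64)
    assert np.all((y.data > 0) & (y.data < 1))


def test_nau_and_attention_unet_have_four_gates():
    for variant in ("nau_net", "attention_unet"):
        cfg = ModelConfig(variant=variant, channel_schedule=TINY_SCHEDULE)
        assert _count_gates(build_model(cfg)) == 4


def test_unsupported_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        ModelConfig(variant="segnet")


def test_forward_rejects_indivisible_dims(tiny_config):
    model = build_model(tiny_config)
    with pytest.raises(ValueError, match="divisible by 16"):
        model(np.zeros((1, 3, 50, 50), dtype=np.float32))


def test_forward_is_deterministic(tiny_config, rng):
    model = build_model(tiny_config).eval()
    x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
    y1, y2 = model(x).data, model(x).data
    np.testing.assert_array_equal(y1, y2)


def test_channel_schedule_must_double():
    with pytest.raises(ValueError, match="double"):
        ModelConfig(channel_schedule=(64, 128, 256, 512, 512))
    with pytest.raises(ValueError, match="5 entries"):
        ModelConfig(channel_schedule=(64, 128, 256, 512))


@pytest.mark.parametrize("variant", ["nau_net", "attention_unet", "unet_pp"])
def test_parameter_audit_layer_walk_vs_enumeration(variant):
    """Closed-form per-layer costs equal the framework's own enumeration."""
    model = build_model(ModelConfig(variant=variant, channel_schedule=TINY_SCHEDULE))
    assert layer_walk_params(model) == model.num_parameters()


def test_pinned_parameter_counts_against_published_sizes():
    """Full-width builds reproduce the published model sizes exactly."""
    expected = {"attention_unet": 34878573, "unet_pp": 36629633,
                "nau_net": 37251157}
    for variant, n in expected.items():
        model = build_model(ModelConfig(variant=variant, seed=0))
        assert model.num_parameters() == n
        assert layer_walk_params(model) == n


def test_gradient_reaches_every_gate_and_fusion_block(tiny_config, rng):
    """One optimization step changes the weights of every attention gate and
    every fusion block: no dead branches."""
    model = build_model(tiny_config)
    x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
    target = (rng.random((2, 1, 32, 32)) > 0.8).astype(np.float32)
    from naunet.losses import bce_dice_loss
    before = {name: p.data.copy() for name, p in model.named_parameters()}
    opt = Adam(model.parameters(), lr=1e-2)
    loss = bce_dice_loss(model(x), target)
    model.zero_grad()
    loss.backward()
    opt.step()
    for name, p in model.named_parameters():
        if "gate" in name or "fuse" in name:
            assert not np.array_equal(before[name], p.data), f"dead branch: {name}"


def test_checkpoint_round_trip(tmp_path, tiny_config, rng):
    model = build_model(tiny_config).eval()
    x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
    y = model(x).data
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    reloaded = load_checkpoint(path).eval()
    assert reloaded.config == tiny_config
    np.testing.assert_array_equal(reloaded(x).data, y)


def test_model_config_yaml_round_trip(tmp_path, tiny_config):
    path = tmp_path / "cfg.yaml"
    tiny_config.to_yaml(path)
    assert ModelConfig.from_yaml(path) == tiny_config
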