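"""Segmentation networks: NAU-Net and its two baselines.

NAU-Net is a five-level U-Net in which, at each of the four decoder levels,
the two *neighbouring* encoder feature maps are fused — the deeper map is
up-convolved and concatenated onto the shallower one — and the fused skip is
re-weighted by an attention gate driven by the decoder feature at that level,
before being concatenated into the decoder path.  The baselines are the
standard attention U-Net (same-level skips, 1x1 gate convolutions) and
U-Net++ (nested dense skip pathways).

All three variants are built from a declarative :class:`ModelConfig`; weight
initialization is He-normal seeded from the config so that a build is fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import nn
from .nn import autograd as ag

VARIANTS = ("nau_net", "attention_unet", "unet_pp")

#: gate intermediate width divisors that reproduce the published model sizes
_GATE_REDUCTION = {"nau_net": 8, "attention_unet": 2}


@dataclass
class ModelConfig:
    """Architecture hyperparameters that fully determine a network."""

    variant: str = "nau_net"
    in_channels: int = 3
    out_channels: int = 1
    channel_schedule: tuple = (64, 128, 256, 512, 1024)
    gate_kernel: int | None = None      # default: 3 for nau_net, 1 for attention_unet
    final_kernel: int | None = None     # default: 3 for nau_net, 1 for baselines
    gate_reduction: int | None = None   # F_int = channels // reduction
    block_order: str = "conv_bn_relu"   # or "conv_relu_bn"
    seed: int = 0

    def __post_init__(self):
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        self.validate()
        if self.gate_kernel is None:
            self.gate_kernel = 3 if self.variant == "nau_net" else 1
        if self.final_kernel is None:
            self.final_kernel = 3 if self.variant == "nau_net" else 1
        if self.gate_reduction is None:
            self.gate_reduction = _GATE_REDUCTION.get(self.variant, 2)

    def validate(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unsupported variant {self.variant!r}; choose from {VARIANTS}")
        if len(self.channel_schedule) != 5:
            raise ValueError("channel_schedule must have 5 entries")
        for a, b in zip(self.channel_schedule, self.channel_schedule[1:]):
            if b != 2 * a:
                raise ValueError("each channel_schedule entry must double its predecessor")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        for k in (self.gate_kernel, self.final_kernel):
            if k is not None and k % 2 == 0:
                raise ValueError("kernel sizes must be odd")
        if self.block_order not in ("conv_bn_relu", "conv_relu_bn"):
            raise ValueError("block_order must be conv_bn_relu or conv_relu_bn")

    @property
    def n_gates(self):
        return len(self.channel_schedule) - 1

    def to_dict(self):
        d = asdict(self)
        d["channel_schedule"] = list(self.channel_schedule)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


# -- building blocks -------------------------------------------------------

class ConvBlock(nn.Module):
    """Two (3x3 conv -> BN -> ReLU) stages; spatial dims preserved."""

    def __init__(self, in_channels, out_channels, rng=None, order="conv_bn_relu"):
        super().__init__()
        if out_channels < 1:
            raise ValueError(f"out_channels must be positive, got {out_channels}")
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.order = order

    def _stage(self, x, conv, bn):
        x = conv(x)
        if self.order == "conv_bn_relu":
            return ag.relu(bn(x))
        return bn(ag.relu(x))

    def forward(self, x):
        return self._stage(self._stage(x, self.conv1, self.bn1), self.conv2, self.bn2)


class UpConv(nn.Module):
    """x2 nearest upsample followed by 3x3 conv -> BN -> ReLU (doubles H, W)."""

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(ag.upsample_nearest2(x))))


class AttentionGate(nn.Module):
    """Additive attention gate.

    ``forward(signal, skip)`` computes q = ReLU(W_g(signal) + W_x(skip)),
    alpha = sigmoid(BN(psi(q))) in (0, 1), and returns alpha * skip.  Each of
    the three convolutions is followed by batch normalization.  The attention
    map of the last call is kept on ``last_alpha`` for inspection.
    """

    def __init__(self, signal_channels, skip_channels, inter_channels,
                 kernel=1, rng=None):
        super().__init__()
        pad = kernel // 2
        self.w_g = nn.Conv2d(signal_channels, inter_channels, kernel, padding=pad, rng=rng)
        self.bn_g = nn.BatchNorm2d(inter_channels)
        self.w_x = nn.Conv2d(skip_channels, inter_channels, kernel, padding=pad, rng=rng)
        self.bn_x = nn.BatchNorm2d(inter_channels)
        self.psi = nn.Conv2d(inter_channels, 1, kernel, padding=pad, rng=rng)
        self.bn_psi = nn.BatchNorm2d(1)
        self.last_alpha = None

    def forward(self, signal, skip):
        if signal.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"attention gate: spatial mismatch between signal {signal.shape} "
                f"and skip {skip.shape}")
        q = ag.relu(self.bn_g(self.w_g(signal)) + self.bn_x(self.w_x(skip)))
        alpha = ag.sigmoid(self.bn_psi(self.psi(q)))
        self.last_alpha = alpha
        return ag.mul(alpha, skip)


def attention_gate(e_fused, d, gate: AttentionGate):
    """Apply ``gate`` with the fused encoder map driving W_g and the decoder
    map both driving W_x and being re-weighted: returns alpha * d."""
    return gate(e_fused, d)


class NeighborFuse(nn.Module):
    """Fuse two neighbouring encoder maps into a 2*ch skip.

    The deeper map (2*ch channels, half resolution) is up-convolved to ch
    channels at the shallow resolution and concatenated in front of the
    shallow map: output = [transformed deep, shallow].
    """

    def __init__(self, channels, rng=None):
        super().__init__()
        self.up = UpConv(2 * channels, channels, rng=rng)
        self.channels = channels

    def forward(self, e_deep, e_shallow):
        b, c_deep, h, w = e_deep.shape
        bs, c_sh, hs, ws = e_shallow.shape
        if c_deep != 2 * c_sh or 2 * h != hs or 2 * w != ws:
            raise ValueError(
                f"neighbor_fuse: deep map {e_deep.shape} incompatible with "
                f"shallow map {e_shallow.shape}; expected 2x channels and half "
                f"spatial dims")
        return ag.concat([self.up(e_deep), e_shallow], axis=1)


# -- networks --------------------------------------------------------------

class SegmentationModel(nn.Module):
    """Common forward contract: sigmoid probability map, dims preserved."""

    config: ModelConfig

    def forward_logits(self, x):
        raise NotImplementedError

    def forward(self, x):
        x = ag.as_tensor(x)
        b, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(
                f"input spatial dims ({h}, {w}) must be divisible by 16; "
                f"resize the image (e.g. to 576x576) first")
        return ag.sigmoid(self.forward_logits(x))


class NAUNet(SegmentationModel):
    """Neighbored-attention U-Net.

    Encoder: five ConvBlocks with 2x2 max pooling.  At each decoder level
    (channel width c): the decoder feature d is the up-convolution of the
    level below; the fused skip e' = [up-conv of deeper encoder map, encoder
    map] carries 2c channels (at the deepest level the decoder's own up-conv
    output doubles as the transformed deep map, since both transforms act on
    the same bottleneck tensor); an attention gate driven by d re-weights e';
    and a single 3x3 merge convolution maps [d, gated e'] (3c channels) back
    to c.  A 3x3 convolution head produces the single-channel output.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channel_schedule
        order = config.block_order
        self.enc1 = ConvBlock(config.in_channels, ch[0], rng, order)
        self.enc2 = ConvBlock(ch[0], ch[1], rng, order)
        self.enc3 = ConvBlock(ch[1], ch[2], rng, order)
        self.enc4 = ConvBlock(ch[2], ch[3], rng, order)
        self.enc5 = ConvBlock(ch[3], ch[4], rng, order)
        k = config.gate_kernel
        red = config.gate_reduction
        for lvl, c in enumerate([ch[3], ch[2], ch[1], ch[0]]):  # deep -> shallow
            setattr(self, f"up{lvl}", UpConv(2 * c, c, rng))
            if lvl > 0:
                setattr(self, f"fuse{lvl}", NeighborFuse(c, rng))
            setattr(self, f"gate{lvl}",
                    AttentionGate(c, 2 * c, max(c // red, 1), k, rng))
            merge = nn.Sequential(nn.Conv2d(3 * c, c, 3, padding=1, rng=rng),
                                  nn.BatchNorm2d(c), nn.ReLU())
            setattr(self, f"merge{lvl}", merge)
        self.head = nn.Conv2d(ch[0], config.out_channels, config.final_kernel,
                              padding=config.final_kernel // 2, rng=rng)

    def forward_logits(self, x):
        x = ag.as_tensor(x)
        e1 = self.enc1(x)
        e2 = self.enc2(ag.max_pool2(e1))
        e3 = self.enc3(ag.max_pool2(e2))
        e4 = self.enc4(ag.max_pool2(e3))
        e5 = self.enc5(ag.max_pool2(e4))
        enc = [e4, e3, e2, e1]
        deeper = [e5, e4, e3, e2]
        d = None
        for lvl in range(4):
            up = getattr(self, f"up{lvl}")
            d = up(e5 if lvl == 0 else d)
            if lvl == 0:
                # both the decoder signal and the transformed deep encoder map
                # are up-conv(e5); reuse the same tensor for the fusion
                fused = ag.concat([d, enc[lvl]], axis=1)
            else:
                fused = getattr(self, f"fuse{lvl}")(deeper[lvl], enc[lvl])
            gated = getattr(self, f"gate{lvl}")(d, fused)
            d = getattr(self, f"merge{lvl}")(ag.concat([d, gated], axis=1))
        return self.head(d)


class AttentionUNet(SegmentationModel):
    """Reference attention U-Net: same-level skips gated with 1x1 convs."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channel_schedule
        order = config.block_order
        self.enc1 = ConvBlock(config.in_channels, ch[0], rng, order)
        self.enc2 = ConvBlock(ch[0], ch[1], rng, order)
        self.enc3 = ConvBlock(ch[1], ch[2], rng, order)
        self.enc4 = ConvBlock(ch[2], ch[3], rng, order)
        self.enc5 = ConvBlock(ch[3], ch[4], rng, order)
        k = config.gate_kernel
        red = config.gate_reduction
        for lvl, c in enumerate([ch[3], ch[2], ch[1], ch[0]]):
            setattr(self, f"up{lvl}", UpConv(2 * c, c, rng))
            setattr(self, f"gate{lvl}",
                    AttentionGate(c, c, max(c // red, 1), k, rng))
            setattr(self, f"dec{lvl}", ConvBlock(2 * c, c, rng, order))
        self.head = nn.Conv2d(ch[0], config.out_channels, config.final_kernel,
                              padding=config.final_kernel // 2, rng=rng)

    def forward_logits(self, x):
        x = ag.as_tensor(x)
        e1 = self.enc1(x)
        e2 = self.enc2(ag.max_pool2(e1))
        e3 = self.enc3(ag.max_pool2(e2))
        e4 = self.enc4(ag.max_pool2(e3))
        d = self.enc5(ag.max_pool2(e4))
        for lvl, skip in enumerate([e4, e3, e2, e1]):
            d = getattr(self, f"up{lvl}")(d)
            gated = getattr(self, f"gate{lvl}")(d, skip)
            d = getattr(self, f"dec{lvl}")(ag.concat([gated, d], axis=1))
        return self.head(d)


class UNetPlusPlus(SegmentationModel):
    """U-Net++ with nested dense skip pathways (no deep supervision).

    Node X(i, j) receives the channel-concatenation of all previous nodes at
    level i and the x2-upsampled node X(i+1, j-1); upsampling carries no
    parameters.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channel_schedule
        order = config.block_order
        ci = config.in_channels
        for i in range(5):
            setattr(self, f"conv{i}_0", ConvBlock(ci, ch[i], rng, order))
            ci = ch[i]
        for j in range(1, 5):
            for i in range(5 - j):
                setattr(self, f"conv{i}_{j}",
                        ConvBlock(j * ch[i] + ch[i + 1], ch[i], rng, order))
        self.head = nn.Conv2d(ch[0], config.out_channels, config.final_kernel,
                              padding=config.final_kernel // 2, rng=rng)

    def forward_logits(self, x):
        x = ag.as_tensor(x)
        nodes = {}
        inp = x
        for i in range(5):
            nodes[(i, 0)] = getattr(self, f"conv{i}_0")(
                inp if i == 0 else ag.max_pool2(nodes[(i - 1, 0)]))
        for j in range(1, 5):
            for i in range(5 - j):
                parts = [nodes[(i, jj)] for jj in range(j)]
                parts.append(ag.upsample_nearest2(nodes[(i + 1, j - 1)]))
                nodes[(i, j)] = getattr(self, f"conv{i}_{j}")(ag.concat(parts, axis=1))
        return self.head(nodes[(0, 4)])


_CLASSES = {"nau_net": NAUNet, "attention_unet": AttentionUNet,
            "unet_pp": UNetPlusPlus}


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct the network described by ``config``."""
    config.validate()
    return _CLASSES[config.variant](config)


# -- checkpoints -----------------------------------------------------------

CHECKPOINT_VERSION = "1"


def save_checkpoint(model: SegmentationModel, path):
    """Write weights + config + format version into a single .npz archive."""
    state = model.state_dict()
    meta = json.dumps({"config": model.config.to_dict(),
                       "version": CHECKPOINT_VERSION})
    np.savez(path, __meta__=np.array(meta), **state)


def load_checkpoint(path) -> SegmentationModel:
    """Rebuild the exact network stored by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = ModelConfig.from_dict(meta["config"])
    model = build_model(config)
    model.load_state_dict(state)
    return model
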