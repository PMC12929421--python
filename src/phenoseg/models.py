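"""Segmentation architectures: U-Net, SE-UNet, FCN and DeepLabv3+.

All four families share a small convolutional encoder and emit per-pixel
2-class logits at the input resolution. SE-UNet differs from U-Net only by
a squeeze-and-excitation gate appended at the end of each encoder stage
(after the second convolution, before pooling); the decoder carries no SE
blocks. A ResNet-101 backbone (randomly initialised; no pretrained weights
are shipped) can stand behind the FCN and DeepLabv3+ heads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

ARCHS = ("unet", "se_unet", "fcn", "deeplabv3plus")
BACKBONES = ("builtin_cnn", "resnet101")


class ConfigError(ValueError):
    """Invalid model configuration."""


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network stride."""


@dataclass
class SegModelConfig:
    """Fully determines a buildable network."""

    arch: str = "se_unet"
    encoder_stages: int = 4
    base_channels: int = 64
    se_reduction: int = 16
    num_classes: int = 2
    aspp_dilations: tuple[int, ...] = (6, 12, 18)
    backbone: str = "builtin_cnn"

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ConfigError(f"arch must be one of {ARCHS}, got {self.arch!r}")
        if self.backbone not in BACKBONES:
            raise ConfigError(
                f"backbone must be one of {BACKBONES}, got {self.backbone!r}")
        if self.backbone == "resnet101" and self.arch in ("unet", "se_unet"):
            raise ConfigError(
                "backbone 'resnet101' is only supported for fcn/deeplabv3plus; "
                "unet/se_unet use the builtin encoder")
        if self.encoder_stages < 1:
            raise ConfigError("encoder_stages must be >= 1")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.se_reduction < 1:
            raise ConfigError("se_reduction must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        self.aspp_dilations = tuple(int(d) for d in self.aspp_dilations)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspp_dilations"] = list(self.aspp_dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegModelConfig":
        d = dict(d)
        if "aspp_dilations" in d:
            d["aspp_dilations"] = tuple(d["aspp_dilations"])
        return cls(**d)


def se_block(x: np.ndarray, r: int,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised SE gate to ``x`` (C, H, W) or (N, C, H, W).

    Convenience functional form used for experimentation; networks embed
    :class:`phenoseg.nn.SEBlock` modules directly.
    """
    squeezed = x[None] if x.ndim == 3 else x
    blk = nn.SEBlock(squeezed.shape[1], r, rng=rng).eval()
    out = blk.forward(squeezed.astype(np.float32))
    return out[0] if x.ndim == 3 else out


def se_fc_parameter_count(channels: int, reduction: int) -> int:
    """Closed-form parameter count of one SE gate: 2*C*ceil(C/r) + C + ceil(C/r)."""
    hidden = max(1, math.ceil(channels / reduction))
    return 2 * channels * hidden + channels + hidden


class _DoubleConv(nn.Sequential):
    def __init__(self, in_ch: int, out_ch: int, rng) -> None:
        super().__init__(nn.ConvBNReLU(in_ch, out_ch, rng=rng),
                         nn.ConvBNReLU(out_ch, out_ch, rng=rng))


class _BuiltinEncoder(nn.Module):
    """Pyramid encoder: stage i outputs features at stride 2**i; a final
    double-conv bottleneck sits at stride 2**stages."""

    def __init__(self, stages: int, base: int, *, use_se: bool,
                 se_reduction: int, rng) -> None:
        super().__init__()
        self.stages = stages
        self.channels = [base * 2 ** i for i in range(stages)]
        self.bottom_channels = base * 2 ** stages
        blocks, ses, pools = [], [], []
        in_ch = 3
        for ch in self.channels:
            blocks.append(_DoubleConv(in_ch, ch, rng))
            ses.append(nn.SEBlock(ch, se_reduction, rng=rng) if use_se else None)
            pools.append(nn.MaxPool2d())
            in_ch = ch
        self.blocks = blocks
        self.se_blocks = [s for s in ses if s is not None]
        self._ses = ses
        self.pools = pools
        self.bottleneck = _DoubleConv(in_ch, self.bottom_channels, rng)

    @property
    def pyramid_strides(self) -> list[int]:
        return [2 ** i for i in range(self.stages)] + [2 ** self.stages]

    @property
    def pyramid_channels(self) -> list[int]:
        return self.channels + [self.bottom_channels]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        feats = []
        h = x
        for block, se, pool in zip(self.blocks, self._ses, self.pools):
            h = block.forward(h)
            if se is not None:
                h = se.forward(h)
            feats.append(h)
            h = pool.forward(h)
        feats.append(self.bottleneck.forward(h))
        return feats

    def backward(self, dfeats: list[np.ndarray]) -> np.ndarray:
        dh = self.bottleneck.backward(dfeats[-1])
        for i in range(self.stages - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dfeats[i]
            if self._ses[i] is not None:
                dh = self._ses[i].backward(dh)
            dh = self.blocks[i].backward(dh)
        return dh


class _Bottleneck(nn.Module):
    """ResNet bottleneck residual block (1x1 -> 3x3 -> 1x1, expansion 4)."""

    def __init__(self, in_ch: int, mid_ch: int, stride: int, rng) -> None:
        super().__init__()
        out_ch = mid_ch * 4
        self.conv1 = nn.ConvBNReLU(in_ch, mid_ch, 1, rng=rng)
        self.conv2 = nn.ConvBNReLU(mid_ch, mid_ch, 3, stride=stride, rng=rng)
        self.conv3 = nn.Sequential(
            nn.Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch))
        self.relu = nn.ReLU()
        self.shortcut = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch))

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.conv3.forward(self.conv2.forward(self.conv1.forward(x)))
        short = self.shortcut.forward(x) if self.shortcut is not None else x
        return self.relu.forward(main + short)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        dmain = self.conv1.backward(self.conv2.backward(self.conv3.backward(d)))
        dshort = self.shortcut.backward(d) if self.shortcut is not None else d
        return dmain + dshort


class _ResNetEncoder(nn.Module):
    """ResNet-101 layout ([3, 4, 23, 3] bottleneck blocks), random init.

    Pyramid strides 4/8/16/32. No pretrained weights are shipped.
    """

    LAYERS = (3, 4, 23, 3)

    def __init__(self, rng) -> None:
        super().__init__()
        self.stem = nn.Sequential(
            nn.ConvBNReLU(3, 64, 7, stride=2, padding=3, rng=rng),
            nn.MaxPool2d())
        self.layer_groups: list[list[_Bottleneck]] = []
        in_ch = 64
        for gi, (n_blocks, mid) in enumerate(zip(self.LAYERS, (64, 128, 256, 512))):
            group = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and gi > 0) else 1
                group.append(_Bottleneck(in_ch, mid, stride, rng))
                in_ch = mid * 4
            self.layer_groups.append(group)
        self.groups_flat = [b for g in self.layer_groups for b in g]

    @property
    def pyramid_strides(self) -> list[int]:
        return [4, 8, 16, 32]

    @property
    def pyramid_channels(self) -> list[int]:
        return [256, 512, 1024, 2048]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        h = self.stem.forward(x)
        feats = []
        for group in self.layer_groups:
            for block in group:
                h = block.forward(h)
            feats.append(h)
        return feats

    def backward(self, dfeats: list[np.ndarray]) -> np.ndarray:
        dh = np.zeros_like(dfeats[-1])
        for gi in range(3, -1, -1):
            dh = dh + dfeats[gi]
            for block in reversed(self.layer_groups[gi]):
                dh = block.backward(dh)
        return self.stem.backward(dh)


class _Ups(nn.Module):
    """Nearest-neighbour upsampling by a power-of-two factor."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        if factor < 1 or factor & (factor - 1):
            raise ConfigError(f"upsampling factor must be a power of 2, got {factor}")
        self.ups = [nn.UpsampleNearest2x() for _ in range(factor.bit_length() - 1)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for u in self.ups:
            x = u.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for u in reversed(self.ups):
            dy = u.backward(dy)
        return dy


class SegmentationModel(nn.Module):
    """Base class: config, stride contract and logits prediction."""

    def __init__(self, config: SegModelConfig) -> None:
        super().__init__()
        self.config = config

    @property
    def size_multiple(self) -> int:
        if self.config.backbone == "resnet101":
            return 32
        return 2 ** self.config.encoder_stages

    def check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (N, 3, H, W) input, got {x.shape}")
        m = self.size_multiple
        if x.shape[2] % m or x.shape[3] % m:
            raise ShapeError(
                f"input H and W must be multiples of {m} for arch="
                f"{self.config.arch}; got {x.shape[2]}x{x.shape[3]}")

    def predict_logits(self, batch: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass; validates input and output finiteness."""
        if not np.isfinite(batch).all():
            raise ValueError("non-finite values in input batch")
        self.check_input(batch)
        was_training = self.training
        self.eval()
        out = self.forward(batch.astype(np.float32))
        if was_training:
            self.train()
        return out


class UNet(SegmentationModel):
    """U-Net encoder-decoder; ``use_se=True`` builds SE-UNet (gates at the
    end of every encoder stage only)."""

    def __init__(self, config: SegModelConfig, rng) -> None:
        super().__init__(config)
        use_se = config.arch == "se_unet"
        self.encoder = _BuiltinEncoder(config.encoder_stages,
                                       config.base_channels,
                                       use_se=use_se,
                                       se_reduction=config.se_reduction,
                                       rng=rng)
        chans = self.encoder.channels
        self.up_convs, self.dec_blocks = [], []
        in_ch = self.encoder.bottom_channels
        for ch in reversed(chans):
            self.up_convs.append(nn.Sequential(
                nn.UpsampleNearest2x(), nn.ConvBNReLU(in_ch, ch, 1, rng=rng)))
            self.dec_blocks.append(_DoubleConv(2 * ch, ch, rng))
            in_ch = ch
        self.head = nn.Conv2d(chans[0], config.num_classes, 1, rng=rng)
        self._skip_ch = list(reversed(chans))

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = self.encoder.forward(x)
        skips, h = feats[:-1], feats[-1]
        for up, dec, skip in zip(self.up_convs, self.dec_blocks,
                                 reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=1)
            h = dec.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        dskips: list[np.ndarray] = []
        for up, dec, ch in zip(reversed(self.up_convs),
                               reversed(self.dec_blocks),
                               reversed(self._skip_ch)):
            dcat = dec.backward(dh)
            dup, dskip = dcat[:, :ch], dcat[:, ch:]
            dskips.append(dskip)
            dh = up.backward(np.ascontiguousarray(dup))
        # dskips collected decoder-deepest-last = encoder stage order 0..S-1
        dfeats = dskips + [dh]
        return self.encoder.backward(dfeats)

    @property
    def se_blocks(self) -> list[nn.SEBlock]:
        return self.encoder.se_blocks

    def set_identity_gates(self, value: bool) -> None:
        for blk in self.se_blocks:
            blk.identity_gate = value


class FCN(SegmentationModel):
    """FCN-8s-style head: scores from the three deepest pyramid levels are
    fused by stepwise 2x upsampling and addition, then upsampled to the
    input resolution."""

    def __init__(self, config: SegModelConfig, rng) -> None:
        super().__init__(config)
        if config.backbone == "resnet101":
            self.encoder = _ResNetEncoder(rng)
        else:
            self.encoder = _BuiltinEncoder(config.encoder_stages,
                                           config.base_channels,
                                           use_se=False,
                                           se_reduction=config.se_reduction,
                                           rng=rng)
        strides = self.encoder.pyramid_strides
        chans = self.encoder.pyramid_channels
        if len(strides) < 3:
            raise ConfigError("fcn needs an encoder with >= 3 pyramid levels")
        self.levels = [-3, -2, -1]
        k = config.num_classes
        self.scores = [nn.Conv2d(chans[i], k, 1, rng=rng) for i in self.levels]
        self.up2a = _Ups(2)
        self.up2b = _Ups(2)
        self.up_final = _Ups(strides[-3])

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = self.encoder.forward(x)
        self._shapes = [f.shape for f in feats]
        s3 = self.scores[2].forward(feats[-1])
        s2 = self.scores[1].forward(feats[-2])
        s1 = self.scores[0].forward(feats[-3])
        fused = self.up2b.forward(self.up2a.forward(s3) + s2) + s1
        return self.up_final.forward(fused)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfused = self.up_final.backward(dlogits)
        ds1 = dfused
        dmid = self.up2b.backward(dfused)
        ds2 = dmid
        ds3 = self.up2a.backward(dmid)
        dfeats: list = [None] * len(self._shapes)
        dfeats[-1] = self.scores[2].backward(ds3)
        dfeats[-2] = self.scores[1].backward(ds2)
        dfeats[-3] = self.scores[0].backward(ds1)
        filled = [d if d is not None else np.zeros(s, dtype=np.float32)
                  for d, s in zip(dfeats, self._shapes)]
        return self.encoder.backward(filled)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: 1x1, three dilated 3x3 branches and a
    global image-pooling branch, concatenated and projected."""

    def __init__(self, in_ch: int, out_ch: int, dilations, rng) -> None:
        super().__init__()
        self.branch1 = nn.ConvBNReLU(in_ch, out_ch, 1, rng=rng)
        self.dil_branches = [nn.ConvBNReLU(in_ch, out_ch, 3, dilation=d, rng=rng)
                             for d in dilations]
        self.pool_conv = nn.ConvBNReLU(in_ch, out_ch, 1, rng=rng)
        self.project = nn.ConvBNReLU((2 + len(self.dil_branches)) * out_ch,
                                     out_ch, 1, rng=rng)
        self.out_ch = out_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._hw = (h, w)
        branches = [self.branch1.forward(x)]
        branches += [b.forward(x) for b in self.dil_branches]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        gp = self.pool_conv.forward(pooled)
        branches.append(np.broadcast_to(gp, (n, self.out_ch, h, w)).copy())
        return self.project.forward(np.concatenate(branches, axis=1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        dcat = self.project.backward(dy)
        c = self.out_ch
        parts = [np.ascontiguousarray(dcat[:, i * c:(i + 1) * c])
                 for i in range(2 + len(self.dil_branches))]
        dx = self.branch1.backward(parts[0])
        for branch, part in zip(self.dil_branches, parts[1:-1]):
            dx = dx + branch.backward(part)
        dgp = parts[-1].sum(axis=(2, 3), keepdims=True)
        dpooled = self.pool_conv.backward(dgp)
        dx = dx + dpooled / (h * w)
        return dx


class DeepLabV3Plus(SegmentationModel):
    """Encoder + ASPP at the deepest level + decoder fusing a low-level
    feature map, emitting full-resolution logits."""

    def __init__(self, config: SegModelConfig, rng) -> None:
        super().__init__(config)
        if config.backbone == "resnet101":
            self.encoder = _ResNetEncoder(rng)
            low_idx = 1          # stride 8 level
            aspp_ch = 256
            low_proj_ch = 48
        else:
            self.encoder = _BuiltinEncoder(config.encoder_stages,
                                           config.base_channels,
                                           use_se=False,
                                           se_reduction=config.se_reduction,
                                           rng=rng)
            low_idx = max(0, config.encoder_stages - 2)  # stride/4 of deepest
            aspp_ch = 4 * config.base_channels
            low_proj_ch = config.base_channels
        strides = self.encoder.pyramid_strides
        chans = self.encoder.pyramid_channels
        self.low_idx = low_idx
        self.aspp = ASPP(chans[-1], aspp_ch, config.aspp_dilations, rng)
        self.up_mid = _Ups(strides[-1] // strides[low_idx])
        self.low_proj = nn.ConvBNReLU(chans[low_idx], low_proj_ch, 1, rng=rng)
        self.fuse = nn.Sequential(
            nn.ConvBNReLU(aspp_ch + low_proj_ch, aspp_ch, rng=rng),
            nn.ConvBNReLU(aspp_ch, aspp_ch, rng=rng))
        self.up_out = _Ups(strides[low_idx])
        self.head = nn.Conv2d(aspp_ch, config.num_classes, 1, rng=rng)
        self._aspp_ch = aspp_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = self.encoder.forward(x)
        self._shapes = [f.shape for f in feats]
        mid = self.up_mid.forward(self.aspp.forward(feats[-1]))
        low = self.low_proj.forward(feats[self.low_idx])
        h = self.fuse.forward(np.concatenate([mid, low], axis=1))
        return self.head.forward(self.up_out.forward(h))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.up_out.backward(self.head.backward(dlogits))
        dcat = self.fuse.backward(dh)
        c = self._aspp_ch
        dmid = np.ascontiguousarray(dcat[:, :c])
        dlow = np.ascontiguousarray(dcat[:, c:])
        dfeats: list = [None] * len(self._shapes)
        dfeats[self.low_idx] = self.low_proj.backward(dlow)
        dtop = self.aspp.backward(self.up_mid.backward(dmid))
        dfeats[-1] = dtop
        filled = [d if d is not None else np.zeros(s, dtype=np.float32)
                  for d, s in zip(dfeats, self._shapes)]
        return self.encoder.backward(filled)


def build_model(config: SegModelConfig,
                seed: int | np.random.Generator = 0) -> SegmentationModel:
    """Construct a randomly initialised network from its configuration."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if config.arch in ("unet", "se_unet"):
        return UNet(config, rng)
    if config.arch == "fcn":
        return FCN(config, rng)
    return DeepLabV3Plus(config, rng)


def predict_logits(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`SegmentationModel.predict_logits`."""
    return model.predict_logits(batch)
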