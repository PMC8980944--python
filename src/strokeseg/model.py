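"""The cross-attention deep-supervision U-Net.

Encoder: a ResNet-34-style stack of five blocks — a 7x7 stride-2 stem,
then four stages of (3, 4, 6, 3) basic residual units at strides
4/8/16/32 with ``base, 2*base, 4*base, 8*base`` channels (``base=64``
reproduces ResNet-34; smaller widths are used for CPU-scale runs).  The
first convolution takes a single channel (T1 slices are grayscale).

Decoder: four stages starting from the stride-32 feature.  Each stage
bilinearly upsamples the running decoder feature x2, aligns its channel
count to the matching encoder feature with a 1x1 convolution, fuses the
pair through cross-spatial attention followed by channel attention (or a
plain concatenation in the baseline ablation), and reduces with two
Conv-BN-ReLU layers.  Every stage feeds a side head (1x1 conv, sigmoid,
bilinear upsample to input resolution) for deep supervision; heads are
numbered step 1 (finest, the model's prediction) to step 4 (coarsest).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .attention import ChannelAttention, CrossSpatialAttention
from .autograd import Tensor, as_tensor, concat, sigmoid

__all__ = ["ModelConfig", "BasicBlock", "ResNetEncoder", "DecoderStage",
           "CrossAttentionUNet"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    base_channels: width of the first encoder stage (64 = ResNet-34).
    reduction: channel-attention bottleneck ratio (CBAM convention).
    use_csam / use_cam: ablation switches for the two attention modules;
        with both off the skip path is a plain concatenation (baseline).
    deep_supervision: whether auxiliary heads contribute to the loss
        (all four heads are always computed; this flag is read by the
        training loop).
    """

    in_channels: int = 1
    base_channels: int = 64
    reduction: int = 16
    use_csam: bool = True
    use_cam: bool = True
    deep_supervision: bool = True
    seed: int = 0

    @classmethod
    def ablation(cls, name: str, **kwargs) -> "ModelConfig":
        """Named ablation configurations: baseline / csam / csam_cam / full."""
        presets = {
            "baseline": dict(use_csam=False, use_cam=False, deep_supervision=False),
            "csam": dict(use_csam=True, use_cam=False, deep_supervision=False),
            "csam_cam": dict(use_csam=True, use_cam=True, deep_supervision=False),
            "full": dict(use_csam=True, use_cam=True, deep_supervision=True),
        }
        if name not in presets:
            raise ValueError(f"unknown ablation {name!r}; choose from {sorted(presets)}")
        return cls(**{**presets[name], **kwargs})

    def to_dict(self) -> dict:
        return asdict(self)


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(out + shortcut)


class ResNetEncoder(nn.Module):
    """Five-block encoder producing the stride-2..32 feature pyramid."""

    UNITS = (3, 4, 6, 3)

    def __init__(self, in_channels: int, base: int, rng):
        super().__init__()
        self.base = base
        self.stem_conv = nn.Conv2d(in_channels, base, 7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(base)
        self.pool = nn.MaxPool2d(3, 2, 1)
        widths = (base, 2 * base, 4 * base, 8 * base)
        self.stages = nn.ModuleList()
        in_ch = base
        for stage_idx, (n_units, width) in enumerate(zip(self.UNITS, widths)):
            blocks = []
            for unit in range(n_units):
                stride = 2 if (unit == 0 and stage_idx > 0) else 1
                blocks.append(BasicBlock(in_ch, width, stride, rng))
                in_ch = width
            self.stages.append(nn.Sequential(*blocks))

    @property
    def channels(self) -> tuple[int, ...]:
        b = self.base
        return (b, b, 2 * b, 4 * b, 8 * b)

    def forward(self, x: Tensor) -> list[Tensor]:
        _, _, H, W = x.shape
        if H % 32 or W % 32:
            raise ValueError(
                f"input spatial size must be divisible by 32, got {H}x{W}")
        f1 = nn.relu(self.stem_bn(self.stem_conv(x)))      # stride 2
        f2 = self.stages[0](self.pool(f1))                  # stride 4
        f3 = self.stages[1](f2)                             # stride 8
        f4 = self.stages[2](f3)                             # stride 16
        f5 = self.stages[3](f4)                             # stride 32
        return [f1, f2, f3, f4, f5]


class DecoderStage(nn.Module):
    """Upsample x2, align channels, fuse with the encoder feature, reduce."""

    def __init__(self, in_ch: int, enc_ch: int, out_ch: int, cfg: ModelConfig, rng):
        super().__init__()
        self.align = nn.Conv2d(in_ch, enc_ch, 1, rng=rng)
        self.csam = CrossSpatialAttention(rng) if cfg.use_csam else None
        self.cam = (ChannelAttention(2 * enc_ch, cfg.reduction, rng=rng)
                    if cfg.use_cam else None)
        self.reduce = nn.Sequential(
            nn.Conv2d(2 * enc_ch, out_ch, 3, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch), nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch), nn.ReLU(),
        )

    def forward(self, dec: Tensor, enc: Tensor) -> Tensor:
        up = nn.upsample_to(dec, enc.shape[2:])
        aligned = self.align(up)
        if self.csam is not None:
            fused = self.csam(enc, aligned)
        else:
            fused = concat([enc, aligned], axis=1)  # plain skip (baseline)
        if self.cam is not None:
            fused = self.cam(fused)
        return self.reduce(fused)


class SideHead(nn.Module):
    """1x1 conv to one channel, sigmoid, upsample to full resolution.

    The bias starts at -2 so the initial foreground probability (~0.12)
    reflects the class imbalance instead of a 50% coin flip.
    """

    def __init__(self, in_ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, 1, 1, rng=rng)
        self.conv.bias.data[:] = -2.0

    def forward(self, x: Tensor, out_hw: tuple[int, int]) -> Tensor:
        return nn.upsample_to(sigmoid(self.conv(x)), out_hw)


class CrossAttentionUNet(nn.Module):
    """Full network; ``forward`` returns the four supervision outputs
    ordered step 1 (finest — the prediction) to step 4 (coarsest)."""

    def __init__(self, config: ModelConfig | None = None, **kwargs):
        super().__init__()
        self.config = config or ModelConfig(**kwargs)
        rng = np.random.default_rng(self.config.seed)
        b = self.config.base_channels
        self.encoder = ResNetEncoder(self.config.in_channels, b, rng)
        enc_ch = self.encoder.channels            # (b, b, 2b, 4b, 8b)
        # stages run coarse -> fine, fusing f4, f3, f2, f1
        plan = [  # (incoming dec channels, encoder channels, output channels)
            (8 * b, 4 * b, 4 * b),
            (4 * b, 2 * b, 2 * b),
            (2 * b, b, b),
            (b, b, b),
        ]
        self.decoder = nn.ModuleList(
            DecoderStage(i, e, o, self.config, rng) for i, e, o in plan)
        self.heads = nn.ModuleList(SideHead(o, rng) for _, _, o in plan)

    def forward(self, x) -> list[Tensor]:
        x = as_tensor(x)
        unbatched = x.ndim == 3
        if unbatched:
            x = x.reshape(1, *x.shape)
        hw = x.shape[2:]
        f1, f2, f3, f4, f5 = self.encoder(x)
        dec = f5
        outputs_coarse_first = []
        for stage, head, enc in zip(self.decoder, self.heads, (f4, f3, f2, f1)):
            dec = stage(dec, enc)
            outputs_coarse_first.append(head(dec, hw))
        steps = outputs_coarse_first[::-1]  # step1 = finest
        if unbatched:
            steps = [s.reshape(*s.shape[1:]) for s in steps]
        return steps

    def predict(self, x) -> np.ndarray:
        """Step-1 probability map as a numpy array (inference head)."""
        return self.forward(x)[0].data
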