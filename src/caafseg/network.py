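"""Residual U-Net with adaptive attention fusion and ASPP bridge.

Architecture (default 64×64 single-channel patches):

* stem: conv–BN–ReLU to ``stage_channels[0]`` at full resolution; the
  stem output also feeds the Adaptive Attention Controller, whose single
  per-sample weight pair is broadcast to every fusion block;
* encoder: one residual stage per entry of ``stage_channels`` (the first
  at stride 1, the rest at stride 2), each followed by a dual-attention
  fusion block — default schedule 64×64×32 → 32×32×64 → 16×16×128 →
  8×8×256;
* bridge: ASPP at the deepest resolution (dilations 6/12/18, 1×1 branch,
  pooled global branch), output shape equal to its input;
* decoder: fuse the bridge output with the deepest encoder features, then
  three upsampling stages (bilinear 2× + conv) with skip concatenation
  and attention fusion at each level, back to 64×64×32;
* head: an optional lightweight full-resolution ASPP, a 1×1 convolution
  to one channel and a sigmoid, so outputs are probabilities in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .attention import AdaptiveAttentionController, DualAttentionBlock, fixed_fusion_weights
from .nn import Module, ModuleList, Tensor

__all__ = ["NetworkConfig", "SegmentationOutput", "ResidualBlock", "ASPP", "CAAFResUNet"]

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``stage_channels`` must be strictly increasing; the deepest spatial
    size is ``input_size / 2**(len(stage_channels) - 1)`` (64 → 8 with
    the default four stages).
    """

    input_size: int = 64
    in_channels: int = 1
    stage_channels: tuple = (32, 64, 128, 256)
    aspp_dilations: tuple = (6, 12, 18)
    aac_enabled: bool = True
    aac_fixed_weights: tuple = (0.5, 0.5)
    aac_downsample: int = 8
    attn_max_positions: int = 256
    final_aspp: bool = True
    normalize_inputs: bool = True

    def __post_init__(self):
        ch = tuple(self.stage_channels)
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError(f"stage_channels must be strictly increasing, got {ch}")
        self.stage_channels = ch
        self.aspp_dilations = tuple(self.aspp_dilations)
        self.aac_fixed_weights = tuple(self.aac_fixed_weights)
        if self.input_size % self.divisor != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {self.divisor} "
                f"(2 ** (number of stages - 1))")

    @property
    def divisor(self) -> int:
        return 2 ** (len(self.stage_channels) - 1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationOutput:
    """Probability mask plus the per-sample fusion weights that produced it."""

    prob_mask: Tensor        # B×1×H×W in [0, 1]
    fusion_weights: Tensor   # B×2 on the simplex


class ResidualBlock(Module):
    """Two conv–BN–ReLU layers with an identity / 1×1-projected shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return nn.relu(out + shortcut)


class ASPP(Module):
    """Atrous spatial pyramid pooling.

    Parallel 3×3 atrous convolutions at the configured dilations, a 1×1
    branch and a global-average-pooled branch, concatenated and fused by
    a 1×1 convolution back to ``out_ch``. Dilated branches use zero
    padding (a dilation can exceed the reflectable border); a dilation at
    or beyond the spatial size degenerates to mostly-padding context and
    is logged as a warning.
    """

    def __init__(self, in_ch: int, out_ch: int, dilations=(6, 12, 18),
                 branch_ch: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dilations = tuple(dilations)
        bc = branch_ch or out_ch
        self.branch1 = nn.Conv2d(in_ch, bc, 1, rng=rng)
        self.atrous = ModuleList(
            nn.Conv2d(in_ch, bc, 3, dilation=d, pad_mode="zero", rng=rng)
            for d in self.dilations
        )
        self.global_conv = nn.Conv2d(in_ch, bc, 1, rng=rng)
        n_branches = 2 + len(self.dilations)
        self.fuse = nn.Conv2d(n_branches * bc, out_ch, 1, rng=rng)
        self.fuse_bn = nn.BatchNorm2d(out_ch)
        self._warned = False

    def forward(self, x: Tensor, include_global: bool = True) -> Tensor:
        H, W = x.shape[-2], x.shape[-1]
        if not self._warned:
            for d in self.dilations:
                if d >= min(H, W):
                    logger.warning(
                        "ASPP dilation %d >= spatial size %dx%d; atrous branch is "
                        "dominated by padding", d, H, W)
                    object.__setattr__(self, "_warned", True)
        branches = [self.branch1(x)]
        branches += [conv(x) for conv in self.atrous]
        if include_global:
            pooled = nn.adaptive_avg_pool2d(x, (1, 1))
            g = self.global_conv(pooled)
            branches.append(g.expand((x.shape[0], g.shape[1], H, W)))
        else:
            branches.append(self.branch1(x) * 0.0)
        out = nn.concat(branches, axis=1)
        return nn.relu(self.fuse_bn(self.fuse(out)))


class _DecoderStage(Module):
    """Skip concatenation → 1×1 reduce → attention fusion → 2× upsample conv."""

    def __init__(self, ch: int, out_ch: int | None, attn_max_positions: int,
                 rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(2 * ch, ch, 1, rng=rng)
        self.reduce_bn = nn.BatchNorm2d(ch)
        self.attn = DualAttentionBlock(ch, max_positions=attn_max_positions, rng=rng)
        if out_ch is not None:
            self.up_conv = nn.Conv2d(ch, out_ch, 3, rng=rng)
            self.up_bn = nn.BatchNorm2d(out_ch)
        else:
            self.up_conv = None

    def forward(self, x: Tensor, skip: Tensor, weights: Tensor) -> Tensor:
        out = nn.concat([x, skip], axis=1)
        out = nn.relu(self.reduce_bn(self.reduce(out)))
        out = self.attn(out, weights)
        if self.up_conv is not None:
            out = nn.upsample_bilinear2d(out, (out.shape[-2] * 2, out.shape[-1] * 2))
            out = nn.relu(self.up_bn(self.up_conv(out)))
        return out


class CAAFResUNet(Module):
    """Encoder–bridge–decoder segmentation network with adaptive fusion.

    Construction is fully determined by ``(config, seed)``: the same pair
    yields bitwise-identical initial parameters.
    """

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        ch = cfg.stage_channels

        self.stem = nn.Conv2d(cfg.in_channels, ch[0], 3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(ch[0])
        self.aac = AdaptiveAttentionController(ch[0], cfg.aac_downsample, rng=rng)

        enc, enc_attn = [], []
        prev = ch[0]
        for i, c in enumerate(ch):
            enc.append(ResidualBlock(prev, c, stride=1 if i == 0 else 2, rng=rng))
            enc_attn.append(DualAttentionBlock(c, max_positions=cfg.attn_max_positions, rng=rng))
            prev = c
        self.encoder = ModuleList(enc)
        self.encoder_attn = ModuleList(enc_attn)

        self.bridge = ASPP(ch[-1], ch[-1], cfg.aspp_dilations, rng=rng)

        dec = []
        for i in range(len(ch) - 1, -1, -1):
            out_ch = ch[i - 1] if i > 0 else None
            dec.append(_DecoderStage(ch[i], out_ch, cfg.attn_max_positions, rng))
        self.decoder = ModuleList(dec)

        if cfg.final_aspp:
            # lightweight full-resolution refinement: narrow branches,
            # fused back to the stage width
            self.final_aspp = ASPP(ch[0], ch[0], cfg.aspp_dilations,
                                   branch_ch=max(ch[0] // 4, 4), rng=rng)
        else:
            self.final_aspp = None
        self.head = nn.Conv2d(ch[0], 1, 1, rng=rng)

        self.stage_shapes: dict = {}

    # -- helpers ---------------------------------------------------------------
    def _check_input(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected B×{self.config.in_channels}×H×W input, got {x.shape}")
        d = self.config.divisor
        if x.shape[-2] % d or x.shape[-1] % d:
            raise ValueError(
                f"input spatial size {x.shape[-2:]} must be divisible by {d} "
                f"(2 ** (number of stages - 1))")
        if self.config.normalize_inputs:
            lo = x.data.min(axis=(1, 2, 3), keepdims=True)
            hi = x.data.max(axis=(1, 2, 3), keepdims=True)
            x = (x - Tensor(lo)) * Tensor(1.0 / (hi - lo + 1e-8))
        return x

    def fusion_weights(self, stem_features: Tensor) -> Tensor:
        if self.config.aac_enabled:
            return self.aac(stem_features)
        return fixed_fusion_weights(stem_features.shape[0], self.config.aac_fixed_weights)

    # -- forward ---------------------------------------------------------------
    def forward(self, image) -> SegmentationOutput:
        x = self._check_input(image)
        shapes = {}

        f0 = nn.relu(self.stem_bn(self.stem(x)))
        weights = self.fusion_weights(f0)

        skips = []
        out = f0
        for i, (stage, attn) in enumerate(zip(self.encoder, self.encoder_attn)):
            out = attn(stage(out), weights)
            skips.append(out)
            shapes[f"encoder{i}"] = tuple(out.shape[1:])

        out = self.bridge(out)
        shapes["bridge"] = tuple(out.shape[1:])

        for j, stage in enumerate(self.decoder):
            out = stage(out, skips[len(skips) - 1 - j], weights)
            shapes[f"decoder{j}"] = tuple(out.shape[1:])

        if self.final_aspp is not None:
            out = self.final_aspp(out)
        prob = nn.sigmoid(self.head(out))
        shapes["output"] = tuple(prob.shape[1:])
        self.stage_shapes = shapes
        return SegmentationOutput(prob_mask=prob, fusion_weights=weights)

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())
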