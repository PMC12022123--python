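"""Segmentation network architectures.

Two variants are built here:

* a **basic segmentation network** — a residual encoder–decoder with six
  resolution stages, strided-convolution downsampling (x/y pooled five
  times, z pooled three times, matching 1.2 x 0.5 x 0.5 mm anisotropic
  voxels), transposed-convolution upsampling with skip concatenation, and
  four 1x1x1 deep-supervision heads emitting one channel per class
  (background / GTVp / GTVn);

* a **Dual Flow UNet (DFUNet)** — the same layout duplicated into a primary
  (mid-treatment image) encoder and a secondary (registered pre-treatment
  image + label prior) encoder.  At each encoder stage a CNN-based
  cross-attention block gates the secondary features with channel and
  spatial attention and adds them residually into the primary stream; a
  single decoder consumes the fused primary skips.

The residual branch of every cross-attention block is scaled by a learnable
scalar initialized to zero, so a freshly constructed DFUNet computes exactly
the same function as the basic network on the primary input.  That makes the
fusion wiring testable and stabilizes early training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

__all__ = [
    "NetworkSpec",
    "FusionSpec",
    "BasicSegNet",
    "DFUNet",
    "CrossAttention",
    "build_basic_segnet",
    "build_dfunet",
    "count_parameters",
    "default_pooling_pattern",
]


def default_pooling_pattern(n_stages: int = 6) -> list[tuple[int, int, int]]:
    """Per-transition (z, y, x) strides: x/y pooled at every transition,
    z only at the later ones so early stages keep anisotropic voxels."""
    n_pool = n_stages - 1
    n_z = max(0, n_pool - 2)
    pattern = []
    for i in range(n_pool):
        z = 2 if i >= n_pool - n_z else 1
        pattern.append((z, 2, 2))
    return pattern


@dataclass
class NetworkSpec:
    """Architectural description shared by both network variants."""

    n_stages: int = 6
    channels_per_stage: tuple[int, ...] = (32, 64, 128, 256, 320, 320)
    pooling_pattern: tuple[tuple[int, int, int], ...] | None = None
    n_classes: int = 3
    in_channels_primary: int = 1
    in_channels_secondary: int = 2
    deep_supervision_heads: int = 4
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.pooling_pattern is None:
            self.pooling_pattern = tuple(default_pooling_pattern(self.n_stages))
        self.pooling_pattern = tuple(tuple(s) for s in self.pooling_pattern)
        if len(self.channels_per_stage) != self.n_stages:
            raise ValueError("channels_per_stage length must equal n_stages")
        if len(self.pooling_pattern) != self.n_stages - 1:
            raise ValueError("pooling_pattern needs n_stages-1 entries")
        if self.deep_supervision_heads > self.n_stages - 1:
            raise ValueError("deep_supervision_heads must be <= n_stages-1")

    def cumulative_strides(self) -> list[tuple[int, int, int]]:
        """Cumulative (z, y, x) downsampling factor at each stage, stage 0
        first (factor 1)."""
        out = [(1, 1, 1)]
        for s in self.pooling_pattern:
            prev = out[-1]
            out.append(tuple(p * q for p, q in zip(prev, s)))
        return out

    def head_strides(self) -> list[tuple[int, int, int]]:
        """Cumulative strides of the deep-supervision heads, finest first."""
        return self.cumulative_strides()[: self.deep_supervision_heads]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if d.get("pooling_pattern") is not None:
            d["pooling_pattern"] = tuple(tuple(s) for s in d["pooling_pattern"])
        d["channels_per_stage"] = tuple(d["channels_per_stage"])
        return cls(**d)


@dataclass
class FusionSpec:
    """Where and how the secondary stream merges into the primary one."""

    fusion_stages: tuple[int, ...] | None = None  # None -> every stage
    reduction_ratio: int = 2

    def stages(self, n_stages: int) -> tuple[int, ...]:
        if self.fusion_stages is None:
            return tuple(range(n_stages))
        bad = [s for s in self.fusion_stages if not 0 <= s < n_stages]
        if bad:
            raise ValueError(f"fusion stages out of range: {bad}")
        return tuple(self.fusion_stages)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionSpec":
        d = dict(d)
        if d.get("fusion_stages") is not None:
            d["fusion_stages"] = tuple(d["fusion_stages"])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ResidualStage(Module):
    """Two conv + instance-norm + LeakyReLU layers with a residual shortcut.

    The shortcut is a 1x1x1 projection when the channel count changes.
    """

    def __init__(self, cin, cout, rng, slope=0.01):
        self.slope = slope
        self.conv1 = nn.Conv3d(cin, cout, 3, rng=rng)
        self.norm1 = nn.InstanceNorm3d(cout)
        self.conv2 = nn.Conv3d(cout, cout, 3, rng=rng)
        self.norm2 = nn.InstanceNorm3d(cout)
        self.proj = nn.Conv3d(cin, cout, 1, rng=rng, bias=False) if cin != cout else None

    def forward(self, x):
        y = nn.leaky_relu(self.norm1(self.conv1(x)), self.slope)
        y = self.norm2(self.conv2(y))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.leaky_relu(y + shortcut, self.slope)


class DownPool(Module):
    """Strided 3x3x3 convolution + instance norm + LeakyReLU."""

    def __init__(self, cin, cout, stride, rng, slope=0.01):
        self.slope = slope
        self.conv = nn.Conv3d(cin, cout, 3, stride=stride, rng=rng)
        self.norm = nn.InstanceNorm3d(cout)

    def forward(self, x):
        return nn.leaky_relu(self.norm(self.conv(x)), self.slope)


class CrossAttention(Module):
    """CNN-based cross attention fusing secondary features into the primary
    stream.

    Channel attention: global-average descriptor of the secondary features
    through a bottleneck MLP (1x1x1 convolutions) and a sigmoid.  Spatial
    attention: channel mean and max of the secondary features through a
    3x3x3 convolution and a sigmoid.  The doubly gated secondary features
    are added to the primary features, scaled by a learnable scalar that
    starts at zero, so fusion is an exact identity at initialization and
    the whole DFUNet begins as the basic network on the primary stream.

    ``gate_override`` replaces both attention maps with a constant, which
    pins the block's two limiting behaviours: 0 -> primary unchanged,
    1 (with ``scale``=1) -> primary + secondary.
    """

    def __init__(self, channels, reduction_ratio, rng, slope=0.01):
        hidden = max(1, channels // reduction_ratio)
        self.slope = slope
        self.ch_fc1 = nn.Conv3d(channels, hidden, 1, rng=rng)
        self.ch_fc2 = nn.Conv3d(hidden, channels, 1, rng=rng)
        self.sp_conv = nn.Conv3d(2, 1, 3, rng=rng)
        self.scale = Parameter(np.zeros(1, dtype=np.float32))
        self.gate_override: float | None = None

    def forward(self, f_mid: Tensor, f_pre: Tensor) -> Tensor:
        if f_mid.shape != f_pre.shape:
            raise ValueError(
                f"cross-attention shape mismatch: {f_mid.shape} vs {f_pre.shape}")
        if self.gate_override is not None:
            g = float(self.gate_override)
            gated = f_pre * g * g
        else:
            ca = self.channel_gate(f_pre)
            sa = self.spatial_gate(f_pre)
            gated = f_pre * ca * sa
        return f_mid + self.scale * gated

    def channel_gate(self, f_pre: Tensor) -> Tensor:
        desc = f_pre.mean(axis=(2, 3, 4), keepdims=True)
        h = nn.leaky_relu(self.ch_fc1(desc), self.slope)
        return nn.sigmoid(self.ch_fc2(h))

    def spatial_gate(self, f_pre: Tensor) -> Tensor:
        pooled = nn.concat(
            [f_pre.mean(axis=1, keepdims=True), f_pre.max(axis=1, keepdims=True)],
            axis=1)
        return nn.sigmoid(self.sp_conv(pooled))


class _Encoder(Module):
    def __init__(self, in_channels, spec: NetworkSpec, rng):
        ch = spec.channels_per_stage
        self.stages = [
            ResidualStage(in_channels if s == 0 else ch[s], ch[s], rng,
                          spec.negative_slope)
            for s in range(spec.n_stages)
        ]
        self.downs = [
            DownPool(ch[s], ch[s + 1], spec.pooling_pattern[s], rng,
                     spec.negative_slope)
            for s in range(spec.n_stages - 1)
        ]


class _Decoder(Module):
    def __init__(self, spec: NetworkSpec, rng):
        ch = spec.channels_per_stage
        n = spec.n_stages
        self.ups = [
            nn.ConvTranspose3d(ch[s + 1], ch[s], spec.pooling_pattern[s], rng=rng)
            for s in range(n - 1)
        ]
        self.stages = [
            ResidualStage(2 * ch[s], ch[s], rng, spec.negative_slope)
            for s in range(n - 1)
        ]
        self.heads = [
            nn.Conv3d(ch[s], spec.n_classes, 1, rng=rng)
            for s in range(spec.deep_supervision_heads)
        ]

    def forward(self, skips: list[Tensor]) -> list[Tensor]:
        n = len(skips)
        g = skips[-1]
        decoded: dict[int, Tensor] = {}
        for s in range(n - 2, -1, -1):
            g = self.ups[s](g)
            g = nn.concat([g, skips[s]], axis=1)
            g = self.stages[s](g)
            decoded[s] = g
        return [self.heads[s](decoded[s]) for s in range(len(self.heads))]


class BasicSegNet(Module):
    """Residual encoder–decoder with deep supervision.

    ``forward`` returns a list of logit tensors, finest resolution first,
    each with ``n_classes`` channels.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 in_channels: int | None = None):
        rng = np.random.default_rng(seed)
        self.spec = spec
        cin = spec.in_channels_primary if in_channels is None else in_channels
        self.in_channels = cin
        self.encoder = _Encoder(cin, spec, rng)
        self.decoder = _Decoder(spec, rng)

    def encode(self, x: Tensor) -> list[Tensor]:
        feats = []
        f = x
        for s, stage in enumerate(self.encoder.stages):
            f = stage(f)
            feats.append(f)
            if s < len(self.encoder.downs):
                f = self.encoder.downs[s](f)
        return feats

    def forward(self, x) -> list[Tensor]:
        x = nn.tensor(x)
        self._check_divisible(x)
        return self.decoder(self.encode(x))

    def _check_divisible(self, x: Tensor):
        total = self.spec.cumulative_strides()[-1]
        for ax, (size, s) in enumerate(zip(x.shape[2:], total)):
            if size % s:
                raise ValueError(
                    f"patch axis {ax} size {size} not divisible by cumulative "
                    f"stride {s}")


class DFUNet(Module):
    """Dual Flow UNet: two encoders, cross-attention fusion, one decoder.

    ``forward(x_primary, x_secondary)`` — the primary input is the image to
    segment (mid-treatment scan), the secondary input stacks the registered
    prior image and its label channel(s).
    """

    def __init__(self, spec: NetworkSpec, fusion: FusionSpec | None = None,
                 seed: int = 0):
        if spec.in_channels_secondary < 1:
            raise ValueError("DFUNet needs at least one secondary channel")
        fusion = fusion or FusionSpec()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.fusion_spec = fusion
        self.fusion_stages = fusion.stages(spec.n_stages)
        self.in_channels = spec.in_channels_primary
        # primary path mirrors BasicSegNet attribute-for-attribute so its
        # state dict is interchangeable with a basic network's
        self.encoder = _Encoder(spec.in_channels_primary, spec, rng)
        self.decoder = _Decoder(spec, rng)
        rng2 = np.random.default_rng(seed + 1)
        self.encoder2 = _Encoder(spec.in_channels_secondary, spec, rng2)
        self.attn = [
            CrossAttention(spec.channels_per_stage[s], fusion.reduction_ratio,
                           rng2, spec.negative_slope)
            if s in self.fusion_stages else None
            for s in range(spec.n_stages)
        ]

    def forward(self, x_primary, x_secondary) -> list[Tensor]:
        xp = nn.tensor(x_primary)
        xs = nn.tensor(x_secondary)
        if xp.shape[2:] != xs.shape[2:]:
            raise ValueError("primary/secondary spatial shapes differ")
        if xs.shape[1] != self.spec.in_channels_secondary:
            raise ValueError(
                f"secondary input has {xs.shape[1]} channels, spec expects "
                f"{self.spec.in_channels_secondary}")
        BasicSegNet._check_divisible(self, xp)
        skips = []
        f, g = xp, xs
        for s in range(self.spec.n_stages):
            f = self.encoder.stages[s](f)
            g = self.encoder2.stages[s](g)
            if self.attn[s] is not None:
                f = self.attn[s](f, g)
            skips.append(f)
            if s < len(self.encoder.downs):
                f = self.encoder.downs[s](f)
                g = self.encoder2.downs[s](g)
        return self.decoder(skips)

    def load_primary_from(self, basic_state: dict[str, np.ndarray]):
        """Copy a basic network's weights into the primary encoder/decoder."""
        return self.load_state_dict(basic_state, strict=False)

    def set_gate_override(self, value: float | None):
        for a in self.attn:
            if a is not None:
                a.gate_override = value

    def set_fusion_scale(self, value: float):
        for a in self.attn:
            if a is not None:
                a.scale.data[:] = value


def build_basic_segnet(spec: NetworkSpec, seed: int = 0,
                       in_channels: int | None = None) -> BasicSegNet:
    return BasicSegNet(spec, seed=seed, in_channels=in_channels)


def build_dfunet(spec: NetworkSpec, fusion: FusionSpec | None = None,
                 seed: int = 0) -> DFUNet:
    return DFUNet(spec, fusion, seed=seed)


def count_parameters(network: Module) -> int:
    return network.count_parameters()
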