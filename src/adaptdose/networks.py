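"""Dose-prediction architectures: baseline 3D U-Net and the dual-head MHU-Net.

Both networks share the same building blocks:

* **encoder block** — two (3x3x3 conv -> group norm -> ReLU -> block dropout)
  stages at the level width;
* **dual-pool downsampling** — concatenation of 2x2x2 max pooling and 2x2x2
  average pooling, halving the spatial dimensions and doubling the channels;
* **triple-branch upsampling** — concatenation of nearest-neighbour
  interpolation, trilinear interpolation and a stride-2 transposed
  convolution;
* a 1x1x1 output convolution producing the single-channel dose map (followed
  by ReLU by default, since dose is non-negative).

MHU-Net adds a secondary encoder that ingests the pre-treatment plan
(91 channels including the approved dose).  Each head applies its own dual
pooling; the pooled secondary features are concatenated onto the pooled
primary features before the primary head's next block, whose convolutions
project back to the nominal level width.  After the third downsampling the
concatenated streams feed a single shared bottleneck, and one decoder with
skip connections from the primary encoder reconstructs the dose.

Block dropout grows with depth: ``rate(f) = max_rate * (f / max_filters) **
power`` where ``f`` is the block's filter count and ``max_filters`` the
bottleneck width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import ShapeProxy, Tensor, concat, relu
from .nn.layers import effective_groups


@dataclass(frozen=True)
class DropoutSpec:
    max_rate: float = 0.05
    power: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_rate < 1.0:
            raise ValueError("max_rate must be in [0, 1)")
        if self.power <= 0:
            raise ValueError("power must be positive")


def dropout_rate(num_filters: int, spec: DropoutSpec, max_filters: int) -> float:
    """Depth-scaled block dropout: max_rate * (num_filters / max_filters)^power."""
    if num_filters <= 0:
        raise ValueError("num_filters must be positive")
    if max_filters <= 0:
        raise ValueError("max_filters must be positive")
    return spec.max_rate * (num_filters / max_filters) ** spec.power


@dataclass(frozen=True)
class NetworkConfig:
    in_channels_primary: int = 90
    in_channels_secondary: int = 91
    base_width: int = 64
    n_levels: int = 4
    norm_groups: int = 32
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    final_relu: bool = True
    normalize_decoder: bool = True
    bypass_stream: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least two resolution levels")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")

    @property
    def level_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2**lvl for lvl in range(self.n_levels))

    @property
    def max_filters(self) -> int:
        return self.level_widths[-1]


class ConvBlock(nn.Module):
    """Two conv->groupnorm->ReLU->dropout stages at a fixed width."""

    def __init__(self, cin: int, width: int, cfg: NetworkConfig,
                 rng: np.random.Generator, drop_rng: np.random.Generator,
                 stem: bool = False, normalize: bool = True):
        super().__init__()
        rate = dropout_rate(width, cfg.dropout, cfg.max_filters)
        self.conv1 = nn.Conv3d(cin, width, rng, stem=stem)
        self.conv2 = nn.Conv3d(width, width, rng)
        self.norm1 = nn.GroupNorm(width, cfg.norm_groups) if normalize else None
        self.norm2 = nn.GroupNorm(width, cfg.norm_groups) if normalize else None
        self.drop1 = nn.Dropout(rate, drop_rng)
        self.drop2 = nn.Dropout(rate, drop_rng)

    def __call__(self, x):
        x = self.conv1(x)
        if self.norm1 is not None:
            x = self.norm1(x)
        x = self.drop1(relu(x))
        x = self.conv2(x)
        if self.norm2 is not None:
            x = self.norm2(x)
        return self.drop2(relu(x))


class DualPool(nn.Module):
    """Concatenated max/average 2x2x2 pooling: halves space, doubles channels."""

    def __init__(self):
        super().__init__()
        self.maxpool = nn.MaxPool2x()
        self.avgpool = nn.AvgPool2x()

    def __call__(self, x):
        return concat([self.maxpool(x), self.avgpool(x)], axis=0)


class UpStage(nn.Module):
    """Triple-branch upsampling: nearest + trilinear + transposed convolution."""

    def __init__(self, cin: int, rng: np.random.Generator):
        super().__init__()
        self.nearest = nn.UpsampleNearest2x()
        self.trilinear = nn.UpsampleTrilinear2x()
        self.tconv = nn.ConvTranspose3d2x(cin, cin, rng)

    def __call__(self, x):
        return concat([self.nearest(x), self.trilinear(x), self.tconv(x)], axis=0)


class DosePredictor(nn.Module):
    """Shared decoder scaffolding and audit utilities."""

    kind: str = "base"

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        self._rng = np.random.default_rng(config.seed)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]).generate_state(1)[0]
        )

    def _build_decoder(self) -> None:
        cfg = self.config
        w = cfg.level_widths
        self.up_stages = [UpStage(w[lvl + 1], self._rng) for lvl in range(cfg.n_levels - 1)]
        self.dec_blocks = [
            ConvBlock(3 * w[lvl + 1] + w[lvl], w[lvl], cfg, self._rng, self._drop_rng,
                      normalize=cfg.normalize_decoder)
            for lvl in range(cfg.n_levels - 1)
        ]
        head_in = w[0] + (w[-1] if cfg.bypass_stream else 0)
        self.head = nn.Conv3d(head_in, 1, self._rng, kernel=1)

    def _decode(self, x, skips, trace):
        cfg = self.config
        bypass = x
        for lvl in range(cfg.n_levels - 2, -1, -1):
            x = self.up_stages[lvl](x)
            _record(trace, f"decoder.up{lvl}", x)
            x = concat([x, skips[lvl]], axis=0)
            x = self.dec_blocks[lvl](x)
            _record(trace, f"decoder.block{lvl}", x)
            if cfg.bypass_stream:
                bypass = nn.tensor.upsample_nearest2(bypass)
        if cfg.bypass_stream:
            x = concat([x, bypass], axis=0)
        y = self.head(x)
        if cfg.final_relu:
            y = relu(y)
        _record(trace, "output", y)
        return y

    def _check_spatial(self, shape) -> None:
        down = 2 ** (self.config.n_levels - 1)
        if any(s % down for s in shape[1:]):
            raise ValueError(
                f"spatial dims {tuple(shape[1:])} must be divisible by {down} "
                f"for {self.config.n_levels} resolution levels"
            )

    def summarize(self, spatial_shape: tuple[int, int, int]) -> dict[str, tuple[int, ...]]:
        """Audit table: named feature-map shapes (with a leading batch of 1).

        Walks the real layer graph with shape proxies, so the table reflects
        the instantiated network, not separate arithmetic.
        """
        trace: dict[str, tuple[int, ...]] = {}
        self.forward_shapes(spatial_shape, trace)
        return {name: (1,) + shape for name, shape in trace.items()}


def _record(trace, name, x) -> None:
    if trace is not None:
        trace[name] = tuple(x.shape)


class UNet3D(DosePredictor):
    """Baseline single-head network: adaptive-session channels only."""

    kind = "unet"

    def __init__(self, config: NetworkConfig):
        super().__init__(config)
        cfg = config
        w = cfg.level_widths
        enc_in = [cfg.in_channels_primary] + [2 * w[lvl - 1] for lvl in range(1, cfg.n_levels - 1)]
        self.enc_blocks = [
            ConvBlock(enc_in[lvl], w[lvl], cfg, self._rng, self._drop_rng, stem=(lvl == 0))
            for lvl in range(cfg.n_levels - 1)
        ]
        self.pool = DualPool()
        self.bottleneck = ConvBlock(2 * w[-2], w[-1], cfg, self._rng, self._drop_rng)
        self._build_decoder()

    def __call__(self, primary, trace: dict | None = None):
        self._check_spatial(primary.shape)
        skips = []
        x = primary
        for lvl, block in enumerate(self.enc_blocks):
            x = block(x)
            _record(trace, f"primary.enc{lvl}", x)
            skips.append(x)
            x = self.pool(x)
            _record(trace, f"primary.down{lvl}", x)
        x = self.bottleneck(x)
        _record(trace, "bottleneck", x)
        return self._decode(x, skips, trace)

    def forward_shapes(self, spatial_shape, trace):
        self(ShapeProxy((self.config.in_channels_primary,) + tuple(spatial_shape)), trace)


class MHUNet(DosePredictor):
    """Dual-head network: adaptive session plus pre-treatment plan conditioning."""

    kind = "mhunet"

    def __init__(self, config: NetworkConfig):
        super().__init__(config)
        cfg = config
        w = cfg.level_widths
        p_in = [cfg.in_channels_primary] + [4 * w[lvl - 1] for lvl in range(1, cfg.n_levels - 1)]
        s_in = [cfg.in_channels_secondary] + [2 * w[lvl - 1] for lvl in range(1, cfg.n_levels - 1)]
        self.enc_blocks = [
            ConvBlock(p_in[lvl], w[lvl], cfg, self._rng, self._drop_rng, stem=(lvl == 0))
            for lvl in range(cfg.n_levels - 1)
        ]
        self.sec_blocks = [
            ConvBlock(s_in[lvl], w[lvl], cfg, self._rng, self._drop_rng, stem=(lvl == 0))
            for lvl in range(cfg.n_levels - 1)
        ]
        self.pool = DualPool()
        self.bottleneck = ConvBlock(4 * w[-2], w[-1], cfg, self._rng, self._drop_rng)
        self._build_decoder()

    def __call__(self, primary, secondary, trace: dict | None = None):
        if secondary is None:
            raise ValueError("MHU-Net requires the secondary (pre-treatment) input")
        self._check_spatial(primary.shape)
        if tuple(primary.shape[1:]) != tuple(secondary.shape[1:]):
            raise ValueError("primary and secondary inputs must share spatial shape")
        skips = []
        p, s = primary, secondary
        for lvl in range(self.config.n_levels - 1):
            p = self.enc_blocks[lvl](p)
            _record(trace, f"primary.enc{lvl}", p)
            skips.append(p)
            pd = self.pool(p)
            _record(trace, f"primary.down{lvl}", pd)
            s = self.sec_blocks[lvl](s)
            _record(trace, f"secondary.enc{lvl}", s)
            sd = self.pool(s)
            _record(trace, f"secondary.down{lvl}", sd)
            p = concat([pd, sd], axis=0)  # cross-head fusion
            s = sd
        x = self.bottleneck(p)
        _record(trace, "bottleneck", x)
        return self._decode(x, skips, trace)

    def forward_shapes(self, spatial_shape, trace):
        sp = tuple(spatial_shape)
        self(
            ShapeProxy((self.config.in_channels_primary,) + sp),
            ShapeProxy((self.config.in_channels_secondary,) + sp),
            trace,
        )


def build_unet(config: NetworkConfig = NetworkConfig()) -> UNet3D:
    return UNet3D(config)


def build_mhunet(config: NetworkConfig = NetworkConfig()) -> MHUNet:
    return MHUNet(config)


def forward_volume(model: DosePredictor, primary: np.ndarray,
                   secondary: np.ndarray | None = None) -> np.ndarray:
    """Single inference-mode forward pass on (C, X, Y, Z) arrays -> (X, Y, Z)."""
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            if model.kind == "mhunet":
                y = model(Tensor(primary), Tensor(secondary))
            else:
                y = model(Tensor(primary))
    finally:
        if was_training:
            model.train()
    return y.data[0]


__all__ = [
    "ConvBlock",
    "DosePredictor",
    "DropoutSpec",
    "DualPool",
    "MHUNet",
    "NetworkConfig",
    "UNet3D",
    "UpStage",
    "build_mhunet",
    "build_unet",
    "dropout_rate",
    "effective_groups",
    "forward_volume",
]
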