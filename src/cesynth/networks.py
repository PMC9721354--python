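"""The four sub-networks: generator, global/local discriminators, segmentor.

Generator: U-Net with residual modules before each sampling step, 2x2
stride-2 sampling convolutions (batch norm + leaky ReLU down / ReLU up),
skip concatenations, self-attention where the decoder feature maps have side
``image_size // 4``, spectral normalization on every sampling convolution,
and a tanh head bounding the output to [-1, 1].

Discriminators: conditional patch critics over 4 channels
[conditioning image, conditioning edge, candidate image, candidate edge].
The global critic applies four 2x2 stride-2 feature layers (penultimate map:
side/16, receptive field 16) and a stride-2 score convolution (score grid
side/32, receptive field 32); the local critic is the three-layer analogue
on tumor-centered patches.  The feature map before the score convolution is
exposed for feature matching.

Segmentor: plain U-Net (no spectral norm anywhere), five down/up sampling
levels by default, sigmoid head producing a tumor probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, ConvTranspose2d, Identity, LeakyReLU, Module, ReLU,
    ResidualBlock, SelfAttention, Sequential, Tensor, cat,
)

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "SegmentorConfig", "NetworkBundle",
    "Generator", "Discriminator", "Segmentor",
    "build_generator", "build_discriminator", "build_segmentor",
]

LEAK = 0.2


def _widths(base: int, depth: int) -> list[int]:
    return [base * min(2 ** i, 8) for i in range(depth + 1)]


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 64
    depth: int = 4
    image_size: int = 256
    use_spectral_norm: bool = True
    use_residual: bool = True
    use_attention: bool = True

    def validate(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.image_size % (2 ** self.depth):
            raise ValueError("image_size must be divisible by 2**depth")
        return self


@dataclass(frozen=True)
class DiscriminatorConfig:
    n_layers: int = 4
    in_channels: int = 4
    base_width: int = 64
    input_size: int = 256
    use_spectral_norm: bool = True

    def validate(self):
        if self.input_size % (2 ** (self.n_layers + 1)):
            raise ValueError("input_size must be divisible by 2**(n_layers+1)")
        return self


@dataclass(frozen=True)
class SegmentorConfig:
    depth: int = 5
    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 64
    image_size: int = 256

    def validate(self):
        if self.image_size % (2 ** self.depth):
            raise ValueError("image_size must be divisible by 2**depth")
        return self


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c = _widths(cfg.base_width, cfg.depth)
        sn = cfg.use_spectral_norm
        self.stem = Conv2d(cfg.in_channels, c[0], 3, pad=1, rng=rng)

        self.enc_res, self.enc_down = [], []
        for i in range(cfg.depth):
            self.enc_res.append(
                ResidualBlock(c[i], c[i], rng) if cfg.use_residual else Identity())
            self.enc_down.append(Sequential(
                Conv2d(c[i], c[i + 1], 2, stride=2, bias=False, spectral_norm=sn, rng=rng),
                BatchNorm2d(c[i + 1]), LeakyReLU(LEAK)))

        self.dec_up, self.dec_fuse = [], []
        for i in range(cfg.depth):
            cin, cout = c[cfg.depth - i], c[cfg.depth - 1 - i]
            self.dec_up.append(Sequential(
                ConvTranspose2d(cin, cout, 2, stride=2, bias=False, spectral_norm=sn, rng=rng),
                BatchNorm2d(cout), ReLU()))
            if cfg.use_residual:
                self.dec_fuse.append(ResidualBlock(2 * cout, cout, rng))
            else:
                self.dec_fuse.append(Sequential(
                    Conv2d(2 * cout, cout, 3, pad=1, bias=False, rng=rng),
                    BatchNorm2d(cout), LeakyReLU(LEAK)))

        # decoder stage i outputs side image/2**(depth-1-i); attention sits
        # where that side equals image_size // 4
        self.attention_stage = cfg.depth - 3 if cfg.depth >= 3 else None
        self.attention = (SelfAttention(c[cfg.depth - 1 - self.attention_stage], rng)
                          if (cfg.use_attention and self.attention_stage is not None)
                          else None)
        self.head = Conv2d(c[0], cfg.out_channels, 3, pad=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = self.cfg.image_size
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels or x.shape[2:] != (s, s):
            raise ValueError(f"generator expects (N,{self.cfg.in_channels},{s},{s}), got {x.shape}")
        h = self.stem(x)
        skips = []
        for res, down in zip(self.enc_res, self.enc_down):
            h = res(h)
            skips.append(h)
            h = down(h)
        for i, (up, fuse) in enumerate(zip(self.dec_up, self.dec_fuse)):
            h = up(h)
            h = fuse(cat([h, skips[-1 - i]], axis=1))
            if self.attention is not None and i == self.attention_stage:
                h = self.attention(h)
        return self.head(h).tanh()


class Discriminator(Module):
    """Conditional critic returning (score grid, penultimate features)."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        sn = cfg.use_spectral_norm
        w = _widths(cfg.base_width, cfg.n_layers)
        layers = []
        cin = cfg.in_channels
        for i in range(cfg.n_layers):
            block = [Conv2d(cin, w[i], 2, stride=2, bias=(i == 0),
                            spectral_norm=sn, rng=rng)]
            if i > 0:
                block.append(BatchNorm2d(w[i]))
            block.append(LeakyReLU(LEAK))
            layers.append(Sequential(*block))
            cin = w[i]
        self.features = layers
        self.score = Conv2d(cin, 1, 2, stride=2, spectral_norm=sn, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        s = self.cfg.input_size
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels or x.shape[2:] != (s, s):
            raise ValueError(
                f"discriminator expects (N,{self.cfg.in_channels},{s},{s}), got {x.shape}")
        h = x
        for layer in self.features:
            h = layer(h)
        return self.score(h), h


class Segmentor(Module):
    def __init__(self, cfg: SegmentorConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c = _widths(cfg.base_width, cfg.depth)
        self.stem = Sequential(Conv2d(cfg.in_channels, c[0], 3, pad=1, rng=rng),
                               LeakyReLU(LEAK))
        self.downs = [Sequential(Conv2d(c[i], c[i + 1], 2, stride=2, bias=False, rng=rng),
                                 BatchNorm2d(c[i + 1]), LeakyReLU(LEAK))
                      for i in range(cfg.depth)]
        self.ups, self.fuses = [], []
        for i in range(cfg.depth):
            cin, cout = c[cfg.depth - i], c[cfg.depth - 1 - i]
            self.ups.append(Sequential(ConvTranspose2d(cin, cout, 2, stride=2, bias=False, rng=rng),
                                       BatchNorm2d(cout), LeakyReLU(LEAK)))
            self.fuses.append(Sequential(Conv2d(2 * cout, cout, 3, pad=1, bias=False, rng=rng),
                                         BatchNorm2d(cout), LeakyReLU(LEAK)))
        self.head = Conv2d(c[0], cfg.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        skips = []
        for down in self.downs:
            skips.append(h)
            h = down(h)
        for i, (up, fuse) in enumerate(zip(self.ups, self.fuses)):
            h = up(h)
            h = fuse(cat([h, skips[-1 - i]], axis=1))
        return self.head(h).sigmoid()


@dataclass
class NetworkBundle:
    """The four trained parties plus their configurations."""

    G: Generator
    GD: Discriminator
    LD: Discriminator
    S: Segmentor

    def modules(self):
        return {"G": self.G, "GD": self.GD, "LD": self.LD, "S": self.S}


def build_generator(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> Generator:
    return Generator(cfg, rng if rng is not None else np.random.default_rng())


def build_discriminator(cfg: DiscriminatorConfig, rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(cfg, rng if rng is not None else np.random.default_rng())


def build_segmentor(cfg: SegmentorConfig, rng: np.random.Generator | None = None) -> Segmentor:
    return Segmentor(cfg, rng if rng is not None else np.random.default_rng())


def parameter_count(m: Module) -> int:
    return int(sum(p.data.size for p in m.parameters()))
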