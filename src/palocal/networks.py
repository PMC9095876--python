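"""Conditional-GAN architectures for sparse-to-dense localization imaging.

The generator is a customized U-Net. The 3D variant takes a two-channel
volume (sparse localization + regular OR-PAM) and uses transposed
convolutions for upsampling, with batch normalization and spatial dropout;
the 2D variant takes the sparse localization PACT image alone, upsamples by
pixel shuffle (transposed convolutions produce checkerboard artifacts at this
scale), and omits batch normalization and dropout. Both add long skip
connections (channel-wise concatenation of encoder features) and
parameter-free short skip connections (element-wise sum of a stride-1
max-pooled residual, emphasizing local maxima — the localization targets).

The discriminator is a patch-wise classifier of five convolutional layers:
four strided leaky-ReLU blocks and a sigmoid output convolution.

With the default specifications the generators instantiate exactly 17
convolutional layers (counting each upsampling convolution as one layer).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grad import (Tensor, concatenate, conv_nd, max_pool_nd, pixel_shuffle_2d,
                   Module, Conv, ConvTranspose2x, BatchNorm, SpatialDropout)

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator", "pixel_shuffle_upsample",
    "count_parameters", "save_checkpoint", "load_generator",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture hyperparameters of the U-Net generator."""

    dim: int
    in_channels: int
    out_channels: int = 1
    base_width: int = 64
    width_cap: int = 512
    levels: int = 4
    convs_per_block: int = 2
    upsample: str = "transposed"  # "transposed" | "pixel_shuffle"
    batchnorm: bool = True
    dropout_rate: float = 0.0
    final_activation: str = "sigmoid"
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.dim == 3 and self.upsample != "transposed":
            raise ValueError("3D generator uses transposed-convolution upsampling")
        if self.dim == 2:
            if self.upsample != "pixel_shuffle":
                raise ValueError("2D generator uses pixel-shuffle upsampling")
            if self.batchnorm or self.dropout_rate > 0:
                raise ValueError("2D generator omits batch normalization and dropout")
        if self.levels < 1 or self.convs_per_block < 1:
            raise ValueError("levels and convs_per_block must be >= 1")

    @property
    def conv_layer_count(self) -> int:
        """2 * levels * convs_per_block + 1 (output convolution)."""
        return 2 * self.levels * self.convs_per_block + 1

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(min(self.base_width * 2**i, self.width_cap)
                     for i in range(self.levels))

    @staticmethod
    def default_3d() -> "GeneratorSpec":
        """Volumetric OR-PAM generator (two-channel input; ~43 M parameters)."""
        return GeneratorSpec(dim=3, in_channels=2, base_width=64, width_cap=512,
                             upsample="transposed", batchnorm=True, dropout_rate=0.2)

    @staticmethod
    def default_2d() -> "GeneratorSpec":
        """Planar PACT generator (one-channel input; ~102 M parameters)."""
        return GeneratorSpec(dim=2, in_channels=1, base_width=128, width_cap=1024,
                             upsample="pixel_shuffle", batchnorm=False,
                             dropout_rate=0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "GeneratorSpec":
        return GeneratorSpec(**d)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Five convolutional layers: 4 strided leaky-ReLU blocks + sigmoid output."""

    dim: int
    in_channels: int = 1
    base_width: int = 64
    blocks: int = 4
    leaky_slope: float = 0.2
    sigmoid_output: bool = True

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.blocks != 4:
            raise ValueError("the discriminator has exactly 4 convolution blocks")
        if not self.sigmoid_output:
            raise ValueError("the output layer uses a sigmoid activation")

    @property
    def conv_layer_count(self) -> int:
        return self.blocks + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "DiscriminatorSpec":
        return DiscriminatorSpec(**d)

    @staticmethod
    def default_3d() -> "DiscriminatorSpec":
        return DiscriminatorSpec(dim=3)

    @staticmethod
    def default_2d() -> "DiscriminatorSpec":
        return DiscriminatorSpec(dim=2)


def pixel_shuffle_upsample(features: np.ndarray, factor: int = 2) -> np.ndarray:
    """Channel-to-space rearrangement of a (B, C*r^2, H, W) feature array.

    A pure permutation: out[c, r*i + di, r*j + dj] = in[c*r^2 + r*di + dj, i, j].
    """
    return pixel_shuffle_2d(Tensor(np.asarray(features, dtype=np.float64)),
                            factor).data


class _ConvBlock(Module):
    """convs_per_block convolutions with a max-pooled short skip connection.

    out = act(conv_k(... act(conv_2(y1)))) + maxpool3_stride1(y1), where
    y1 = act(conv_1(x)). The residual is parameter-free and channel-matched.
    """

    def __init__(self, cin, cout, spec: GeneratorSpec, rng):
        super().__init__()
        self.dim = spec.dim
        self.slope = spec.leaky_slope
        self.convs = [Conv(cin if i == 0 else cout, cout, 3, dim=spec.dim, rng=rng)
                      for i in range(spec.convs_per_block)]
        self.norms = ([BatchNorm(cout) for _ in range(spec.convs_per_block)]
                      if spec.batchnorm else None)
        self.drop = (SpatialDropout(spec.dropout_rate, rng)
                     if spec.dropout_rate > 0 else None)

    def forward(self, x: Tensor) -> Tensor:
        y = x
        first = None
        for i, conv in enumerate(self.convs):
            y = conv(y)
            if self.norms is not None:
                y = self.norms[i](y)
            y = y.leaky_relu(self.slope)
            if i == 0:
                first = y
        if len(self.convs) > 1:
            y = y + max_pool_nd(first, 3, stride=1, same=True)
        if self.drop is not None:
            y = self.drop(y)
        return y

    @property
    def n_convs(self) -> int:
        return len(self.convs)


class _Upsample(Module):
    """One upsampling convolution: transposed (3D) or pixel shuffle (2D)."""

    def __init__(self, cin, cout, spec: GeneratorSpec, rng):
        super().__init__()
        self.mode = spec.upsample
        if self.mode == "transposed":
            self.op = ConvTranspose2x(cin, cout, 3, dim=spec.dim, rng=rng)
        else:
            self.op = Conv(cin, cout * 4, 3, dim=2, rng=rng)
        self.slope = spec.leaky_slope

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return self.op(x).leaky_relu(self.slope)
        return pixel_shuffle_2d(self.op(x), 2).leaky_relu(self.slope)


class _DecoderStage(Module):
    """Upsample, concatenate the long skip, then refine; short skip via
    max-pooled residual of the upsampled features."""

    def __init__(self, cin, cout, spec: GeneratorSpec, rng):
        super().__init__()
        self.up = _Upsample(cin, cout, spec, rng)
        self.slope = spec.leaky_slope
        self.convs = [Conv(2 * cout if i == 0 else cout, cout, 3, dim=spec.dim, rng=rng)
                      for i in range(spec.convs_per_block - 1)]
        self.norms = ([BatchNorm(cout) for _ in self.convs] if spec.batchnorm else None)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.up(x)
        y = concatenate([up, skip], axis=1)
        for i, conv in enumerate(self.convs):
            y = conv(y)
            if self.norms is not None:
                y = self.norms[i](y)
            y = y.leaky_relu(self.slope)
        if self.convs:
            y = y + max_pool_nd(up, 3, stride=1, same=True)
        return y

    @property
    def n_convs(self) -> int:
        return 1 + len(self.convs)


class UNetGenerator(Module):
    """The sparse-to-dense generator network."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = spec.widths
        self.encoder = []
        cin = spec.in_channels
        for w in widths:
            self.encoder.append(_ConvBlock(cin, w, spec, rng))
            cin = w
        self.decoder = []
        for i in reversed(range(spec.levels)):
            self.decoder.append(_DecoderStage(cin, widths[i], spec, rng))
            cin = widths[i]
        self.out_conv = Conv(cin, spec.out_channels, 3, dim=spec.dim, rng=rng)

    @property
    def num_conv_layers(self) -> int:
        n = sum(b.n_convs for b in self.encoder)
        n += sum(s.n_convs for s in self.decoder)
        return n + 1

    def forward(self, x: Tensor) -> Tensor:
        d = self.spec.dim
        div = 2**self.spec.levels
        for n in x.shape[2:]:
            if n % div:
                raise ValueError(
                    f"input spatial sizes must be divisible by 2^levels = {div}, "
                    f"got {x.shape[2:]}")
        skips = []
        y = x
        for block in self.encoder:
            y = block(y)
            skips.append(y)
            y = max_pool_nd(y, 2)
        for stage, skip in zip(self.decoder, reversed(skips)):
            y = stage(y, skip)
        y = self.out_conv(y)
        if self.spec.final_activation == "sigmoid":
            y = y.sigmoid()
        return y


class PatchDiscriminator(Module):
    """Patch-wise real/synthetic classifier; outputs probabilities in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [spec.base_width * 2**i for i in range(spec.blocks)]
        self.convs = []
        cin = spec.in_channels
        for w in widths:
            self.convs.append(Conv(cin, w, 3, dim=spec.dim, stride=2, pad=1, rng=rng))
            cin = w
        self.out_conv = Conv(cin, 1, 3, dim=spec.dim, rng=rng)

    @property
    def num_conv_layers(self) -> int:
        return len(self.convs) + 1

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for conv in self.convs:
            y = conv(y).leaky_relu(self.spec.leaky_slope)
        return self.out_conv(y).sigmoid()

    def mean_probability(self, x: Tensor) -> Tensor:
        """Average patch probability, the scalar fed to the adversarial loss."""
        return self.forward(x).mean()


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    """Instantiate a seeded, He-normal-initialized generator from its spec."""
    return UNetGenerator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    """Instantiate a seeded, He-normal-initialized discriminator from its spec."""
    return PatchDiscriminator(spec, seed=seed)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars in a network."""
    return model.count_parameters()


def save_checkpoint(model: UNetGenerator, path) -> None:
    """Save generator weights (.npz) with a reconstructible spec sidecar (.yaml)."""
    import yaml
    from pathlib import Path

    path = Path(path)
    np.savez(path, *model.state_arrays())
    with open(path.with_suffix(".yaml"), "w") as f:
        yaml.safe_dump({"generator_spec": model.spec.to_dict()}, f)


def load_generator(path) -> UNetGenerator:
    """Rebuild a generator from a checkpoint written by :func:`save_checkpoint`."""
    import yaml
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".yaml")) as f:
        spec = GeneratorSpec.from_dict(yaml.safe_load(f)["generator_spec"])
    model = UNetGenerator(spec)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_arrays([z[f"arr_{i}"] for i in range(len(z.files))])
    return model
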