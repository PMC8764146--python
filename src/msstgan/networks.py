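"""MsSTNet segmentor and the 70x70 patch discriminator.

The segmentor is a five-stage residual encoder (stage topology and channel
counts follow the residual-18 layout: 64, 64, 128, 256, 512, overall
downsampling x32), an MsST attention bottleneck fed by stages 2-5, and a
U-Net-style decoder: per-level 2x upsampling + convolution blocks with
skip connections from the matching encoder stages, ending in a
single-channel logistic output at full input resolution.

The discriminator is a fully convolutional patch classifier: each output
unit scores one NxN input patch as real or fake; the default stack of
4x4 convolutions with strides 2, 2, 2, 1, 1 has an analytic receptive
field of exactly 70 pixels, verified at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import MsSTBlock
from .nn import Tensor, as_tensor
from .nn import functional as F

__all__ = [
    "EncoderSpec", "DiscriminatorSpec", "Segmentor", "PatchDiscriminator",
    "build_segmentor", "build_discriminator", "segment", "discriminate",
    "receptive_field",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Channel plan of the five encoder stages (input downsampled x32)."""

    stage_channels: tuple[int, int, int, int, int] = (64, 64, 128, 256, 512)
    input_channels: int = 3

    def __post_init__(self):
        if len(self.stage_channels) != 5:
            raise ValueError("encoder needs exactly 5 stages")
        if any(c < 1 for c in self.stage_channels):
            raise ValueError("stage channels must be positive")

    @classmethod
    def tiny(cls) -> "EncoderSpec":
        """Small channel plan for CPU-scale runs; same topology and code path."""
        return cls(stage_channels=(8, 8, 16, 32, 64))


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Strided-convolution stack of the patch classifier.

    ``layers`` lists (out_channels, kernel, stride) in forward order; the
    analytic receptive field of one output unit must equal ``patch_size``.
    """

    layers: tuple[tuple[int, int, int], ...] = (
        (64, 4, 2), (128, 4, 2), (256, 4, 2), (512, 4, 1), (1, 4, 1))
    input_channels: int = 4  # RGB image + 1-channel mask
    patch_size: int = 70

    def __post_init__(self):
        if not self.layers:
            raise ValueError("discriminator needs at least one layer")
        rf = receptive_field(self)
        if rf != self.patch_size:
            raise ValueError(
                f"receptive field of layer stack is {rf}, configured patch size "
                f"is {self.patch_size}")

    @classmethod
    def tiny(cls) -> "DiscriminatorSpec":
        return cls(layers=((8, 4, 2), (16, 4, 2), (32, 4, 2), (64, 4, 1), (1, 4, 1)))


def receptive_field(spec: DiscriminatorSpec | list | tuple) -> int:
    """Analytic receptive field of one output unit.

    Standard recurrence over layers in forward order:
    ``rf <- rf + (k - 1) * jump; jump <- jump * stride``.
    """
    layers = spec.layers if isinstance(spec, DiscriminatorSpec) else tuple(spec)
    if not layers:
        raise ValueError("empty layer list")
    rf, jump = 1, 1
    for layer in layers:
        k, s = layer[-2], layer[-1]
        rf += (k - 1) * jump
        jump *= s
    return rf


class _ResidualBlock(nn.Module):
    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.norm1 = nn.GroupNorm(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.norm2 = nn.GroupNorm(channels)

    def forward(self, x):
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        return (x + y).relu()


class _DownStage(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.down = nn.Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng)
        self.norm = nn.GroupNorm(cout)
        self.block = _ResidualBlock(cout, rng)

    def forward(self, x):
        return self.block(self.norm(self.down(x)).relu())


class _UpBlock(nn.Module):
    """2x upsample (bilinear, or zero-stuffed 'transposed' variant),
    concatenation with the skip features, then conv + norm + ReLU."""

    def __init__(self, cin: int, skip: int, cout: int, rng, transposed: bool = False):
        super().__init__()
        self.transposed = transposed
        self.conv = nn.Conv2d(cin + skip, cout, 3, padding=1, rng=rng)
        self.norm = nn.GroupNorm(cout)

    def forward(self, x, skip=None):
        _, _, h, w = x.shape
        if self.transposed:
            x = F.zero_upsample2x(x)
        else:
            x = F.bilinear_resize(x, 2 * h, 2 * w)
        if skip is not None:
            x = nn.concat([x, skip], axis=1)
        return self.norm(self.conv(x)).relu()


class Segmentor(nn.Module):
    """Encoder -> MsST bottleneck -> decoder, logistic per-pixel output."""

    def __init__(self, spec: EncoderSpec | None = None, msst: MsSTBlock | None = None,
                 reduction: int = 8, seed: int = 0, transposed_decoder: bool = False):
        super().__init__()
        spec = spec or EncoderSpec()
        rng = np.random.default_rng(seed)
        c = spec.stage_channels
        if msst is None:
            msst = MsSTBlock(top_channels=c[4], stage_channels=(c[1], c[2], c[3]),
                             reduction=reduction, rng=rng)
        if msst.top_channels != c[4]:
            raise ValueError(
                f"MsST block built for {msst.top_channels} channels, encoder "
                f"top stage has {c[4]}")
        self.spec = spec
        self.stem_conv = nn.Conv2d(spec.input_channels, c[0], 7, stride=2, padding=3, rng=rng)
        self.stem_norm = nn.GroupNorm(c[0])
        self.stage2 = _DownStage(c[0], c[1], rng)
        self.stage3 = _DownStage(c[1], c[2], rng)
        self.stage4 = _DownStage(c[2], c[3], rng)
        self.stage5 = _DownStage(c[3], c[4], rng)
        self.msst = msst
        self.up1 = _UpBlock(c[4], c[3], c[3], rng, transposed_decoder)
        self.up2 = _UpBlock(c[3], c[2], c[2], rng, transposed_decoder)
        self.up3 = _UpBlock(c[2], c[1], c[1], rng, transposed_decoder)
        self.up4 = _UpBlock(c[1], c[0], c[0], rng, transposed_decoder)
        self.up5 = _UpBlock(c[0], 0, c[0], rng, transposed_decoder)
        self.head = nn.Conv2d(c[0], 1, 1, rng=rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        _, _, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size {(h, w)} not divisible by 32; pad or resize first")
        f1 = self.stem_norm(self.stem_conv(x)).relu()   # /2
        f2 = self.stage2(f1)                            # /4
        f3 = self.stage3(f2)                            # /8
        f4 = self.stage4(f3)                            # /16
        f5 = self.stage5(f4)                            # /32
        bottleneck = self.msst(f2, f3, f4, f5)
        y = self.up1(bottleneck, f4)
        y = self.up2(y, f3)
        y = self.up3(y, f2)
        y = self.up4(y, f1)
        y = self.up5(y)
        return self.head(y).sigmoid()


class PatchDiscriminator(nn.Module):
    """Fully convolutional real/fake classifier over image (+) mask pairs.

    No normalization layers: each output unit's decision then depends on
    exactly its NxN input patch (feature normalization with spatial
    statistics would couple distant patches)."""

    def __init__(self, spec: DiscriminatorSpec | None = None, seed: int = 0):
        super().__init__()
        spec = spec or DiscriminatorSpec()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.convs = []
        cin = spec.input_channels
        for cout, k, s in spec.layers:
            self.convs.append(nn.Conv2d(cin, cout, k, stride=s, padding=1, rng=rng))
            cin = cout

    @staticmethod
    def _leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
        return x.relu() - slope * (-x).relu()

    def forward(self, pair) -> Tensor:
        x = as_tensor(pair)
        for idx, conv in enumerate(self.convs):
            x = conv(x)
            if idx == len(self.convs) - 1:
                return x.sigmoid()
            x = self._leaky_relu(x)
        return x


def build_segmentor(spec: EncoderSpec | None = None, msst: MsSTBlock | None = None,
                    pretrained: bool = False, seed: int = 0,
                    transposed_decoder: bool = False) -> Segmentor:
    """Construct the segmentor; encoder weights are seeded random.

    ``pretrained`` asks for externally trained encoder weights; none are
    bundled, so the flag currently falls back to seeded random
    initialization with a warning.
    """
    model = Segmentor(spec=spec, msst=msst, seed=seed,
                      transposed_decoder=transposed_decoder)
    if pretrained:
        warnings.warn("no pretrained encoder weights bundled; using seeded "
                      "random initialization", stacklevel=2)
    return model


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec=spec, seed=seed)


def segment(model: Segmentor, images) -> np.ndarray:
    """Per-pixel lesion probabilities, (B, 1, H, W) in [0, 1].

    ``images`` is (B, 3, H, W), float in [0, 1], H and W divisible by 32.
    """
    images = as_tensor(images)
    if images.ndim != 4 or images.shape[1] != model.spec.input_channels:
        raise ValueError(f"expected (B, {model.spec.input_channels}, H, W), got {images.shape}")
    model.eval()
    from .nn.tensor import no_grad

    with no_grad():
        return model(images).data


def discriminate(d: PatchDiscriminator, image, mask) -> Tensor:
    """Concatenate image and mask along channels and score the patches."""
    image, mask = as_tensor(image), as_tensor(mask)
    if image.shape[0] != mask.shape[0] or image.shape[2:] != mask.shape[2:]:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} are not spatially aligned")
    return d(nn.concat([image, mask], axis=1))
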