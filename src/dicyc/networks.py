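"""Generator, global transformer and PatchGAN discriminator.

The generator is the standard Resnet-style translation network (reflection
padding, instance norm, 6 residual blocks at the bottleneck) split into an
encoder ``F`` and decoder ``G``, with four modified deformable-convolution
insertion points: before the input convolution, before each of the two
downsampling convolutions, and before the residual stack.  A separate
transformer ``T`` regresses the target coordinates of a regular 6x6 TPS
control grid from the concatenated latents of the two translation directions.

Each direction produces two outputs per input:

* the *undeformed* pass (offsets forced to zero, no global warp) — the pure
  appearance translation, aligned with the source; this is the only pass run
  at prediction time;
* the *deformed* pass — encoder with learned local offset fields, latent
  features warped by the TPS field, then decoded; this is what the
  discriminators see, so the adversarial objective can absorb the
  domain-specific deformation without dragging the appearance mapping along.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np

from ._autograd import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    Linear,
    Module,
    Tensor,
    concat,
    grid_sample,
    pad2d,
)
from .dcn import OffsetConvSpec, make_offset_conv, offset_convolution, warp_by_field
from .phantom import ImageSlice
from .tps import (
    ControlPointSet,
    DenseDisplacementField,
    identity_grid,
    regular_control_grid,
    tps_basis,
)

__all__ = [
    "GeneratorSpec",
    "TransformerSpec",
    "DualSynthesisResult",
    "Generator",
    "Transformer",
    "Discriminator",
    "build_generator",
    "build_transformer",
    "build_discriminator",
    "forward_undeformed",
    "forward_deformed",
    "to_tensor",
    "count_parameters",
]


@dataclasses.dataclass
class GeneratorSpec:
    """Architecture of one translation direction (defaults: standard setup)."""

    in_channels: int = 1
    base_channels: int = 64
    resnet_blocks: int = 6
    first_kernel: int = 7
    other_kernels: int = 3
    deformable: bool = True
    norm: bool = True  # instance normalization (off only for analysis probes)
    # tanh output is scaled to cover +-3 standardized intensity units, since
    # inputs are mean/std normalized rather than min/max scaled
    output_scale: float = 3.0

    def __post_init__(self):
        if self.base_channels < 1 or self.resnet_blocks < 0:
            raise ValueError("invalid generator spec")
        if self.first_kernel % 2 == 0 or self.other_kernels % 2 == 0:
            raise ValueError("kernels must be odd")

    @property
    def latent_channels(self) -> int:
        return self.base_channels * 4


@dataclasses.dataclass
class TransformerSpec:
    """Head regressing TPS control points from two concatenated latents."""

    grid_side: int = 6
    reducer_channels: int = 64
    hidden: int = 64
    max_displacement: float = 0.5

    @property
    def n_points(self) -> int:
        return self.grid_side**2


@dataclasses.dataclass
class DualSynthesisResult:
    """Both outputs of one generator direction plus the fields used."""

    undeformed: Tensor
    deformed: Tensor
    local_fields: List[Tensor]
    global_field: Optional[DenseDisplacementField]
    control_points: Optional[ControlPointSet]
    latent_deformed: Optional[Tensor] = None


def to_tensor(x) -> Tensor:
    """ImageSlice / 2-D array -> (1, 1, H, W) Tensor; Tensors pass through."""
    if isinstance(x, Tensor):
        return x
    if isinstance(x, ImageSlice):
        x = x.pixels
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr)


class _Identity(Module):
    def forward(self, x):
        return x


def _norm(enabled: bool) -> Module:
    return InstanceNorm2d() if enabled else _Identity()


class ResnetBlock(Module):
    def __init__(self, ch: int, k: int, rng, norm: bool = True):
        p = k // 2
        self.conv1 = Conv2d(ch, ch, k, rng=rng)
        self.conv2 = Conv2d(ch, ch, k, rng=rng)
        self.norm1 = _norm(norm)
        self.norm2 = _norm(norm)
        self.pad = p

    def forward(self, x):
        h = self.norm1(self.conv1(pad2d(x, self.pad, "reflect"))).relu()
        h = self.norm2(self.conv2(pad2d(h, self.pad, "reflect")))
        return x + h


class Encoder(Module):
    """Input conv + two downsampling convs + residual stack, with four
    optional deformable insertion points producing shared offset fields."""

    def __init__(self, spec: GeneratorSpec, rng):
        c0, k0, k = spec.base_channels, spec.first_kernel, spec.other_kernels
        self.spec = spec
        self.conv_in = Conv2d(spec.in_channels, c0, k0, rng=rng)
        self.norm_in = _norm(spec.norm)
        self.down1 = Conv2d(c0, c0 * 2, k, stride=2, pad=k // 2, rng=rng)
        self.norm1 = _norm(spec.norm)
        self.down2 = Conv2d(c0 * 2, c0 * 4, k, stride=2, pad=k // 2, rng=rng)
        self.norm2 = _norm(spec.norm)
        self.blocks = [
            ResnetBlock(c0 * 4, k, rng, norm=spec.norm) for _ in range(spec.resnet_blocks)
        ]
        if spec.deformable:
            # one zero-initialized offset conv per insertion point: input
            # conv, both downsample convs, and the residual stack
            self.offsets = [
                make_offset_conv(OffsetConvSpec(spec.in_channels), rng=rng),
                make_offset_conv(OffsetConvSpec(c0), rng=rng),
                make_offset_conv(OffsetConvSpec(c0 * 2), rng=rng),
                make_offset_conv(OffsetConvSpec(c0 * 4), rng=rng),
            ]
        else:
            self.offsets = []

    def offset_parameters(self):
        out = []
        for conv in self.offsets:
            out.append(conv.weight)
            if conv.bias is not None:
                out.append(conv.bias)
        return out

    def synthesis_parameters(self):
        offset = {id(p) for p in self.offset_parameters()}
        return [p for p in self.parameters() if id(p) not in offset]

    def forward(self, x: Tensor, deformed: bool = False, record: Optional[list] = None) -> Tensor:
        def maybe_warp(h, idx):
            if deformed and self.spec.deformable:
                field = offset_convolution(h, self.offsets[idx])
                if record is not None:
                    record.append(field)
                return warp_by_field(h, field)
            return h

        h = maybe_warp(x, 0)
        h = self.norm_in(self.conv_in(pad2d(h, self.spec.first_kernel // 2, "reflect"))).relu()
        h = maybe_warp(h, 1)
        h = self.norm1(self.down1(h)).relu()
        h = maybe_warp(h, 2)
        h = self.norm2(self.down2(h)).relu()
        h = maybe_warp(h, 3)
        for blk in self.blocks:
            h = blk(h)
        return h


class Decoder(Module):
    def __init__(self, spec: GeneratorSpec, rng):
        c0, k = spec.base_channels, spec.other_kernels
        self.up1 = ConvTranspose2d(c0 * 4, c0 * 2, k, stride=2, pad=k // 2, output_pad=1, rng=rng)
        self.norm1 = _norm(spec.norm)
        self.up2 = ConvTranspose2d(c0 * 2, c0, k, stride=2, pad=k // 2, output_pad=1, rng=rng)
        self.norm2 = _norm(spec.norm)
        self.conv_out = Conv2d(c0, spec.in_channels, spec.first_kernel, rng=rng)
        self.first_kernel = spec.first_kernel
        self.output_scale = spec.output_scale

    def forward(self, z: Tensor) -> Tensor:
        h = self.norm1(self.up1(z)).relu()
        h = self.norm2(self.up2(h)).relu()
        out = self.conv_out(pad2d(h, self.first_kernel // 2, "reflect")).tanh()
        return out * self.output_scale if self.output_scale != 1.0 else out


class Generator(Module):
    """Encoder F + decoder G of one translation direction."""

    def __init__(self, spec: GeneratorSpec, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.encoder = Encoder(spec, rng)
        self.decoder = Decoder(spec, rng)

    def offset_parameters(self):
        return self.encoder.offset_parameters()

    def synthesis_parameters(self):
        offset = {id(p) for p in self.offset_parameters()}
        return [p for p in self.parameters() if id(p) not in offset]

    def forward(self, x, deformed: bool = False, record: Optional[list] = None) -> Tensor:
        z = self.encoder(to_tensor(x), deformed=deformed, record=record)
        return self.decoder(z)


class Transformer(Module):
    """Regresses TPS target control points from two concatenated latents.

    The final layer is zero-initialized and the output is
    ``clip(grid + max_disp * tanh(raw), -1, 1)``: exactly the regular grid at
    initialization (identity warp), hard-bounded to the normalized square.
    """

    def __init__(self, spec: TransformerSpec, latent_channels: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        c = spec.reducer_channels
        self.reduce_a1 = Conv2d(latent_channels, c, 3, stride=2, pad=1, rng=rng)
        self.reduce_a2 = Conv2d(c, c, 3, stride=2, pad=1, rng=rng)
        self.reduce_b1 = Conv2d(latent_channels, c, 3, stride=2, pad=1, rng=rng)
        self.reduce_b2 = Conv2d(c, c, 3, stride=2, pad=1, rng=rng)
        self.fc1 = Linear(2 * c, spec.hidden, rng=rng)
        self.fc2 = Linear(spec.hidden, 2 * spec.n_points, rng=rng, zero_init=True)
        self.grid = regular_control_grid(spec.grid_side)

    def forward(self, latent_a: Tensor, latent_b: Tensor) -> Tensor:
        za = self.reduce_a2(self.reduce_a1(latent_a).relu()).relu()
        zb = self.reduce_b2(self.reduce_b1(latent_b).relu()).relu()
        h = concat([za.mean(axis=(2, 3)), zb.mean(axis=(2, 3))], axis=1)  # (N, 2c)
        raw = self.fc2(self.fc1(h).relu())  # (N, 2 * n_points)
        pts = raw.reshape(self.spec.n_points, 2).tanh() * self.spec.max_displacement
        return (pts + Tensor(self.grid.points)).clip(-1.0, 1.0)

    def control_points(self, latent_a: Tensor, latent_b: Tensor) -> ControlPointSet:
        return ControlPointSet(self.forward(latent_a, latent_b).data)


class Discriminator(Module):
    """70x70-receptive-field PatchGAN: 4x4 convs, 64-128-256-512-1 channels,
    stride 2 except the last two layers, instance norm on the middle layers."""

    def __init__(self, in_channels: int = 1, ndf: int = 64, rng=None, use_norm: bool = True):
        rng = rng or np.random.default_rng(0)
        self.c1 = Conv2d(in_channels, ndf, 4, stride=2, pad=1, rng=rng)
        self.c2 = Conv2d(ndf, ndf * 2, 4, stride=2, pad=1, rng=rng)
        self.c3 = Conv2d(ndf * 2, ndf * 4, 4, stride=2, pad=1, rng=rng)
        self.c4 = Conv2d(ndf * 4, ndf * 8, 4, stride=1, pad=1, rng=rng)
        self.c5 = Conv2d(ndf * 8, 1, 4, stride=1, pad=1, rng=rng)
        self.norms = [InstanceNorm2d() for _ in range(3)] if use_norm else None

    def forward(self, x) -> Tensor:
        h = self.c1(to_tensor(x)).leaky_relu(0.2)
        for conv, k in ((self.c2, 0), (self.c3, 1), (self.c4, 2)):
            h = conv(h)
            if self.norms is not None:
                h = self.norms[k](h)
            h = h.leaky_relu(0.2)
        return self.c5(h)


def build_generator(spec: Optional[GeneratorSpec] = None, seed: int = 0) -> Generator:
    return Generator(spec or GeneratorSpec(), rng=np.random.default_rng(seed))


def build_transformer(
    spec: Optional[TransformerSpec] = None,
    latent_channels: int = 256,
    seed: int = 0,
) -> Transformer:
    return Transformer(spec or TransformerSpec(), latent_channels, rng=np.random.default_rng(seed))


def build_discriminator(in_channels: int = 1, ndf: int = 64, seed: int = 0, use_norm: bool = True) -> Discriminator:
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    return Discriminator(in_channels, ndf, rng=np.random.default_rng(seed), use_norm=use_norm)


def count_parameters(module: Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.data.size for p in module.parameters()))


def forward_undeformed(generator: Generator, x) -> Tensor:
    """Pure appearance pass: offsets bypassed, no global warp."""
    return generator(to_tensor(x), deformed=False)


def global_warp_latent(
    latent: Tensor, points: Tensor, grid: ControlPointSet, basis: Optional[np.ndarray] = None
) -> Tuple[Tensor, DenseDisplacementField]:
    """Warp latent features by the TPS defined by predicted control points.

    The dense warped positions are linear in the points (see
    :func:`dicyc.tps.tps_basis`), so this stays differentiable with a single
    matmul.  Returns the warped latent and the dense displacement field.
    """
    h, w = latent.shape[2], latent.shape[3]
    if basis is None:
        basis = tps_basis(grid, (h, w))
    positions = Tensor(basis) @ points  # (H*W, 2)
    sample_grid = positions.reshape(1, h, w, 2)
    warped = grid_sample(latent, sample_grid, padding="border")
    field = DenseDisplacementField(positions.data.reshape(h, w, 2) - identity_grid((h, w)))
    return warped, field


def forward_deformed(
    generator: Generator,
    transformer: Transformer,
    x,
    latent_opposite: Tensor,
    basis: Optional[np.ndarray] = None,
) -> DualSynthesisResult:
    """Run both passes of one direction; the deformed pass warps the latent.

    ``latent_opposite`` is the opposite-direction encoder's latent of a
    domain-target image from the same minibatch (a training-time-only
    dependency; prediction uses only the undeformed pass).
    """
    x = to_tensor(x)
    undeformed = generator(x, deformed=False)
    fields: List[Tensor] = []
    z_t = generator.encoder(x, deformed=True, record=fields)
    points = transformer(z_t, latent_opposite)
    warped, global_field = global_warp_latent(z_t, points, transformer.grid, basis)
    deformed = generator.decoder(warped)
    return DualSynthesisResult(
        undeformed=undeformed,
        deformed=deformed,
        local_fields=fields,
        global_field=global_field,
        control_points=ControlPointSet(points.data.copy()),
        latent_deformed=z_t,
    )
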