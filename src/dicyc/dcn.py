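"""Modified deformable convolution with a single shared 2-D offset field.

The original deformable convolution learns 2N offset maps — an independent
(x, y) displacement per input channel.  For synthesis we want the local
deformation to act like a warp of the *image*, identical across channels, so
the offset convolution here emits exactly two maps (one x, one y) that
displace the bilinear sampling locations of every channel alike.  This costs
1/N of the original offset parameters and, with zero-initialized offset
weights, degenerates bit-exactly to the plain convolution.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from ._autograd import Conv2d, Module, Tensor, as_tensor, grid_sample
from .tps import identity_grid

__all__ = [
    "OffsetConvSpec",
    "DeformableConv2d",
    "offset_convolution",
    "deformable_apply",
]


@dataclasses.dataclass
class OffsetConvSpec:
    """Configuration of the offset-predicting convolution (2 output maps)."""

    in_channels: int
    kernel_size: int = 3
    init: Literal["zero", "random"] = "zero"

    out_channels: int = dataclasses.field(default=2, init=False)

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")


def make_offset_conv(spec: OffsetConvSpec, rng=None) -> Conv2d:
    conv = Conv2d(
        spec.in_channels,
        2,
        spec.kernel_size,
        stride=1,
        pad=spec.kernel_size // 2,
        rng=rng,
        zero_init=spec.init == "zero",
    )
    return conv


def offset_convolution(features: Tensor, conv: Conv2d) -> Tensor:
    """Predict one shared (x, y) offset field, shape (N, 2, H, W).

    Offsets are in normalized [-1, 1] coordinates and are not clipped;
    out-of-range samples rely on border padding downstream.
    """
    features = as_tensor(features)
    field = conv(features)
    if field.shape[1] != 2:
        raise ValueError("offset convolution must output exactly 2 channels")
    return field


def warp_by_field(features: Tensor, field: Tensor) -> Tensor:
    """Bilinearly warp all channels by one shared offset field.

    ``field`` is (N, 2, H, W) in normalized coordinates.  An exactly zero
    field short-circuits to the input (identity warp, bit-exact) while still
    letting gradients flow into the field.
    """
    features = as_tensor(features)
    field = as_tensor(field)
    if field.shape[0] != features.shape[0] or field.shape[2:] != features.shape[2:]:
        raise ValueError("field spatial shape must match the features")
    if not np.any(field.data) and not (field.requires_grad or field._parents):
        return features
    n, _, h, w = field.shape
    base = identity_grid((h, w))[None]  # (1, H, W, 2)
    grid = field.transpose(0, 2, 3, 1) + Tensor(base)
    return grid_sample(features, grid, padding="border")


class DeformableConv2d(Module):
    """Offset convolution + shared-field warp + standard convolution."""

    def __init__(self, spec: OffsetConvSpec, conv: Conv2d, rng=None):
        self.spec = spec
        self.offset_conv = make_offset_conv(spec, rng=rng)
        self.conv = conv

    def offset_parameters(self):
        return [self.offset_conv.weight] + (
            [self.offset_conv.bias] if self.offset_conv.bias is not None else []
        )

    def forward(self, x: Tensor, deformed: bool = True, record=None) -> Tensor:
        if not deformed:
            return self.conv(x)
        field = offset_convolution(x, self.offset_conv)
        if record is not None:
            record.append(field)
        warped = deformable_apply_field(x, field)
        return self.conv(warped)


def deformable_apply_field(features: Tensor, field: Tensor) -> Tensor:
    """Warp features by a shared field (no convolution)."""
    return warp_by_field(features, field)


def deformable_apply(features: Tensor, field: Tensor, conv: Conv2d) -> Tensor:
    """Resample ``features`` through the shared field, then convolve.

    With an exactly zero field this equals the plain convolution bit-exactly;
    gradients flow through both the sampling locations and the kernel.
    """
    return conv(warp_by_field(features, field))
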