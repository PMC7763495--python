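"""Loss terms: LSGAN adversarial, NMI alignment, and the two cycle losses.

The full objective is

    L = L_GAN(A->B) + L_GAN(B->A)
        + lambda_align * L_align + lambda_cyc * L_cyc + lambda_dicyc * L_dicyc

with defaults lambda_cyc = lambda_dicyc = 10 and lambda_align = 0.9.  The
crucial structural property is *which pass feeds which term*: the adversarial
losses consume only the deformed outputs, while the alignment loss consumes
only the undeformed outputs.  A deformation-reproducing solution therefore
lowers the GAN loss without touching the alignment loss, and vice versa — the
two objectives no longer pull the same parameters in opposite directions.

The alignment measure is pluggable (``nmi``, ``gcc``, or a registered
plugin); NMI is normalized as 2 I(X;Y) / (H(X) + H(Y)) in [0, 1] so the
constant 2 in the alignment loss makes its minimum exactly 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Dict, Union

import numpy as np

from ._autograd import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "lsgan_discriminator_loss",
    "lsgan_generator_loss",
    "gan_discriminator_loss",
    "gan_generator_loss",
    "normalized_mutual_information",
    "soft_nmi",
    "gcc_alignment",
    "alignment_loss",
    "cycle_loss",
    "dicyc_loss",
    "total_loss",
    "register_alignment_measure",
    "get_alignment_measure",
]

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclasses.dataclass
class LossWeights:
    lambda_cyc: float = 10.0
    lambda_dicyc: float = 10.0
    lambda_align: float = 0.9

    def __post_init__(self):
        if min(self.lambda_cyc, self.lambda_dicyc, self.lambda_align) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclasses.dataclass
class LossBreakdown:
    """The five loss terms and their exact weighted sum."""

    gan_AB: float
    gan_BA: float
    align: float
    cyc: float
    dicyc: float
    total: float

    @classmethod
    def assemble(cls, gan_AB, gan_BA, align, cyc, dicyc, weights: LossWeights):
        parts = {"gan_AB": gan_AB, "gan_BA": gan_BA, "align": align, "cyc": cyc, "dicyc": dicyc}
        vals = {}
        for name, v in parts.items():
            v = float(v.item() if isinstance(v, Tensor) else v)
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite loss term: {name}")
            vals[name] = v
        total = (
            vals["gan_AB"]
            + vals["gan_BA"]
            + weights.lambda_align * vals["align"]
            + weights.lambda_cyc * vals["cyc"]
            + weights.lambda_dicyc * vals["dicyc"]
        )
        return cls(total=total, **vals)


def total_loss(gan_AB, gan_BA, align, cyc, dicyc, weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Assemble the weighted total; raises naming any non-finite term."""
    return LossBreakdown.assemble(gan_AB, gan_BA, align, cyc, dicyc, weights)


# ---------------------------------------------------------------------------
# adversarial losses (least-squares by default; log form behind a flag)
# ---------------------------------------------------------------------------

def lsgan_discriminator_loss(d_real: ArrayOrTensor, d_fake: ArrayOrTensor) -> Tensor:
    """mean((D(real) - 1)^2) / 2 + mean(D(fake)^2) / 2 over the patch map."""
    d_real, d_fake = as_tensor(d_real), as_tensor(d_fake)
    if d_real.shape != d_fake.shape:
        raise ValueError("patch maps must share a shape")
    return ((d_real - 1.0) ** 2.0).mean() * 0.5 + (d_fake**2.0).mean() * 0.5


def lsgan_generator_loss(d_fake: ArrayOrTensor) -> Tensor:
    """mean((D(fake) - 1)^2); the fake here is the *deformed* output."""
    d_fake = as_tensor(d_fake)
    return ((d_fake - 1.0) ** 2.0).mean()


def gan_discriminator_loss(d_real: ArrayOrTensor, d_fake: ArrayOrTensor, eps: float = 1e-12) -> Tensor:
    """Cross-entropy form on sigmoid(D); available for completeness."""
    d_real, d_fake = as_tensor(d_real), as_tensor(d_fake)
    pr = 1.0 / ((-d_real).exp() + 1.0)
    pf = 1.0 / ((-d_fake).exp() + 1.0)
    return -((pr + eps).log().mean() + (1.0 - pf + eps).log().mean())


def gan_generator_loss(d_fake: ArrayOrTensor, eps: float = 1e-12) -> Tensor:
    d_fake = as_tensor(d_fake)
    pf = 1.0 / ((-d_fake).exp() + 1.0)
    return -(pf + eps).log().mean()


# ---------------------------------------------------------------------------
# normalized mutual information
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    pix = getattr(x, "pixels", x)
    return np.asarray(pix, dtype=float)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(
    x,
    y,
    bins: int = 64,
    mode: str = "hard",
    binning: str = "width",
) -> float:
    """NMI = 2 I(X;Y) / (H(X) + H(Y)) in [0, 1] from a joint histogram.

    ``mode='hard'`` uses a plain joint histogram (evaluation); use
    :func:`soft_nmi` for the differentiable Parzen estimate.
    ``binning='rank'`` assigns equal-mass rank bins, making the value
    invariant under strictly monotone intensity transforms.
    """
    if mode == "soft":
        return float(soft_nmi(Tensor(_as_array(x)), Tensor(_as_array(y)), bins=min(bins, 32)).item())
    if bins < 2:
        raise ValueError("need at least 2 bins")
    xa, ya = _as_array(x).ravel(), _as_array(y).ravel()
    if xa.shape != ya.shape:
        raise ValueError("images must share a shape")
    if xa.std() == 0 or ya.std() == 0:
        warnings.warn("constant image has zero entropy; NMI defined as 0")
        return 0.0
    if binning == "rank":
        xa = np.argsort(np.argsort(xa, kind="stable"), kind="stable")
        ya = np.argsort(np.argsort(ya, kind="stable"), kind="stable")
    joint, _, _ = np.histogram2d(xa, ya, bins=bins)
    p = joint / joint.sum()
    hx = _entropy(p.sum(axis=1))
    hy = _entropy(p.sum(axis=0))
    hxy = _entropy(p.ravel())
    if hx + hy == 0:
        warnings.warn("degenerate histograms; NMI defined as 0")
        return 0.0
    mi = hx + hy - hxy
    return float(2.0 * mi / (hx + hy))


def soft_nmi(x: Tensor, y: Tensor, bins: int = 32, bandwidth_bins: float = 1.5, clip_std: float = 3.0) -> Tensor:
    """Differentiable NMI via Parzen soft-binning with Gaussian kernels.

    Intensities are standardized (statistics detached) and clipped to
    ``+-clip_std``; bin centers span that range and each sample spreads over
    bins with a Gaussian of ``bandwidth_bins`` bin widths.
    """
    x, y = as_tensor(x), as_tensor(y)
    n = x.data.size
    if y.data.size != n:
        raise ValueError("images must share a shape")

    def memberships(t: Tensor) -> Tensor:
        mu, sd = float(t.data.mean()), float(t.data.std())
        if sd == 0:
            raise ValueError("constant image has zero entropy")
        z = ((t - mu) * (1.0 / sd)).clip(-clip_std, clip_std).reshape(n, 1)
        centers = np.linspace(-clip_std, clip_std, bins)[None, :]
        h = bandwidth_bins * (2.0 * clip_std / (bins - 1))
        w = (-((z - Tensor(centers)) ** 2.0) * (1.0 / (2.0 * h * h))).exp()
        return w / w.sum(axis=1, keepdims=True)

    wx = memberships(x)
    wy = memberships(y)
    joint = wx.transpose(1, 0) @ wy * (1.0 / n)  # (bins, bins)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    eps = 1e-12
    hx = -(px * (px + eps).log()).sum()
    hy = -(py * (py + eps).log()).sum()
    hxy = -(joint * (joint + eps).log()).sum()
    mi = hx + hy - hxy
    return (mi * 2.0) / (hx + hy)


# ---------------------------------------------------------------------------
# gradient cross-correlation
# ---------------------------------------------------------------------------

def _pearson_abs(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-gradient image; GCC defined as 0")
        return 0.0
    return float(abs(a @ b / (na * nb)))


def gcc_alignment(x, y) -> float:
    """Mean absolute Pearson correlation of horizontal/vertical gradients."""
    xa, ya = _as_array(x), _as_array(y)
    if xa.shape != ya.shape:
        raise ValueError("images must share a shape")
    gx = np.gradient(xa)
    gy = np.gradient(ya)
    return 0.5 * (_pearson_abs(gx[1], gy[1]) + _pearson_abs(gx[0], gy[0]))


def gcc_alignment_t(x: Tensor, y: Tensor) -> Tensor:
    """Differentiable GCC on tensors shaped (..., H, W)."""
    x, y = as_tensor(x), as_tensor(y)

    def corr(a: Tensor, b: Tensor) -> Tensor:
        am = a - a.mean()
        bm = b - b.mean()
        num = (am * bm).sum()
        den = ((am * am).sum() * (bm * bm).sum()).sqrt() + 1e-12
        return (num / den).abs()

    dx_x = x[..., :, 1:] - x[..., :, :-1]
    dx_y = y[..., :, 1:] - y[..., :, :-1]
    dy_x = x[..., 1:, :] - x[..., :-1, :]
    dy_y = y[..., 1:, :] - y[..., :-1, :]
    return (corr(dx_x, dx_y) + corr(dy_x, dy_y)) * 0.5


# ---------------------------------------------------------------------------
# pluggable alignment measures
# ---------------------------------------------------------------------------

_MEASURES: Dict[str, Callable] = {}


def register_alignment_measure(name: str, fn: Callable) -> None:
    """Register a similarity measure scaled to [0, 1] under ``plugin:<name>``."""
    _MEASURES[name] = fn


def get_alignment_measure(key: str) -> Callable:
    if key == "nmi":
        return soft_nmi
    if key == "gcc":
        return gcc_alignment_t
    if key.startswith("plugin:"):
        name = key.split(":", 1)[1]
        if name not in _MEASURES:
            raise KeyError(f"no alignment measure registered as {name!r}")
        return _MEASURES[name]
    raise KeyError(f"unknown alignment measure {key!r}")


def alignment_loss(
    x_a,
    synth_ab_undeformed,
    x_b,
    synth_ba_undeformed,
    measure: Union[str, Callable] = "nmi",
):
    """2 - m(xA, undeformed A->B output) - m(xB, undeformed B->A output).

    Consumes only the undeformed outputs, so it carries no gradient with
    respect to any deformation parameter.
    """
    if isinstance(measure, str):
        measure = get_alignment_measure(measure)
    m1 = measure(as_tensor(_as_array(x_a)), synth_ab_undeformed if isinstance(synth_ab_undeformed, Tensor) else as_tensor(_as_array(synth_ab_undeformed)))
    m2 = measure(as_tensor(_as_array(x_b)), synth_ba_undeformed if isinstance(synth_ba_undeformed, Tensor) else as_tensor(_as_array(synth_ba_undeformed)))
    for m in (m1, m2):
        v = m.item() if isinstance(m, Tensor) else float(m)
        if not -1e-9 <= v <= 1.0 + 1e-9:
            raise ValueError(f"alignment measure out of [0, 1]: {v}")
    if isinstance(m1, Tensor) or isinstance(m2, Tensor):
        return 2.0 - as_tensor(m1) - as_tensor(m2)
    return 2.0 - m1 - m2


# ---------------------------------------------------------------------------
# cycle losses
# ---------------------------------------------------------------------------

def _l1(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch in cycle loss")
    return (a - b).abs().mean()


def cycle_loss(x_a, cycled_a, x_b, cycled_b) -> Tensor:
    """Undeformed round-trip penalty: ||cyc(xA) - xA||_1 + ||cyc(xB) - xB||_1."""
    return _l1(cycled_a, x_a) + _l1(cycled_b, x_b)


def dicyc_loss(x_a, cycled_a_deformed, x_b, cycled_b_deformed) -> Tensor:
    """Same functional form, applied to the deformed-pass round trips."""
    return _l1(cycled_a_deformed, x_a) + _l1(cycled_b_deformed, x_b)
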