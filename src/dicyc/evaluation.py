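"""Quantitative and qualitative evaluation: MSE / PSNR / SSIM, paired
t-tests, checkerboard and signed-error visualizations, and model-complexity
accounting (trainable parameters and multiply-add counts).

SSIM is computed *globally* over the evaluated region,

    SSIM = (2 mu_a mu_b + c1)(2 cov_ab + c2)
           / ((mu_a^2 + mu_b^2 + c1)(var_a + var_b + c2)),

with the conventional stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2 where L
is the reference dynamic range; a sliding-window mean-SSIM variant is
available behind a flag.  PSNR uses the *reference* maximum, and identical
images report an infinity flag rather than a number.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from ._autograd import Module, mac_tally
from .phantom import ImageSlice

__all__ = [
    "MetricsReport",
    "metrics",
    "paired_t_test",
    "checkerboard",
    "error_image",
    "count_parameters",
    "count_macs",
    "summarize_reports",
]


@dataclasses.dataclass
class MetricsReport:
    mse: float
    psnr: float  # dB; +inf when mse == 0 (see psnr_infinite)
    ssim: float
    n_voxels: int
    mask_name: Optional[str] = None

    @property
    def psnr_infinite(self) -> bool:
        return np.isinf(self.psnr)


def _pixels(x) -> np.ndarray:
    if isinstance(x, ImageSlice):
        return x.pixels
    return np.asarray(x, dtype=float)


def metrics(x, reference, mask: Optional[np.ndarray] = None, mask_name: Optional[str] = None,
            windowed_ssim: bool = False) -> MetricsReport:
    """MSE, PSNR and SSIM of ``x`` against ``reference`` over ``mask``."""
    xa, ra = _pixels(x), _pixels(reference)
    if xa.shape != ra.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != xa.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask")
        xv, rv = xa[mask], ra[mask]
    else:
        xv, rv = xa.ravel(), ra.ravel()
    mse = float(np.mean((rv - xv) ** 2))
    ref_max = float(np.max(rv))  # the reference (target) maximum, as printed
    psnr = np.inf if mse == 0 else 10.0 * np.log10(ref_max**2 / mse)
    L = float(rv.max() - rv.min())
    if windowed_ssim:
        from skimage.metrics import structural_similarity

        ssim = float(structural_similarity(rv if mask is not None else ra,
                                           xv if mask is not None else xa,
                                           data_range=L if L > 0 else 1.0))
    else:
        c1 = (0.01 * L) ** 2
        c2 = (0.03 * L) ** 2
        mu_a, mu_b = xv.mean(), rv.mean()
        var_a, var_b = xv.var(), rv.var()
        cov = float(np.mean((xv - mu_a) * (rv - mu_b)))
        ssim = float(
            (2 * mu_a * mu_b + c1)
            * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
        )
    return MetricsReport(mse=mse, psnr=psnr, ssim=ssim, n_voxels=int(xv.size), mask_name=mask_name)


def paired_t_test(values_a, values_b) -> Tuple[float, float]:
    """Classical two-sided paired t-test; errors on zero-variance differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def checkerboard(x, y, tile: int) -> np.ndarray:
    """Alternating tiles from two images (qualitative alignment display)."""
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise ValueError("shape mismatch")
    if tile < 1:
        raise ValueError("tile must be >= 1")
    h, w = xa.shape
    yy, xx = np.mgrid[0:h, 0:w]
    take_x = ((yy // tile) + (xx // tile)) % 2 == 0
    return np.where(take_x, xa, ya)


def error_image(x, reference) -> Tuple[np.ndarray, float]:
    """Signed difference map plus its symmetric color-scale limit."""
    xa, ra = _pixels(x), _pixels(reference)
    if xa.shape != ra.shape:
        raise ValueError("shape mismatch")
    diff = xa - ra
    return diff, float(np.abs(diff).max())


def count_parameters(network: Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.data.size for p in network.parameters()))


def count_macs(network, input_shape: Tuple[int, ...], *args, **kwargs) -> int:
    """Multiply-add count of one forward pass at ``input_shape``.

    Counts one MAC per kernel-element multiply in convolutions and matrix
    products; normalization, activations and resampling are excluded.  The
    network is run once on zeros of the given shape.
    """
    x = np.zeros(input_shape, dtype=float)
    with mac_tally() as tally:
        network(x, *args, **kwargs)
    return tally.total


def summarize_reports(reports_by_method, paired_on: str = "mse"):
    """Mean/std table per method plus paired-t p-values against the first.

    ``reports_by_method`` maps method name -> list of MetricsReport (one per
    image/volume).  Returns a pandas DataFrame.
    """
    import pandas as pd

    methods = list(reports_by_method)
    rows = []
    base = methods[0]
    for name in methods:
        reps = reports_by_method[name]
        row = {"method": name, "n": len(reps)}
        for field in ("mse", "psnr", "ssim"):
            vals = np.array([getattr(r, field) for r in reps], dtype=float)
            finite = vals[np.isfinite(vals)]
            row[f"{field}_mean"] = finite.mean() if finite.size else np.nan
            row[f"{field}_std"] = finite.std(ddof=1) if finite.size > 1 else 0.0
        if name != base and len(reps) == len(reports_by_method[base]) and len(reps) >= 2:
            a = [getattr(r, paired_on) for r in reports_by_method[base]]
            b = [getattr(r, paired_on) for r in reps]
            try:
                _, p = paired_t_test(a, b)
            except ValueError:
                p = np.nan
            row[f"p_vs_{base}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
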