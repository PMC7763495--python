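"""Thin-plate-spline machinery for the global deformation model.

A TPS warp maps a regular grid of source control points onto predicted target
points with the interpolant

    Phi(t) = c + A t + W^T s(t),      s_i(t) = delta(||t - t_i||),
    delta(r) = r^2 log r  (delta(0) = 0),

the unique interpolant minimizing the bending energy of the displacement
surface.  All coordinates live on the normalized square ``[-1, 1]^2`` with
pixel centers at the endpoints (align-corners); grids and fields use the
``(x, y)`` channel order.  Dense fields are *displacements*: the zero field is
the identity resampling and composition of translations is additive.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Tuple

import numpy as np

from ._autograd import grid_sample_np

__all__ = [
    "ControlPointSet",
    "TPSCoefficients",
    "DenseDisplacementField",
    "tps_kernel",
    "regular_control_grid",
    "fit_tps",
    "tps_displacement",
    "tps_system_matrix",
    "tps_basis",
    "identity_grid",
    "resample",
    "compose",
    "save_field",
    "load_field",
]


@dataclasses.dataclass(frozen=True)
class ControlPointSet:
    """N control points on the normalized [-1, 1]^2 square."""

    points: np.ndarray  # (N, 2), columns (x, y)
    layout: Literal["regular-grid", "free"] = "free"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("need at least 3 control points of dimension 2")
        if np.abs(pts).max() > 1.0 + 1e-9:
            raise ValueError("control points must lie in [-1, 1]^2")
        if self.layout == "regular-grid":
            n = int(round(np.sqrt(pts.shape[0])))
            if n * n != pts.shape[0]:
                raise ValueError("regular-grid layout requires N = n^2 points")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass(frozen=True)
class TPSCoefficients:
    """Affine part (c, A) and bending weights W of a fitted TPS."""

    affine_offset: np.ndarray  # (2,)
    affine_matrix: np.ndarray  # (2, 2)
    weights: np.ndarray  # (N, 2)
    source_points: ControlPointSet


@dataclasses.dataclass(frozen=True)
class DenseDisplacementField:
    """Per-pixel (x, y) displacement in normalized coordinates.

    ``offsets`` has shape (H, W, 2) and is *added* to the identity sampling
    grid: output(p) = input(p + offsets(p)).
    """

    offsets: np.ndarray

    def __post_init__(self):
        off = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", off)
        if off.ndim != 3 or off.shape[2] != 2:
            raise ValueError("offsets must have shape (H, W, 2)")
        if not np.all(np.isfinite(off)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.offsets.shape[:2]

    def is_zero(self) -> bool:
        return not np.any(self.offsets)

    def mean_abs_displacement(self) -> float:
        return float(np.abs(self.offsets).mean())

    @classmethod
    def zero(cls, shape: Tuple[int, int]) -> "DenseDisplacementField":
        return cls(np.zeros((shape[0], shape[1], 2)))


def tps_kernel(r):
    """Radial kernel r^2 log r with the continuity convention delta(0) = 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("kernel radius must be nonnegative")
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    if out.ndim == 0:
        return float(out)
    return out


def regular_control_grid(n: int) -> ControlPointSet:
    """n x n points evenly spanning [-1, 1]^2 inclusive, row-major order."""
    if n < 2:
        raise ValueError("grid side must be at least 2")
    axis = np.linspace(-1.0, 1.0, n)
    gy, gx = np.meshgrid(axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    return ControlPointSet(points=pts, layout="regular-grid")


def tps_system_matrix(source: ControlPointSet, regularization: float = 0.0) -> np.ndarray:
    """The (N+3) x (N+3) TPS system matrix [[K + lam I, P], [P^T, 0]]."""
    pts = source.points
    n = pts.shape[0]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    k = tps_kernel(d)
    if regularization:
        k = k + regularization * np.eye(n)
    p = np.concatenate([np.ones((n, 1)), pts], axis=1)  # (N, 3)
    top = np.concatenate([k, p], axis=1)
    bottom = np.concatenate([p.T, np.zeros((3, 3))], axis=1)
    return np.concatenate([top, bottom], axis=0)


def fit_tps(
    source: ControlPointSet,
    target: ControlPointSet,
    regularization: float = 0.0,
) -> TPSCoefficients:
    """Solve the TPS interpolation system mapping source points onto targets.

    The side conditions (columns of W summing to zero and W orthogonal to the
    source coordinates) are part of the linear system, so the bending term
    carries no affine component: exactly affine correspondences come out with
    W = 0.
    """
    if source.n != target.n:
        raise ValueError("source and target must have the same number of points")
    L = tps_system_matrix(source, regularization)
    rhs = np.concatenate([target.points, np.zeros((3, 2))], axis=0)
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "degenerate control points (collinear or duplicated); "
            "enable regularization"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular TPS system")
    w = sol[: source.n]
    c = sol[source.n]
    a = sol[source.n + 1 :].T  # (2, 2); rows map (x, y)
    return TPSCoefficients(affine_offset=c, affine_matrix=a, weights=w, source_points=source)


def _tps_evaluate(coeffs: TPSCoefficients, query: np.ndarray) -> np.ndarray:
    """Evaluate Phi at query points (M, 2)."""
    pts = coeffs.source_points.points
    d = np.linalg.norm(query[:, None, :] - pts[None, :, :], axis=-1)
    return (
        coeffs.affine_offset[None, :]
        + query @ coeffs.affine_matrix.T
        + tps_kernel(d) @ coeffs.weights
    )


def identity_grid(shape: Tuple[int, int]) -> np.ndarray:
    """Normalized align-corners sampling grid, shape (H, W, 2), (x, y) order."""
    h, w = shape
    ys = np.linspace(-1.0, 1.0, h)
    xs = np.linspace(-1.0, 1.0, w)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([gx, gy], axis=-1)


def tps_displacement(coeffs: TPSCoefficients, shape: Tuple[int, int]) -> DenseDisplacementField:
    """Evaluate Phi(t) - t on the dense normalized pixel grid."""
    grid = identity_grid(shape).reshape(-1, 2)
    disp = _tps_evaluate(coeffs, grid) - grid
    return DenseDisplacementField(disp.reshape(shape[0], shape[1], 2))


def tps_basis(source: ControlPointSet, shape: Tuple[int, int], regularization: float = 0.0) -> np.ndarray:
    """Linear map from target control points to dense warped positions.

    Because the TPS system matrix depends only on the *source* grid, the
    fitted coefficients — and hence the dense warp — are linear in the target
    coordinates.  Returns B of shape (H*W, N) such that the dense warped
    positions are ``B @ target_points`` (one matmul, so the warp is trivially
    differentiable with respect to the predicted points).
    """
    L = tps_system_matrix(source, regularization)
    Linv = np.linalg.inv(L)[:, : source.n]  # coeffs = Linv @ targets
    grid = identity_grid(shape).reshape(-1, 2)
    d = np.linalg.norm(grid[:, None, :] - source.points[None, :, :], axis=-1)
    basis = np.concatenate(
        [tps_kernel(d), np.ones((grid.shape[0], 1)), grid], axis=1
    )  # (HW, N+3) ordered [kernel | 1 | x y] to match [W | c | A] rows
    return basis @ Linv


def resample(
    grid: np.ndarray,
    field: DenseDisplacementField,
    padding: Literal["border", "zeros"] = "border",
) -> np.ndarray:
    """Bilinearly sample a (..., H, W) array at identity + field locations.

    Accepts (H, W) or (C, H, W) arrays; all channels are sampled with the
    same field.  A zero field returns the input bit-exactly.
    """
    arr = np.asarray(grid, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if arr.shape[-2:] != field.shape:
        raise ValueError("field shape does not match grid spatial shape")
    if field.is_zero():
        out = arr.copy()
        return out[0] if squeeze else out
    sample_at = identity_grid(field.shape) + field.offsets
    out = grid_sample_np(arr[None], sample_at[None], padding)[0]
    return out[0] if squeeze else out


def save_field(field: DenseDisplacementField, path) -> None:
    """Serialize a field to NIfTI (``.nii``/``.nii.gz``, 2 channels) or to a
    compressed array (``.npz``) with a YAML sidecar noting the convention."""
    from pathlib import Path

    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(field.offsets[:, :, None, :], np.eye(4)), str(path))
    elif path.suffix == ".npz":
        import yaml

        np.savez_compressed(path, offsets=field.offsets)
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(
                {
                    "coordinate_convention": "normalized [-1,1], align-corners, "
                    "(x, y) channel order, displacement added to identity grid",
                    "shape": list(field.shape),
                },
                fh,
            )
    else:
        raise ValueError(f"unsupported field format: {path.name}")


def load_field(path) -> DenseDisplacementField:
    from pathlib import Path

    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return DenseDisplacementField(arr[:, :, 0, :])
    if path.suffix == ".npz":
        return DenseDisplacementField(np.load(path)["offsets"])
    raise ValueError(f"unsupported field format: {path.name}")


def compose(first: DenseDisplacementField, second: DenseDisplacementField) -> DenseDisplacementField:
    """Field of applying ``first`` then ``second``.

    With the displacement convention out(p) = in(p + d(p)), warping by
    ``first`` and then warping the result by ``second`` samples the original
    image at ``p + second(p) + first(p + second(p))``, so the composed
    displacement adds ``second`` to ``first`` sampled at the
    second-displaced locations.
    """
    if first.shape != second.shape:
        raise ValueError("fields must share a shape")
    first_chan = np.moveaxis(first.offsets, -1, 0)  # (2, H, W)
    first_at = resample(first_chan, second, padding="border")
    return DenseDisplacementField(second.offsets + np.moveaxis(first_at, 0, -1))
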