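"""Synthetic two-domain phantom data with known domain-specific deformations.

The generator emulates the study design used throughout the package's tests:
co-registered image pairs in two "contrasts" of the same anatomy (think
PD-/T2-weighted MR), where one domain is additionally warped by a known
nonlinear deformation — a global TPS perturbation of a regular control grid
composed with a smooth random local field.  The ground-truth field is stored
with each pair so that alignment and recovery are directly checkable.

Anatomy is 3-8 random ellipses and annuli on a dark background, which gives
both edges (for gradient-based measures) and broad intensity strata (for
histogram-based measures).  The two domains render the *same* geometry under
two distinct monotone intensity mappings plus independent additive noise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .tps import (
    ControlPointSet,
    DenseDisplacementField,
    fit_tps,
    regular_control_grid,
    resample,
    tps_displacement,
    compose,
)

__all__ = [
    "ImageSlice",
    "PhantomPair",
    "PhantomConfig",
    "DatasetManifest",
    "normalize",
    "generate_phantom_pair",
    "generate_phantom_dataset",
    "simulate_domain_deformation",
    "save_dataset",
    "load_dataset",
]


@dataclasses.dataclass
class ImageSlice:
    """A 2-D single-channel intensity grid with a domain label."""

    pixels: np.ndarray
    domain: Literal["A", "B"]
    spacing: Tuple[float, float] = (1.0, 1.0)
    id: str = ""
    patient: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if min(self.pixels.shape) < 16:
            raise ValueError("image sides must be at least 16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.domain not in ("A", "B"):
            raise ValueError("domain must be 'A' or 'B'")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "ImageSlice":
        return dataclasses.replace(self, pixels=normalize(self.pixels))


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-std intensity normalization."""
    pixels = np.asarray(pixels, dtype=float)
    std = pixels.std()
    if std == 0:
        raise ValueError("cannot normalize a constant image")
    return (pixels - pixels.mean()) / std


@dataclasses.dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    Deformation magnitudes are in normalized [-1, 1] coordinates: the default
    global jitter of 0.06 moves 6x6 TPS control points by ~2 px on a 64-px
    image, and the local field is white noise smoothed by a Gaussian of
    sigma = 8 px, scaled to an RMS of ``local_magnitude``.
    """

    n_shapes: Tuple[int, int] = (3, 8)
    noise_std: float = 0.03
    global_magnitude: float = 0.06
    translation_magnitude: float = 0.08
    local_magnitude: float = 0.02
    local_sigma_px: float = 8.0
    grid_side: int = 6
    # monotone intensity mappings per domain: gamma exponents on [0, 1]
    gamma_a: float = 0.7
    gamma_b: float = 1.8

    def validate(self) -> None:
        if self.n_shapes[0] < 1 or self.n_shapes[1] < self.n_shapes[0]:
            raise ValueError("invalid shape-count range")
        if min(self.noise_std, self.global_magnitude, self.local_magnitude,
               self.translation_magnitude) < 0:
            raise ValueError("magnitudes must be nonnegative")
        if self.grid_side < 2:
            raise ValueError("control grid side must be >= 2")


@dataclasses.dataclass
class PhantomPair:
    """A co-registered pair plus the deformed copy and its true field.

    ``control_points`` (the jittered TPS targets of the global part) and
    ``local_field`` are stored alongside the composed ``true_deformation`` so
    the field can be re-derived from its ingredients.
    """

    source: ImageSlice  # domain A
    target_aligned: ImageSlice  # domain B, co-registered with source
    target_deformed: ImageSlice  # domain B after the true deformation
    true_deformation: DenseDisplacementField
    seed: int
    control_points: Optional[ControlPointSet] = None
    local_field: Optional[DenseDisplacementField] = None


@dataclasses.dataclass
class DatasetManifest:
    entries: List[dict]
    format: Literal["NIfTI", "PNG"]
    root: str = "."

    def validate(self, base: Path) -> None:
        if not self.entries:
            raise ValueError("empty dataset")
        domains = {e["domain"] for e in self.entries}
        if not {"A", "B"} <= domains:
            raise ValueError("both domains must be present")
        for e in self.entries:
            if not (base / e["path"]).exists():
                raise FileNotFoundError(base / e["path"])


def _shape_stack(rng: np.random.Generator, size: Tuple[int, int], n_shapes: Tuple[int, int]) -> np.ndarray:
    """Random ellipses/annuli rendered as a smooth label-intensity image in [0, 1]."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    yy = (yy - (h - 1) / 2) / ((h - 1) / 2)
    xx = (xx - (w - 1) / 2) / ((w - 1) / 2)
    img = np.zeros(size)
    n = int(rng.integers(n_shapes[0], n_shapes[1] + 1))
    for _ in range(n):
        cx, cy = rng.uniform(-0.55, 0.55, size=2)
        rx, ry = rng.uniform(0.12, 0.45, size=2)
        theta = rng.uniform(0, np.pi)
        level = rng.uniform(0.25, 1.0)
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / rx
        v = (-(xx - cx) * st + (yy - cy) * ct) / ry
        r2 = u**2 + v**2
        if rng.random() < 0.4:  # annulus
            inner = rng.uniform(0.35, 0.7)
            mask = (r2 <= 1.0) & (r2 >= inner**2)
        else:
            mask = r2 <= 1.0
        img[mask] = level
    img = gaussian_filter(img, 1.0)
    peak = img.max()
    return img / peak if peak > 0 else img


def _render_domain(anatomy: np.ndarray, gamma: float, noise_std: float, rng: np.random.Generator) -> np.ndarray:
    out = np.power(np.clip(anatomy, 0.0, 1.0), gamma)
    return out + rng.normal(0.0, noise_std, size=out.shape)


def _random_deformation(
    rng: np.random.Generator,
    size: Tuple[int, int],
    global_magnitude: float,
    local_magnitude: float,
    local_sigma_px: float = 8.0,
    grid_side: int = 6,
    translation_magnitude: float = 0.0,
) -> Tuple[DenseDisplacementField, ControlPointSet]:
    """Global TPS (coherent shift + jittered control grid) composed with a
    smooth local field.

    The global part is a shared random translation of all control points
    (field-of-view / positioning offsets, the dominant systematic component
    of real domain-specific deformations) plus independent per-point jitter.
    """
    source = regular_control_grid(grid_side)
    shift = (
        rng.uniform(-translation_magnitude, translation_magnitude, size=(1, 2))
        if translation_magnitude > 0
        else np.zeros((1, 2))
    )
    jitter = rng.normal(0.0, global_magnitude, size=source.points.shape) if global_magnitude > 0 else 0.0
    target_pts = np.clip(source.points + shift + jitter, -1.0, 1.0)
    target = ControlPointSet(target_pts)
    if global_magnitude > 0 or translation_magnitude > 0:
        glob = tps_displacement(fit_tps(source, target), size)
    else:
        glob = DenseDisplacementField.zero(size)
    if local_magnitude > 0:
        noise = rng.normal(size=(size[0], size[1], 2))
        loc = np.stack(
            [gaussian_filter(noise[..., k], local_sigma_px) for k in range(2)], axis=-1
        )
        rms = np.sqrt(np.mean(loc**2))
        if rms > 0:
            loc *= local_magnitude / rms
        local = DenseDisplacementField(loc)
    else:
        local = DenseDisplacementField.zero(size)
    if local.is_zero():
        field = glob
    elif glob.is_zero():
        field = local
    else:
        field = compose(local, glob)  # local first, then the global warp
    return field, target, local


def simulate_domain_deformation(
    image: ImageSlice,
    seed: int,
    global_magnitude: float,
    local_magnitude: float,
    local_sigma_px: float = 8.0,
    grid_side: int = 6,
    padding: Literal["border", "zeros"] = "border",
) -> Tuple[ImageSlice, DenseDisplacementField]:
    """Warp ``image`` by a random domain deformation; return image and field."""
    if global_magnitude < 0 or local_magnitude < 0:
        raise ValueError("magnitudes must be nonnegative")
    rng = np.random.default_rng(seed)
    field, _, _ = _random_deformation(
        rng, image.shape, global_magnitude, local_magnitude, local_sigma_px, grid_side
    )
    warped = resample(image.pixels, field, padding=padding)
    return dataclasses.replace(image, pixels=warped), field


def generate_phantom_pair(
    seed: int,
    size: Tuple[int, int] = (128, 128),
    config: Optional[PhantomConfig] = None,
    deformation: Optional[tuple] = None,
) -> PhantomPair:
    """Generate one co-registered A/B pair plus the deformed B copy.

    Everything is a pure function of ``(seed, size, config)``; passing an
    explicit ``deformation`` lets a dataset share one domain-specific field
    across pairs.
    """
    config = config or PhantomConfig()
    config.validate()
    if size[0] < 32 or size[1] < 32:
        raise ValueError("phantom size must be at least 32x32")
    rng = np.random.default_rng(seed)
    anatomy = _shape_stack(rng, size, config.n_shapes)
    a = _render_domain(anatomy, config.gamma_a, config.noise_std, rng)
    b = _render_domain(anatomy, config.gamma_b, config.noise_std, rng)
    if deformation is None:
        field, ctrl, local = _random_deformation(
            rng,
            size,
            config.global_magnitude,
            config.local_magnitude,
            config.local_sigma_px,
            config.grid_side,
            config.translation_magnitude,
        )
    else:
        field, ctrl, local = deformation
    b_def = resample(b, field, padding="border")
    sid = f"phantom{seed:06d}"
    return PhantomPair(
        source=ImageSlice(a, "A", id=f"{sid}_A", patient=sid, slice_index=0),
        target_aligned=ImageSlice(b, "B", id=f"{sid}_B", patient=sid, slice_index=0),
        target_deformed=ImageSlice(b_def, "B", id=f"{sid}_Bdef", patient=sid, slice_index=0),
        true_deformation=field,
        seed=seed,
        control_points=ctrl,
        local_field=local,
    )


def generate_phantom_dataset(
    n_pairs: int,
    seed: int,
    size: Tuple[int, int] = (128, 128),
    config: Optional[PhantomConfig] = None,
    shared_deformation: bool = True,
) -> List[PhantomPair]:
    """A phantom cohort; by default all pairs share one domain deformation.

    A *domain-specific* deformation is systematic — every domain-B image is
    warped the same way — which is what lets an adversarial model learn (and
    wrongly reproduce) it.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    deformation = None
    if shared_deformation:
        deformation = _random_deformation(
            rng, size, config.global_magnitude, config.local_magnitude,
            config.local_sigma_px, config.grid_side, config.translation_magnitude,
        )
    child_seeds = rng.integers(0, 2**31 - 1, size=n_pairs)
    return [
        generate_phantom_pair(int(s), size, config, deformation) for s in child_seeds
    ]


# ---------------------------------------------------------------------------
# dataset I/O (PNG 16-bit with rescale metadata, or NIfTI), YAML manifest
# ---------------------------------------------------------------------------

_MANIFEST_NAME = "manifest.yaml"


def _write_image(path: Path, pixels: np.ndarray, fmt: str, spacing) -> dict:
    meta: dict = {}
    if fmt == "NIfTI":
        import nibabel as nib

        affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
        nib.save(nib.Nifti1Image(pixels[..., None].astype(np.float64), affine), str(path))
    elif fmt == "PNG":
        import imageio.v3 as iio

        lo, hi = float(pixels.min()), float(pixels.max())
        scale = hi - lo if hi > lo else 1.0
        q = np.round((pixels - lo) / scale * 65535.0).astype(np.uint16)
        iio.imwrite(str(path), q)
        meta = {"rescale_offset": lo, "rescale_slope": scale / 65535.0}
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return meta


def save_dataset(pairs: Sequence[PhantomPair], directory, fmt: Literal["NIfTI", "PNG"] = "NIfTI") -> DatasetManifest:
    """Write source/aligned/deformed images per pair and a YAML manifest."""
    if not pairs:
        raise ValueError("empty dataset")
    if fmt not in ("NIfTI", "PNG"):
        raise ValueError(f"unsupported format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if fmt == "NIfTI" else ".png"
    entries = []
    for pair in pairs:
        for role, img in (
            ("source", pair.source),
            ("target_aligned", pair.target_aligned),
            ("target_deformed", pair.target_deformed),
        ):
            name = f"{img.patient}_{role}{ext}"
            meta = _write_image(directory / name, img.pixels, fmt, img.spacing)
            entries.append(
                {
                    "path": name,
                    "domain": img.domain,
                    "patient": img.patient,
                    "slice_index": img.slice_index,
                    "role": role,
                    **meta,
                }
            )
    manifest = DatasetManifest(entries=entries, format=fmt)
    with open(directory / _MANIFEST_NAME, "w") as fh:
        yaml.safe_dump({"format": fmt, "entries": entries}, fh)
    return manifest


def load_dataset(manifest_path, normalize_images: bool = True) -> Tuple[List[ImageSlice], DatasetManifest]:
    """Load a saved dataset; slices are mean/std normalized unless disabled.

    NIfTI *volumes* are expanded into axial slices (one ImageSlice per plane
    of the third dimension).
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / _MANIFEST_NAME
    with open(manifest_path) as fh:
        raw = yaml.safe_load(fh)
    manifest = DatasetManifest(entries=raw["entries"], format=raw["format"])
    base = manifest_path.parent
    manifest.validate(base)
    slices: List[ImageSlice] = []
    for e in manifest.entries:
        path = base / e["path"]
        if manifest.format == "NIfTI":
            import nibabel as nib

            vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
            if vol.ndim == 2:
                vol = vol[..., None]
            planes = [vol[:, :, k] for k in range(vol.shape[2])]
        else:
            import imageio.v3 as iio

            q = iio.imread(str(path)).astype(float)
            planes = [q * e.get("rescale_slope", 1.0) + e.get("rescale_offset", 0.0)]
        for k, plane in enumerate(planes):
            pixels = normalize(plane) if normalize_images else plane
            slices.append(
                ImageSlice(
                    pixels,
                    e["domain"],
                    id=f"{e['path']}#{k}",
                    patient=e.get("patient", ""),
                    slice_index=e.get("slice_index", k),
                )
            )
    return slices, manifest
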