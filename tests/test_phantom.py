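"""Phantom generation determinism, ground-truth closure and dataset I/O."""

import numpy as np
import pytest

from dicyc.phantom import (
    ImageSlice,
    PhantomConfig,
    generate_phantom_dataset,
    generate_phantom_pair,
    load_dataset,
    normalize,
    save_dataset,
    simulate_domain_deformation,
)
from dicyc.tps import (
    ControlPointSet,
    compose,
    fit_tps,
    regular_control_grid,
    resample,
    tps_displacement,
)


class TestImageSlice:
    def test_rejects_tiny_and_nonfinite(self):
        with pytest.raises(ValueError):
            ImageSlice(np.zeros((8, 8)), "A")
        bad = np.zeros((32, 32))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            ImageSlice(bad, "A")

    def test_normalization_contract(self, rng):
        img = ImageSlice(rng.normal(2.0, 3.0, size=(32, 32)), "B").normalized()
        assert abs(img.pixels.mean()) < 1e-6
        assert abs(img.pixels.std() - 1.0) < 1e-6

    def test_constant_image_cannot_normalize(self):
        with pytest.raises(ValueError):
            normalize(np.full((16, 16), 2.0))


class TestGeneratePair:
    def test_zero_magnitudes_give_identity(self):
        cfg = PhantomConfig(global_magnitude=0.0, local_magnitude=0.0, translation_magnitude=0.0)
        pair = generate_phantom_pair(0, (64, 64), cfg)
        assert pair.true_deformation.is_zero()
        assert np.array_equal(pair.target_deformed.pixels, pair.target_aligned.pixels)

    def test_same_seed_is_bit_identical(self):
        a = generate_phantom_pair(3, (64, 64))
        b = generate_phantom_pair(3, (64, 64))
        assert np.array_equal(a.source.pixels, b.source.pixels)
        assert np.array_equal(a.target_deformed.pixels, b.target_deformed.pixels)
        assert np.array_equal(a.true_deformation.offsets, b.true_deformation.offsets)

    def test_different_seeds_differ(self):
        a = generate_phantom_pair(3, (64, 64))
        b = generate_phantom_pair(4, (64, 64))
        assert not np.array_equal(a.source.pixels, b.source.pixels)

    def test_stored_field_reconstructs_from_ingredients(self):
        """Mean absolute displacement matches a re-derivation of the stored
        global TPS targets composed with the stored local field."""
        pair = generate_phantom_pair(1, (64, 64))
        grid = regular_control_grid(6)
        glob = tps_displacement(fit_tps(grid, pair.control_points), (64, 64))
        rebuilt = compose(pair.local_field, glob)
        assert np.allclose(rebuilt.offsets, pair.true_deformation.offsets, atol=1e-12)
        assert pair.true_deformation.mean_abs_displacement() == pytest.approx(
            np.abs(rebuilt.offsets).mean(), abs=1e-12
        )

    def test_ground_truth_closure(self):
        pair = generate_phantom_pair(5, (64, 64))
        rewarped = resample(pair.target_aligned.pixels, pair.true_deformation, padding="border")
        assert np.array_equal(rewarped, pair.target_deformed.pixels)

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom_pair(0, (16, 16))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom_pair(0, (64, 64), PhantomConfig(noise_std=-1.0))


class TestSimulateDeformation:
    def test_zero_magnitudes_identity(self, smooth_image):
        img = ImageSlice(smooth_image, "B")
        warped, field = simulate_domain_deformation(img, 0, 0.0, 0.0)
        assert not np.any(field.offsets)
        assert np.array_equal(warped.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = ImageSlice(np.full((48, 48), 1.5), "B")
        warped, _ = simulate_domain_deformation(img, 1, 0.05, 0.02)
        assert np.allclose(warped.pixels, 1.5)

    def test_global_only_field_matches_tps_of_jittered_grid(self, smooth_image):
        """With no local component the returned field must be exactly the TPS
        displacement of the jittered control grid, recomputed independently."""
        img = ImageSlice(smooth_image, "B")
        seed = 11
        _, field = simulate_domain_deformation(img, seed, 0.05, 0.0)
        rng = np.random.default_rng(seed)
        grid = regular_control_grid(6)
        jitter = rng.normal(0.0, 0.05, size=grid.points.shape)
        tgt = ControlPointSet(np.clip(grid.points + np.zeros((1, 2)) + jitter, -1, 1))
        expected = tps_displacement(fit_tps(grid, tgt), (64, 64))
        assert np.allclose(field.offsets, expected.offsets, atol=1e-12)


class TestDatasetSharedDeformation:
    def test_all_pairs_share_one_domain_deformation(self):
        pairs = generate_phantom_dataset(3, 0, (64, 64))
        f0 = pairs[0].true_deformation.offsets
        assert all(np.array_equal(p.true_deformation.offsets, f0) for p in pairs[1:])

    def test_independent_deformations_when_disabled(self):
        pairs = generate_phantom_dataset(2, 0, (64, 64), shared_deformation=False)
        assert not np.array_equal(
            pairs[0].true_deformation.offsets, pairs[1].true_deformation.offsets
        )


class TestDatasetIO:
    @pytest.mark.parametrize("fmt,tol", [("NIfTI", 0.0), ("PNG", 1.01 / 65535)])
    def test_round_trip_within_quantization(self, tmp_path, fmt, tol):
        pairs = [generate_phantom_pair(s, (32, 32)) for s in (0, 1)]
        manifest = save_dataset(pairs, tmp_path / fmt, fmt)
        assert len(manifest.entries) == 6  # source, aligned, deformed per pair
        slices, _ = load_dataset(tmp_path / fmt, normalize_images=False)
        assert len(slices) == 6
        originals = [
            img.pixels
            for p in pairs
            for img in (p.source, p.target_aligned, p.target_deformed)
        ]
        for orig, loaded in zip(originals, slices):
            span = orig.max() - orig.min()
            assert np.abs(orig - loaded.pixels).max() <= tol * span + 1e-12

    def test_loaded_slices_are_normalized_by_default(self, tmp_path):
        pairs = [generate_phantom_pair(0, (32, 32))]
        save_dataset(pairs, tmp_path, "PNG")
        slices, _ = load_dataset(tmp_path)
        for s in slices:
            assert abs(s.pixels.mean()) < 1e-6
            assert abs(s.pixels.std() - 1.0) < 1e-6

    def test_empty_dataset_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty dataset"):
            save_dataset([], tmp_path, "NIfTI")

    def test_unsupported_format_rejected(self, tmp_path):
        pairs = [generate_phantom_pair(0, (32, 32))]
        with pytest.raises(ValueError):
            save_dataset(pairs, tmp_path, "TIFF")

    def test_nifti_volume_expands_to_header_slice_count(self, tmp_path, rng):
        import nibabel as nib
        import yaml

        vol = rng.normal(size=(24, 20, 5))
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(tmp_path / "vol.nii.gz"))
        with open(tmp_path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "format": "NIfTI",
                    "entries": [
                        {"path": "vol.nii.gz", "domain": "A", "patient": "p0", "slice_index": 0},
                        {"path": "vol.nii.gz", "domain": "B", "patient": "p0", "slice_index": 0},
                    ],
                },
                fh,
            )
        slices, _ = load_dataset(tmp_path / "manifest.yaml")
        assert len(slices) == 2 * vol.shape[2]

    def test_missing_file_raises(self, tmp_path):
        import yaml

        with open(tmp_path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "format": "PNG",
                    "entries": [
                        {"path": "nope.png", "domain": "A"},
                        {"path": "nope2.png", "domain": "B"},
                    ],
                },
                fh,
            )
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "manifest.yaml")
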