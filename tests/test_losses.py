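"""Loss terms, their oracles, and the structural gradient-separation claims."""

import numpy as np
import pytest

from dicyc._autograd import Tensor
from dicyc.losses import (
    LossWeights,
    alignment_loss,
    cycle_loss,
    dicyc_loss,
    gcc_alignment,
    gcc_alignment_t,
    get_alignment_measure,
    lsgan_discriminator_loss,
    lsgan_generator_loss,
    normalized_mutual_information,
    register_alignment_measure,
    soft_nmi,
    total_loss,
)
from dicyc.networks import forward_deformed, to_tensor
from dicyc.tps import DenseDisplacementField, resample


class TestLSGAN:
    def test_perfect_discriminator_scores_zero(self):
        assert lsgan_discriminator_loss(np.ones((1, 1, 4, 4)), np.zeros((1, 1, 4, 4))).item() == 0.0

    def test_maximally_wrong_discriminator_scores_one(self):
        assert lsgan_discriminator_loss(np.zeros((1, 1, 4, 4)), np.ones((1, 1, 4, 4))).item() == 1.0

    def test_generator_loss_closed_forms(self):
        assert lsgan_generator_loss(np.ones((2, 3))).item() == 0.0
        assert lsgan_generator_loss(np.zeros((2, 3))).item() == 1.0
        assert lsgan_generator_loss(np.full((2, 3), 0.5)).item() == pytest.approx(0.25)

    def test_random_maps_match_elementwise_oracle(self, rng):
        dr, df = rng.normal(size=(1, 1, 5, 5)), rng.normal(size=(1, 1, 5, 5))
        expected = 0.5 * np.mean((dr - 1) ** 2) + 0.5 * np.mean(df**2)
        assert lsgan_discriminator_loss(dr, df).item() == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lsgan_discriminator_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))


class TestNMI:
    def test_self_information_is_one(self, rng):
        x = rng.normal(size=(64, 64))
        assert normalized_mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_is_near_zero(self, rng):
        x = rng.uniform(size=(128, 128))
        y = rng.uniform(size=(128, 128))
        assert normalized_mutual_information(x, y, bins=64) < 0.05

    def test_monotone_transform_invariance_with_rank_bins(self, rng):
        x = rng.normal(size=(64, 64))
        fx = np.exp(1.7 * x) + 0.3 * x  # strictly monotone
        assert normalized_mutual_information(x, fx, binning="rank") == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_defined_as_zero_with_warning(self, rng):
        with pytest.warns(UserWarning):
            v = normalized_mutual_information(np.full((32, 32), 2.0), rng.normal(size=(32, 32)))
        assert v == 0.0

    def test_soft_nmi_in_unit_interval_and_orders_alignment(self, rng):
        x = rng.normal(size=(48, 48))
        noisy = x + 0.3 * rng.normal(size=(48, 48))
        unrelated = rng.normal(size=(48, 48))
        v_self = soft_nmi(Tensor(x), Tensor(x)).item()
        v_noisy = soft_nmi(Tensor(x), Tensor(noisy)).item()
        v_far = soft_nmi(Tensor(x), Tensor(unrelated)).item()
        assert 0.0 <= v_far < v_noisy < v_self <= 1.0

    def test_soft_nmi_is_differentiable(self, rng):
        from dicyc._autograd import Parameter

        x = Parameter(rng.normal(size=(16, 16)))
        y = rng.normal(size=(16, 16))
        soft_nmi(x, Tensor(y)).backward()
        assert x.grad is not None and np.any(x.grad)


class TestGCC:
    def test_self_and_inverted_self_are_one(self, smooth_image):
        assert gcc_alignment(smooth_image, smooth_image) == pytest.approx(1.0)
        assert gcc_alignment(smooth_image, 1.0 - smooth_image) == pytest.approx(1.0)

    def test_matches_direct_correlation_computation(self, rng):
        x, y = rng.normal(size=(32, 32)), rng.normal(size=(32, 32))
        gx, gy = np.gradient(x), np.gradient(y)

        def corr(a, b):
            a, b = a.ravel() - a.mean(), b.ravel() - b.mean()
            return abs(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        expected = 0.5 * (corr(gx[1], gy[1]) + corr(gx[0], gy[0]))
        assert gcc_alignment(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_gradient_image_is_zero_with_warning(self, rng):
        with pytest.warns(UserWarning):
            v = gcc_alignment(np.full((16, 16), 1.0), rng.normal(size=(16, 16)))
        assert v == 0.0

    def test_tensor_variant_close_to_numpy_on_smooth_images(self, rng):
        from scipy.ndimage import gaussian_filter

        x = gaussian_filter(rng.normal(size=(32, 32)), 2)
        y = gaussian_filter(rng.normal(size=(32, 32)), 2)
        v = gcc_alignment_t(Tensor(x), Tensor(y)).item()
        assert 0.0 <= v <= 1.0


class TestAlignmentLoss:
    def test_extremes_and_arithmetic(self):
        measured = []

        def fake_measure(vals):
            def m(a, b):
                return measured.pop(0)

            measured.extend(vals)
            return m

        x = np.zeros((16, 16))
        assert alignment_loss(x, x, x, x, measure=fake_measure([1.0, 1.0])) == 0.0
        assert alignment_loss(x, x, x, x, measure=fake_measure([0.0, 0.0])) == 2.0
        assert alignment_loss(x, x, x, x, measure=fake_measure([0.8, 0.6])) == pytest.approx(0.6)

    def test_out_of_range_measure_rejected(self):
        x = np.zeros((16, 16))
        with pytest.raises(ValueError):
            alignment_loss(x, x, x, x, measure=lambda a, b: 1.7)

    def test_plugin_registry(self):
        register_alignment_measure("mymeasure", lambda a, b: 0.5)
        assert get_alignment_measure("plugin:mymeasure")(None, None) == 0.5
        with pytest.raises(KeyError):
            get_alignment_measure("plugin:absent")
        with pytest.raises(KeyError):
            get_alignment_measure("nope")


class TestCycleLosses:
    def test_identity_generators_give_zero(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        y = rng.normal(size=(1, 1, 8, 8))
        assert cycle_loss(x, x, y, y).item() == 0.0
        assert dicyc_loss(x, x, y, y).item() == 0.0

    def test_constant_shift_closed_form(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        y = rng.normal(size=(1, 1, 8, 8))
        c = 0.4
        total = cycle_loss(x, x + 2 * c, y, y + 2 * c).item()
        assert total == pytest.approx(2 * abs(2 * c), abs=1e-12)

    def test_random_inputs_match_l1_oracle(self, rng):
        a, b, c, d = (rng.normal(size=(1, 1, 6, 6)) for _ in range(4))
        expected = np.abs(b - a).mean() + np.abs(d - c).mean()
        assert cycle_loss(a, b, c, d).item() == pytest.approx(expected, abs=1e-12)
        assert dicyc_loss(a, b, c, d).item() == pytest.approx(expected, abs=1e-12)

    def test_forward_field_then_numerical_inverse_round_trip(self, rng):
        """Warping by f then by an (iteratively inverted) f recovers a smooth
        image to interpolation tolerance — the deformed-cycle ideal case."""
        from scipy.ndimage import gaussian_filter

        h = w = 64
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.sin(2 * np.pi * xx / 90.0) * np.cos(2 * np.pi * yy / 110.0)
        win = np.outer(np.hanning(h), np.hanning(w))
        f = np.stack(
            [gaussian_filter(rng.normal(size=(h, w)), 10) * win for _ in range(2)], -1
        )
        f *= 0.05 / np.abs(f).max()
        field = DenseDisplacementField(f)
        # fixed-point inversion: g(p) = -f(p + g(p))
        g = -field.offsets.copy()
        for _ in range(20):
            g = -resample(np.moveaxis(field.offsets, -1, 0), DenseDisplacementField(g), "border")
            g = np.moveaxis(g, 0, -1)
        inv = DenseDisplacementField(g)
        round_trip = resample(resample(img, field), inv)
        loss = dicyc_loss(img[None, None], round_trip[None, None], img[None, None], round_trip[None, None])
        assert loss.item() < 2 * 1e-2


class TestTotalLoss:
    def test_all_zero_parts(self):
        bd = total_loss(0, 0, 0, 0, 0)
        assert bd.total == 0.0

    def test_printed_weights_identity(self):
        bd = total_loss(1, 1, 1, 1, 1, LossWeights())
        assert bd.total == pytest.approx(22.9)

    def test_identity_is_exact_arithmetic(self, rng):
        parts = rng.normal(size=5)
        w = LossWeights(3.0, 7.0, 0.25)
        bd = total_loss(*parts, w)
        assert bd.total == parts[0] + parts[1] + 0.25 * parts[2] + 3.0 * parts[3] + 7.0 * parts[4]

    def test_zero_align_weight_degenerates(self, rng):
        parts = rng.normal(size=5)
        bd = total_loss(*parts, LossWeights(10.0, 10.0, 0.0))
        assert bd.total == parts[0] + parts[1] + 10.0 * parts[3] + 10.0 * parts[4]

    def test_non_finite_part_named(self):
        with pytest.raises(FloatingPointError, match="cyc"):
            total_loss(0, 0, 0, np.inf, 0)


class TestGradientSeparation:
    """The structural resolution of the GAN/alignment gradient conflict."""

    def _dual(self, tiny_generator, tiny_transformer, rng):
        for conv in tiny_generator.encoder.offsets:
            conv.weight.data = rng.normal(0, 0.01, conv.weight.shape)
        tiny_transformer.fc2.bias.data = rng.normal(0, 0.1, tiny_transformer.fc2.bias.shape)
        x = rng.normal(size=(64, 64))
        z_opp = tiny_generator.encoder(to_tensor(rng.normal(size=(64, 64))))
        return forward_deformed(tiny_generator, tiny_transformer, x, z_opp), x

    def test_alignment_loss_has_zero_gradient_on_deformation_parameters(
        self, tiny_generator, tiny_transformer, rng
    ):
        res, x = self._dual(tiny_generator, tiny_transformer, rng)
        loss = alignment_loss(x, res.undeformed, x, res.undeformed, measure="nmi")
        loss.backward()
        for p in tiny_transformer.parameters():
            assert p.grad is None or not np.any(p.grad)
        for conv in tiny_generator.encoder.offsets:
            assert conv.weight.grad is None or not np.any(conv.weight.grad)

    def test_gan_loss_ignores_the_undeformed_output(
        self, tiny_generator, tiny_transformer, rng
    ):
        res, _ = self._dual(tiny_generator, tiny_transformer, rng)
        lsgan_generator_loss(res.deformed).backward()
        assert res.undeformed.grad is None  # never visited by backprop
        assert res.deformed.grad is not None
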