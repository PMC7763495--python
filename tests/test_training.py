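"""EM training mechanics: schedule, sampling, augmentation, freeze contracts,
determinism and checkpointing (all at desk scale)."""

import numpy as np
import pytest

from dicyc.losses import LossWeights
from dicyc.networks import GeneratorSpec, TransformerSpec
from dicyc.phantom import ImageSlice, PhantomConfig, generate_phantom_dataset
from dicyc.tps import DenseDisplacementField, identity_grid, resample
from dicyc.training import (
    AugmentRanges,
    TrainConfig,
    TrainState,
    TrainingSet,
    augment_affine,
    dataset_from_pairs,
    e_step,
    learning_rate,
    m_step,
    sample_minibatch,
    train,
)


def tiny_config(**kw) -> TrainConfig:
    base = dict(
        seed=0,
        lr=1e-3,
        epochs_fixed=1,
        epochs_decay=0,
        iterations_per_epoch=2,
        early_stop_tolerance=(99, 99),
        generator=GeneratorSpec(base_channels=8, resnet_blocks=1),
        transformer=TransformerSpec(reducer_channels=8, hidden=16),
        discriminator_channels=8,
        augment=None,
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def tiny_dataset():
    pairs = generate_phantom_dataset(4, 0, (32, 32), PhantomConfig())
    return dataset_from_pairs(pairs)


class TestSchedule:
    def test_fixed_then_linear_decay(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == 2e-4
        assert learning_rate(99, cfg) == 2e-4
        assert learning_rate(150, cfg) == pytest.approx(1e-4)
        assert learning_rate(199, cfg) == pytest.approx(2e-6)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            learning_rate(200, TrainConfig())


class TestAugment:
    def test_zero_ranges_are_identity(self, smooth_image):
        img = ImageSlice(smooth_image, "A")
        out = augment_affine(img, 0, AugmentRanges(0, 0, 0, 0, 0.0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_flip_is_involutive_mirror(self, smooth_image):
        img = ImageSlice(smooth_image, "A")
        ranges = AugmentRanges(0, 0, 0, 0, 1.0)
        once = augment_affine(img, 0, ranges)
        assert np.allclose(once.pixels, img.pixels[:, ::-1], atol=1e-12)
        twice = augment_affine(once, 0, ranges)
        assert np.allclose(twice.pixels, img.pixels, atol=1e-12)

    def test_pure_rotation_matches_closed_form_affine_field(self, smooth_image):
        img = ImageSlice(smooth_image, "A")
        seed = 5
        out = augment_affine(img, seed, AugmentRanges(0, 10.0, 0, 0, 0.0))
        rng = np.random.default_rng(seed)
        rng.uniform(-0, 0, size=2)  # translation draw
        theta = np.deg2rad(rng.uniform(-10.0, 10.0))
        ct, st = np.cos(theta), np.sin(theta)
        grid = identity_grid(img.shape)
        positions = grid @ np.array([[ct, -st], [st, ct]]).T
        oracle = resample(img.pixels, DenseDisplacementField(positions - grid), "border")
        assert np.allclose(out.pixels, oracle, atol=1e-10)

    def test_deterministic_in_seed(self, smooth_image):
        img = ImageSlice(smooth_image, "A")
        r = AugmentRanges()
        a = augment_affine(img, 9, r)
        b = augment_affine(img, 9, r)
        assert np.array_equal(a.pixels, b.pixels)


class TestSampling:
    def test_reproducible_given_seed(self, tiny_dataset):
        a = sample_minibatch(tiny_dataset, "random-patient-slice", np.random.default_rng(4))
        b = sample_minibatch(tiny_dataset, "random-patient-slice", np.random.default_rng(4))
        assert a[0][0].id == b[0][0].id and a[1][0].id == b[1][0].id

    def test_same_patient_strategy_contract(self):
        def mk(domain, pid, k):
            return ImageSlice(np.zeros((16, 16)) + k, domain, patient=pid, id=f"{pid}{domain}{k}")

        ds = TrainingSet(
            domain_a=[mk("A", p, k) for p in ("p0", "p1") for k in range(3)],
            domain_b=[mk("B", p, k) for p in ("p0", "p1") for k in range(3)],
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            ba, bb = sample_minibatch(ds, "same-patient-random-slice", rng, batch_size=2)
            assert {s.patient for s in ba} == {s.patient for s in bb}
            assert len({s.patient for s in ba}) == 1

    def test_patient_frequencies_near_uniform(self):
        def mk(domain, pid):
            return ImageSlice(np.zeros((16, 16)), domain, patient=pid, id=f"{pid}{domain}")

        n_pat = 5
        ds = TrainingSet(
            domain_a=[mk("A", f"p{k}") for k in range(n_pat)],
            domain_b=[mk("B", f"p{k}") for k in range(n_pat)],
        )
        rng = np.random.default_rng(1)
        counts = np.zeros(n_pat)
        draws = 6000
        for _ in range(draws):
            ba, _ = sample_minibatch(ds, "random-patient-slice", rng)
            counts[int(ba[0].patient[1:])] += 1
        p = 1.0 / n_pat
        sd = np.sqrt(draws * p * (1 - p))
        assert np.abs(counts - draws * p).max() < 3 * sd

    def test_unknown_strategy_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            sample_minibatch(tiny_dataset, "bogus", np.random.default_rng(0))


class TestEStep:
    def test_only_transformer_parameters_move(self, tiny_dataset):
        state = TrainState.initialize(tiny_config())
        batch = sample_minibatch(tiny_dataset, "random-patient-slice", state.rng)
        frozen = {
            name: [p.data.copy() for p in getattr(state, name).parameters()]
            for name in ("gen_ab", "gen_ba", "disc_a", "disc_b")
        }
        before_tr = [p.data.copy() for p in state.tr_ab.parameters()]
        state = e_step(state, batch)
        for name, params in frozen.items():
            for p, old in zip(getattr(state, name).parameters(), params):
                assert np.array_equal(p.data, old)
        moved = any(
            not np.array_equal(p.data, old)
            for p, old in zip(state.tr_ab.parameters(), before_tr)
        )
        assert moved

    def test_zero_lr_leaves_state_unchanged(self, tiny_dataset):
        cfg = tiny_config(lr=1e-30, transformer_lr_scale=0.0)
        state = TrainState.initialize(cfg)
        state.opt_tr.lr = 0.0
        batch = sample_minibatch(tiny_dataset, "random-patient-slice", state.rng)
        before = [p.data.copy() for p in state.tr_ab.parameters()]
        state = e_step(state, batch)
        for p, old in zip(state.tr_ab.parameters(), before):
            assert np.array_equal(p.data, old)


class TestMStep:
    def test_zero_lr_reports_losses_without_updates(self, tiny_dataset):
        state = TrainState.initialize(tiny_config())
        state.opt_gen.lr = 0.0
        state.opt_disc.lr = 0.0
        batch = sample_minibatch(tiny_dataset, "random-patient-slice", state.rng)
        before = [p.data.copy() for p in state.gen_ab.parameters()]
        state, breakdown = m_step(state, batch)
        assert np.isfinite(breakdown.total)
        for p, old in zip(state.gen_ab.parameters(), before):
            assert np.array_equal(p.data, old)

    def test_breakdown_satisfies_weighted_sum_identity(self, tiny_dataset):
        state = TrainState.initialize(tiny_config())
        batch = sample_minibatch(tiny_dataset, "random-patient-slice", state.rng)
        _, bd = m_step(state, batch)
        w = LossWeights()
        assert bd.total == bd.gan_AB + bd.gan_BA + w.lambda_align * bd.align + \
            w.lambda_cyc * bd.cyc + w.lambda_dicyc * bd.dicyc

    def test_determinism_from_same_checkpoint_and_seed(self, tiny_dataset, tmp_path):
        cfg = tiny_config(iterations_per_epoch=3)
        state = train(cfg, tiny_dataset)
        state.save(tmp_path / "ckpt.bin")

        def run(n):
            s = TrainState.load(tmp_path / "ckpt.bin")
            totals = []
            for _ in range(n):
                batch = sample_minibatch(tiny_dataset, cfg.sampling, s.rng)
                s = e_step(s, batch)
                s, bd = m_step(s, batch)
                totals.append(bd.total)
            return totals

        assert run(4) == run(4)


class TestTrainLoop:
    def test_zero_epochs_returns_initialized_state(self, tiny_dataset):
        cfg = tiny_config(epochs_fixed=0, epochs_decay=0)
        state = train(cfg, tiny_dataset)
        assert state.epoch == 0 and not state.loss_history

    def test_bookkeeping_rows_and_loss_log(self, tiny_dataset, tmp_path):
        cfg = tiny_config(epochs_fixed=2, iterations_per_epoch=2)
        state = train(cfg, tiny_dataset, out_dir=tmp_path)
        assert len(state.loss_history) == 4
        import pandas as pd

        df = pd.read_csv(tmp_path / "loss_log.csv")
        assert len(df) == 4
        for col in ("iteration", "epoch", "lr", "gan_AB", "gan_BA", "align", "cyc", "dicyc", "total"):
            assert col in df.columns

    def test_ablation_modes_disable_deformation_terms(self, tiny_dataset):
        for mode, expect_align in (("cyclegan", False), ("cyclegan+align", True)):
            cfg = tiny_config(mode=mode, iterations_per_epoch=1)
            state = train(cfg, tiny_dataset)
            row = state.loss_history[-1]
            assert row["dicyc"] == 0.0
            assert (row["align"] != 0.0) == expect_align

    def test_checkpoint_round_trip_restores_parameters_bitwise(self, tiny_dataset, tmp_path):
        cfg = tiny_config(iterations_per_epoch=2)
        state = train(cfg, tiny_dataset)
        state.save(tmp_path / "s.bin")
        loaded = TrainState.load(tmp_path / "s.bin")
        for name in ("gen_ab", "gen_ba", "tr_ab", "tr_ba", "disc_a", "disc_b"):
            for p, q in zip(getattr(state, name).parameters(), getattr(loaded, name).parameters()):
                assert np.array_equal(p.data, q.data)
        assert loaded.iteration == state.iteration
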