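"""EM-style training: E-steps fit the global transformers, M-steps fit the
synthesis (and discriminator) parameters through two forward passes.

Every iteration alternates an E-step and an M-step on a fresh unpaired
minibatch:

* **E-step** — one Adam step on the transformer parameters theta_T,global
  only, driven by the LSGAN generator terms on the deformed outputs plus the
  deformation-bearing cycle term (the only loss terms that depend on the
  global warp).  All other parameters are provably untouched.
* **M-step** — both forward passes for both directions, the full weighted
  objective, one generator-side step (encoder/decoder and offset convs) and
  one discriminator-side step against a 50-image historical fake pool.

A mode switch degenerates the trainer for ablations: ``cyclegan+align``
disables both deformation modules and the deformation cycle term (adversarial
terms then consume the only — undeformed — outputs), ``cyclegan`` drops the
alignment term as well.
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from ._autograd import Adam, Tensor
from .losses import (
    LossBreakdown,
    LossWeights,
    alignment_loss,
    cycle_loss,
    dicyc_loss,
    lsgan_discriminator_loss,
    lsgan_generator_loss,
)
from .networks import (
    Discriminator,
    Generator,
    GeneratorSpec,
    Transformer,
    TransformerSpec,
    build_discriminator,
    build_generator,
    build_transformer,
    global_warp_latent,
    to_tensor,
)
from .phantom import ImageSlice, PhantomPair
from .tps import DenseDisplacementField, identity_grid, resample, tps_basis

__all__ = [
    "AugmentRanges",
    "TrainConfig",
    "TrainState",
    "TrainingSet",
    "dataset_from_pairs",
    "augment_affine",
    "sample_minibatch",
    "learning_rate",
    "e_step",
    "m_step",
    "train",
]

Mode = Literal["dicyc", "cyclegan", "cyclegan+align"]


@dataclasses.dataclass
class AugmentRanges:
    """Random affine augmentation ranges (applied to generator inputs only)."""

    translation_px: float = 4.0
    rotation_deg: float = 5.0
    scale: float = 0.05
    shear: float = 0.03
    flip_prob: float = 0.5


@dataclasses.dataclass
class TrainConfig:
    lr: float = 2e-4
    epochs_fixed: int = 100
    epochs_decay: int = 100
    iterations_per_epoch: int = 6000
    batch_size: int = 1
    early_stop_tolerance: Tuple[int, int] = (10, 20)
    early_stop_delta: float = 1e-4
    seed: int = 0
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    sampling: Literal["random-patient-slice", "same-patient-random-slice"] = "random-patient-slice"
    augment: Optional[AugmentRanges] = dataclasses.field(default_factory=AugmentRanges)
    mode: Mode = "dicyc"
    align_measure: str = "nmi"
    generator: GeneratorSpec = dataclasses.field(default_factory=GeneratorSpec)
    transformer: TransformerSpec = dataclasses.field(default_factory=TransformerSpec)
    discriminator_channels: int = 64
    pool_size: int = 50
    # the E-step estimates a low-dimensional pose; its few parameters tolerate
    # (and benefit from) a larger step than the synthesis networks
    transformer_lr_scale: float = 10.0

    def __post_init__(self):
        if min(self.lr, self.iterations_per_epoch, self.batch_size) <= 0 and self.iterations_per_epoch != 0:
            raise ValueError("config values must be positive")
        if self.epochs_fixed < 0 or self.epochs_decay < 0:
            raise ValueError("epoch counts must be nonnegative")

    @property
    def total_epochs(self) -> int:
        return self.epochs_fixed + self.epochs_decay


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Constant for the first stage, then linear decay to zero."""
    if epoch < 0 or epoch >= config.total_epochs:
        raise ValueError("epoch out of schedule range")
    if epoch < config.epochs_fixed:
        return config.lr
    frac = (epoch - config.epochs_fixed) / config.epochs_decay
    return config.lr * (1.0 - frac)


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainingSet:
    domain_a: List[ImageSlice]
    domain_b: List[ImageSlice]

    def __post_init__(self):
        if not self.domain_a or not self.domain_b:
            raise ValueError("both domains must be non-empty")


def dataset_from_pairs(pairs: Sequence[PhantomPair], deformed_b: bool = True) -> TrainingSet:
    """Unpaired training set: domain-A sources vs (deformed) domain-B images.

    Slices are mean/std normalized, matching the preprocessing applied when
    loading saved datasets.
    """
    return TrainingSet(
        domain_a=[p.source.normalized() for p in pairs],
        domain_b=[
            (p.target_deformed if deformed_b else p.target_aligned).normalized()
            for p in pairs
        ],
    )


def sample_minibatch(
    dataset: TrainingSet,
    strategy: str,
    rng: np.random.Generator,
    batch_size: int = 1,
) -> Tuple[List[ImageSlice], List[ImageSlice]]:
    """Draw an unpaired minibatch per the sampling strategy."""
    if strategy == "random-patient-slice":
        ia = rng.integers(0, len(dataset.domain_a), size=batch_size)
        ib = rng.integers(0, len(dataset.domain_b), size=batch_size)
        return [dataset.domain_a[i] for i in ia], [dataset.domain_b[i] for i in ib]
    if strategy == "same-patient-random-slice":
        patients = sorted(
            {s.patient for s in dataset.domain_a} & {s.patient for s in dataset.domain_b}
        )
        if not patients:
            raise ValueError("no patient present in both domains")
        pid = patients[int(rng.integers(0, len(patients)))]
        cand_a = [s for s in dataset.domain_a if s.patient == pid]
        cand_b = [s for s in dataset.domain_b if s.patient == pid]
        ia = rng.integers(0, len(cand_a), size=batch_size)
        ib = rng.integers(0, len(cand_b), size=batch_size)
        return [cand_a[i] for i in ia], [cand_b[i] for i in ib]
    raise ValueError(f"unknown sampling strategy {strategy!r}")


def augment_affine(image: ImageSlice, seed: int, ranges: AugmentRanges) -> ImageSlice:
    """One random affine resampling (translate/rotate/scale/shear/flip)."""
    rng = np.random.default_rng(seed)
    h, w = image.shape
    t_px = rng.uniform(-ranges.translation_px, ranges.translation_px, size=2)
    theta = np.deg2rad(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg))
    scale = 1.0 + rng.uniform(-ranges.scale, ranges.scale)
    shear = rng.uniform(-ranges.shear, ranges.shear)
    flip = rng.random() < ranges.flip_prob
    ct, st = np.cos(theta), np.sin(theta)
    mat = np.array([[ct, -st], [st, ct]]) @ np.array([[1.0, shear], [0.0, 1.0]]) * scale
    if flip:
        mat = mat @ np.diag([-1.0, 1.0])
    # normalized translation (x uses W, y uses H)
    t = np.array([2.0 * t_px[0] / max(w - 1, 1), 2.0 * t_px[1] / max(h - 1, 1)])
    grid = identity_grid((h, w))
    positions = grid @ mat.T + t
    field = DenseDisplacementField(positions - grid)
    return dataclasses.replace(image, pixels=resample(image.pixels, field, padding="border"))


# ---------------------------------------------------------------------------
# training state
# ---------------------------------------------------------------------------

class FakePool:
    """CycleGAN-style history buffer of generated images for the D update."""

    def __init__(self, size: int):
        self.size = size
        self.images: List[np.ndarray] = []

    def query(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if rng.random() < 0.5:
            idx = int(rng.integers(0, self.size))
            out = self.images[idx]
            self.images[idx] = image.copy()
            return out
        return image


@dataclasses.dataclass
class TrainState:
    config: TrainConfig
    gen_ab: Generator
    gen_ba: Generator
    tr_ab: Transformer
    tr_ba: Transformer
    disc_a: Discriminator
    disc_b: Discriminator
    opt_gen: Adam
    opt_disc: Adam
    opt_tr: Adam
    rng: np.random.Generator
    epoch: int = 0
    iteration: int = 0
    loss_history: List[dict] = dataclasses.field(default_factory=list)
    pool_a: FakePool = dataclasses.field(default_factory=lambda: FakePool(50))
    pool_b: FakePool = dataclasses.field(default_factory=lambda: FakePool(50))
    _basis_cache: Dict[Tuple[int, int], np.ndarray] = dataclasses.field(default_factory=dict)

    @classmethod
    def initialize(cls, config: TrainConfig) -> "TrainState":
        seed = config.seed
        gen_ab = build_generator(config.generator, seed=seed)
        gen_ba = build_generator(config.generator, seed=seed + 1)
        tr_ab = build_transformer(config.transformer, config.generator.latent_channels, seed=seed + 2)
        tr_ba = build_transformer(config.transformer, config.generator.latent_channels, seed=seed + 3)
        disc_a = build_discriminator(config.generator.in_channels, config.discriminator_channels, seed=seed + 4)
        disc_b = build_discriminator(config.generator.in_channels, config.discriminator_channels, seed=seed + 5)
        opt_gen = Adam(gen_ab.parameters() + gen_ba.parameters(), lr=config.lr)
        opt_disc = Adam(disc_a.parameters() + disc_b.parameters(), lr=config.lr)
        opt_tr = Adam(
            tr_ab.parameters() + tr_ba.parameters(),
            lr=config.lr * config.transformer_lr_scale,
        )
        return cls(
            config=config,
            gen_ab=gen_ab,
            gen_ba=gen_ba,
            tr_ab=tr_ab,
            tr_ba=tr_ba,
            disc_a=disc_a,
            disc_b=disc_b,
            opt_gen=opt_gen,
            opt_disc=opt_disc,
            opt_tr=opt_tr,
            rng=np.random.default_rng(seed),
            pool_a=FakePool(config.pool_size),
            pool_b=FakePool(config.pool_size),
        )

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "config": self.config,
            "epoch": self.epoch,
            "iteration": self.iteration,
            "loss_history": self.loss_history,
            "rng": self.rng,
            "nets": {
                name: getattr(self, name).state_dict()
                for name in ("gen_ab", "gen_ba", "tr_ab", "tr_ba", "disc_a", "disc_b")
            },
            "opts": {
                name: getattr(self, name).state_dict()
                for name in ("opt_gen", "opt_disc", "opt_tr")
            },
            "pools": (self.pool_a.images, self.pool_b.images),
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainState":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        state = cls.initialize(payload["config"])
        for name, sd in payload["nets"].items():
            getattr(state, name).load_state_dict(sd)
        for name, sd in payload["opts"].items():
            getattr(state, name).load_state_dict(sd)
        state.epoch = payload["epoch"]
        state.iteration = payload["iteration"]
        state.loss_history = payload["loss_history"]
        state.rng = payload["rng"]
        state.pool_a.images, state.pool_b.images = payload["pools"]
        return state

    def _basis(self, shape: Tuple[int, int]) -> np.ndarray:
        if shape not in self._basis_cache:
            self._basis_cache[shape] = tps_basis(self.tr_ab.grid, shape)
        return self._basis_cache[shape]

    def _zero_all_grads(self) -> None:
        for m in (self.gen_ab, self.gen_ba, self.tr_ab, self.tr_ba, self.disc_a, self.disc_b):
            m.zero_grad()


def _deformed_pass(state: TrainState, gen: Generator, tr: Transformer, x: Tensor, latent_opp: Tensor):
    fields: list = []
    z_t = gen.encoder(x, deformed=True, record=fields)
    points = tr(z_t, latent_opp)
    basis = state._basis((z_t.shape[2], z_t.shape[3]))
    warped, _ = global_warp_latent(z_t, points, tr.grid, basis)
    return gen.decoder(warped), points, fields


def e_step(state: TrainState, batch: Tuple[List[ImageSlice], List[ImageSlice]]) -> TrainState:
    """One transformer-only update (no-op outside ``dicyc`` mode)."""
    if state.config.mode != "dicyc":
        return state
    xa = to_tensor(batch[0][0])
    xb = to_tensor(batch[1][0])
    state._zero_all_grads()
    z_a = state.gen_ab.encoder(xa)
    z_b = state.gen_ba.encoder(xb)
    synth_b_t, _, _ = _deformed_pass(state, state.gen_ab, state.tr_ab, xa, z_b)
    synth_a_t, _, _ = _deformed_pass(state, state.gen_ba, state.tr_ba, xb, z_a)
    cycled_a_t, _, _ = _deformed_pass(state, state.gen_ba, state.tr_ba, synth_b_t, z_a)
    cycled_b_t, _, _ = _deformed_pass(state, state.gen_ab, state.tr_ab, synth_a_t, z_b)
    loss = (
        lsgan_generator_loss(state.disc_b(synth_b_t))
        + lsgan_generator_loss(state.disc_a(synth_a_t))
        + state.config.weights.lambda_dicyc * dicyc_loss(xa, cycled_a_t, xb, cycled_b_t)
    )
    loss.backward()
    state.opt_tr.step()
    state._zero_all_grads()
    return state


def m_step(
    state: TrainState,
    batch: Tuple[List[ImageSlice], List[ImageSlice]],
    real_batch: Optional[Tuple[List[ImageSlice], List[ImageSlice]]] = None,
) -> Tuple[TrainState, LossBreakdown]:
    """Both forward passes, the full objective, one G step and one D step.

    ``batch`` feeds the generators (possibly augmented); ``real_batch``, when
    given, supplies the unaugmented real images shown to the discriminators.
    """
    cfg = state.config
    xa = to_tensor(batch[0][0])
    xb = to_tensor(batch[1][0])
    real_a = to_tensor(real_batch[0][0]) if real_batch is not None else xa
    real_b = to_tensor(real_batch[1][0]) if real_batch is not None else xb
    deformed = cfg.mode == "dicyc"
    state._zero_all_grads()

    # undeformed passes (latents reused by the transformers and the cycles)
    z_a = state.gen_ab.encoder(xa)
    z_b = state.gen_ba.encoder(xb)
    synth_b_u = state.gen_ab.decoder(z_a)
    synth_a_u = state.gen_ba.decoder(z_b)
    cycled_a = state.gen_ba(synth_b_u)
    cycled_b = state.gen_ab(synth_a_u)
    cyc = cycle_loss(xa, cycled_a, xb, cycled_b)

    if deformed:
        synth_b_t, _, _ = _deformed_pass(state, state.gen_ab, state.tr_ab, xa, z_b)
        synth_a_t, _, _ = _deformed_pass(state, state.gen_ba, state.tr_ba, xb, z_a)
        cycled_a_t, _, _ = _deformed_pass(state, state.gen_ba, state.tr_ba, synth_b_t, z_a)
        cycled_b_t, _, _ = _deformed_pass(state, state.gen_ab, state.tr_ab, synth_a_t, z_b)
        dcy = dicyc_loss(xa, cycled_a_t, xb, cycled_b_t)
        fake_b, fake_a = synth_b_t, synth_a_t
    else:
        dcy = Tensor(0.0)
        fake_b, fake_a = synth_b_u, synth_a_u

    gan_ab = lsgan_generator_loss(state.disc_b(fake_b))
    gan_ba = lsgan_generator_loss(state.disc_a(fake_a))

    if cfg.mode in ("dicyc", "cyclegan+align"):
        align = alignment_loss(xa, synth_b_u, xb, synth_a_u, measure=cfg.align_measure)
    else:
        align = Tensor(0.0)

    lam = cfg.weights
    gen_total = (
        gan_ab
        + gan_ba
        + lam.lambda_align * align
        + lam.lambda_cyc * cyc
        + (lam.lambda_dicyc * dcy if deformed else Tensor(0.0))
    )
    breakdown = LossBreakdown.assemble(
        gan_ab, gan_ba, align, cyc, dcy,
        LossWeights(lam.lambda_cyc, lam.lambda_dicyc if deformed else 0.0, lam.lambda_align),
    )
    gen_total.backward()
    # the E-step owns theta_T,global: discard any transformer gradient here
    for p in state.opt_tr.params:
        p.grad = None
    state.opt_gen.step()
    state._zero_all_grads()

    # discriminators: real vs pooled detached fakes
    pb = state.pool_b.query(fake_b.data, state.rng)
    pa = state.pool_a.query(fake_a.data, state.rng)
    d_loss = lsgan_discriminator_loss(state.disc_b(real_b), state.disc_b(Tensor(pb))) + \
        lsgan_discriminator_loss(state.disc_a(real_a), state.disc_a(Tensor(pa)))
    d_loss.backward()
    state.opt_disc.step()
    state._zero_all_grads()
    return state, breakdown


def train(
    config: TrainConfig,
    dataset: TrainingSet,
    out_dir: Optional[Path] = None,
    checkpoint_every: int = 0,
    monitor=None,
) -> TrainState:
    """Full loop: E/M alternation, LR schedule, two-phase early stopping.

    ``monitor(state, epoch)`` is called after each epoch (used by the
    evaluation harness to track alignment on held-out pairs).
    """
    state = TrainState.initialize(config)
    out_dir = Path(out_dir) if out_dir is not None else None
    epoch_means: List[float] = []
    best = np.inf
    stall = 0
    phase = 0  # 0 = fixed LR, 1 = decaying LR
    epoch = 0
    sched_epoch = 0  # position in the nominal 2-stage schedule
    while epoch < config.total_epochs and sched_epoch < config.total_epochs:
        lr = learning_rate(sched_epoch, config)
        state.opt_gen.lr = lr
        state.opt_disc.lr = lr
        state.opt_tr.lr = lr * config.transformer_lr_scale
        totals = []
        for _ in range(config.iterations_per_epoch):
            raw_batch = sample_minibatch(dataset, config.sampling, state.rng, config.batch_size)
            batch = raw_batch
            if config.augment is not None:
                aug_seed = int(state.rng.integers(0, 2**31 - 1))
                batch = (
                    [augment_affine(s, aug_seed + k, config.augment) for k, s in enumerate(raw_batch[0])],
                    [augment_affine(s, aug_seed + 10_000 + k, config.augment) for k, s in enumerate(raw_batch[1])],
                )
            state = e_step(state, batch)
            state, breakdown = m_step(state, batch, real_batch=raw_batch)
            state.iteration += 1
            totals.append(breakdown.total)
            state.loss_history.append(
                {
                    "iteration": state.iteration,
                    "epoch": epoch,
                    "lr": lr,
                    **dataclasses.asdict(breakdown),
                }
            )
        epoch += 1
        sched_epoch += 1
        state.epoch = epoch
        if totals:
            mean_total = float(np.mean(totals))
            epoch_means.append(mean_total)
            if mean_total < best - config.early_stop_delta:
                best = mean_total
                stall = 0
            else:
                stall += 1
            tol = config.early_stop_tolerance[phase]
            if stall >= tol:
                if phase == 0:
                    phase = 1
                    sched_epoch = max(sched_epoch, config.epochs_fixed)
                    best = mean_total
                    stall = 0
                else:
                    break
        if phase == 0 and sched_epoch >= config.epochs_fixed:
            phase = 1
        if monitor is not None:
            monitor(state, epoch - 1)
        if out_dir is not None and checkpoint_every and epoch % checkpoint_every == 0:
            state.save(out_dir / "ckpt" / f"epoch_{epoch}.bin")
    if out_dir is not None:
        write_loss_log(state, out_dir / "loss_log.csv")
    return state


def write_loss_log(state: TrainState, path) -> None:
    import pandas as pd

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(state.loss_history).to_csv(path, index=False)
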