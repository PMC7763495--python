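# Methods

## Problem and model

Unpaired cross-domain medical image synthesis (e.g. MR contrast A to MR
contrast B, or MR to CT) is usually attacked with a cycle-consistent GAN: two
generators `M_A→B`, `M_B→A`, two patch discriminators, and an L1 round-trip
penalty. When the two domains differ by a *systematic geometric deformation*
— bed shape, field of view, slice planning — the discriminator learns that
deformation as a domain feature, and the adversarial loss rewards generators
that reproduce it. Any image-similarity alignment loss added between source
and output then pulls the same parameters in the opposite direction: the
adversarial term wants the output deformed like the target domain, the
alignment term wants it aligned with the source. The result is a forced
trade-off between signal quality and alignment.

This package implements a deformation-invariant variant that removes the
conflict *structurally* rather than by re-weighting. Each generator is split
into an encoder `F`, a decoder `G`, and a spatial transformer `T`, and every
training input produces **two** outputs:

* the **undeformed** output `x̂ = G(F(x))` — the pure appearance
  translation, evaluated only by the alignment loss (and the plain cycle
  loss);
* the **deformed** output `x̂_T = G(F_T(x) ∘ φ_global)` — the encoder run
  with learned local offset fields, its latent warped by a global
  thin-plate-spline field, then decoded; only this output is shown to the
  discriminators (and used in the deformation-bearing cycle loss).

Because the deformation lives in a separate parameter set
`θ_T = {θ_T,global, θ_T,local}`, the alignment loss has *identically zero*
gradient with respect to it, and the adversarial loss never sees the
undeformed pass. Both claims are asserted as tests, not just argued.

At prediction time only the undeformed pass runs; the deformation modules
are training-time machinery.

### Global deformation: thin-plate spline

The global warp is parameterized by a regular 6×6 control grid on the
normalized square [−1, 1]² (36 points). A small head (two stride-2 3×3 convs
per latent branch, concatenation, global average pooling, one hidden dense
layer, a zero-initialized output layer) regresses target coordinates for the
grid from the concatenated latents of the two translation directions. The
dense warp is the TPS interpolant `Φ(t) = c + A t + Wᵀ s(t)` with kernel
`δ(r) = r² ln r` (δ(0) = 0 by continuity), solved with the standard side
conditions so exactly affine correspondences produce `W = 0`.

Two practical consequences of the TPS algebra are used heavily:

* the system matrix depends only on the *source* grid, so the dense warped
  positions are **linear** in the predicted target points — one precomputed
  `(H·W) × 36` matrix turns the warp into a single matmul, which keeps it
  trivially differentiable;
* the transformer output is `clip(grid + 0.5·tanh(raw), −1, 1)`: exactly the
  regular grid (identity warp) at initialization, hard-bounded to the square.
  The tanh bound and the clip cannot both be active and exact at the grid
  corners; we accept that a bounded head cannot represent warps that push
  corner points outside the image.

### Local deformation: modified deformable convolution

The original deformable convolution learns `2N` offset maps — an independent
(x, y) displacement per input channel. Here the offset convolution emits
exactly **one** shared 2-D field used to bilinearly resample *all* channels
(equivalent to warping the input image and passing it forward), which costs
`(k²·C_in + 1)·2` parameters per insertion point — 1/N of the original.
Offset convolutions sit at four points: before the input convolution, before
each downsampling convolution, and before the residual stack. They are
zero-initialized, so training starts from the identity deformation and the
whole encoder degenerates bit-exactly to the plain CycleGAN encoder when the
offsets are zero.

### Losses

With LSGAN realizations of the adversarial terms, the total objective is

    L = L_GAN(A→B) + L_GAN(B→A) + λ_align·L_align + λ_cyc·L_cyc + λ_dicyc·L_dicyc

with λ_cyc = λ_dicyc = 10 and λ_align = 0.9. `L_align` is
`2 − NMI(x_A, x̂_B) − NMI(x_B, x̂_A)` on the *undeformed* outputs, where NMI
is normalized as `2·I(X;Y)/(H(X)+H(Y)) ∈ [0, 1]` — this normalization (not
the [1, 2]-ranged variant) is what makes the constant 2 give a loss with
minimum 0. `L_cyc` is the usual L1 round trip through the undeformed passes;
`L_dicyc` is the same functional form through the deformed passes. The
cross-entropy adversarial forms are available behind a flag.

**Differentiable NMI.** For the loss, the joint histogram is estimated by
Parzen soft-binning: intensities standardized (statistics detached), clipped
to ±3σ, spread over 32 Gaussian kernels with bandwidth 1.5 bin widths. For
evaluation, a hard 64-bin joint histogram is used; a rank-binning option
makes the hard estimate exactly invariant under strictly monotone intensity
transforms. A constant image has zero entropy; NMI is defined as 0 there,
with a warning.

The alignment measure is pluggable (`nmi`, `gcc`, or a registered plugin).
GCC — mean absolute Pearson correlation of horizontal and vertical gradient
images — is implemented for the ablation harness; descriptor-based measures
(e.g. MIND) can be registered through the plugin slot but are not shipped.

### Training: E/M alternation

Each iteration alternates:

* **E-step** — one Adam step on the transformer parameters θ_T,global only,
  under the only loss terms that depend on them: the LSGAN generator terms on
  the deformed outputs plus λ_dicyc·L_dicyc. All other parameters are
  bitwise untouched (asserted).
* **M-step** — both forward passes for both directions, the full objective,
  one step on the synthesis parameters (encoders, decoders, offset convs),
  then one discriminator step against a 50-image historical fake pool.

Inherited defaults: Adam β = (0.5, 0.999), batch size 1, lr 2·10⁻⁴ fixed for
100 epochs then linearly decayed to zero over 100 more, 6000 iterations per
epoch, random affine augmentation (translation/rotation/scale/shear/flip) of
generator inputs only. Early stopping is two-phase: when the epoch-mean
total loss fails to improve its running minimum by more than 10⁻⁴ for 10
epochs the schedule jumps to the decay stage; in the decay stage the same
rule with a 20-epoch tolerance ends training.

**Transformer learning rate.** The transformer optimizer runs at 10× the
synthesis learning rate (`transformer_lr_scale`). The pose head has ~2·10⁴
parameters against millions in the synthesis path and a much smoother
objective; at 1× it absorbs a known translation so slowly that the conflict
the architecture is meant to remove persists for hundreds of iterations.
This is a deliberate asymmetry of the E/M split: pose estimation is cheap
and should converge faster than appearance.

## Numerical core

The networks, losses and training run on a compact reverse-mode automatic
differentiation engine written on NumPy (`dicyc._autograd`): broadcasted
arithmetic, matmul, reductions, slicing/concatenation, reflection/zero
padding, strided 2-D convolution and transposed convolution (im2col with
einsum), instance normalization (composed from primitives), differentiable
bilinear grid sampling with border/zeros padding, and Adam. Everything is
float64. All operator gradients are verified against central finite
differences in the test suite.

Two numerical conventions matter:

* coordinates are normalized to [−1, 1] with pixel centers at the endpoints
  (align-corners); fields are *displacements* added to the identity grid, so
  the zero field is the identity and translations compose additively;
* pixel coordinates within 10⁻⁹ of a pixel center are snapped onto it inside
  the sampler, which makes identity resampling (zero field, identity TPS up
  to solver round-off) **bit-exact** — this is what turns the degeneration
  claims ("offsets zero ⇒ plain CycleGAN") into exact equalities rather than
  approximations.

Composition `compose(f, g)` returns the field of applying `f` then `g`:
`c(p) = g(p) + f(p + g(p))`, verified against sequential resampling.

## Synthetic phantom data

The phantom generator emulates the simulated-deformation study design:
3–8 random ellipses/annuli on a dark background rendered under two distinct
monotone intensity mappings (gamma 0.7 vs 1.8) plus independent Gaussian
noise (σ = 0.03 of the intensity range), giving both edges and intensity
strata for gradient- and histogram-based measures. Domain B is additionally
warped by a known deformation stored with the pair:

* **global**: a coherent random translation of all control points (uniform,
  ±0.08 by default — field-of-view/positioning offsets are the dominant
  systematic component of real domain-specific deformations) plus
  independent per-point jitter (σ = 0.06), interpolated by the same 6×6 TPS;
* **local**: white noise smoothed by a Gaussian of σ = 8 px, scaled to an
  RMS of 0.02 normalized units.

By default every pair in a dataset shares one deformation — a
*domain-specific* deformation is systematic, which is exactly what lets an
adversarial model learn and wrongly reproduce it. Generation is a pure
function of (seed, size, config); warping the stored aligned image by the
stored field reproduces the stored deformed image bit-exactly.

What the phantoms do **not** emulate: anatomy with long-range structure,
bias fields, partial-volume effects, modality-specific noise statistics, or
inter-subject variability. Tests passing on phantoms show the mechanics of
the method — gradient separation, deformation absorption, loss dynamics —
not clinical image quality.

## Desk-scale experiments

Full-scale training (128×128 images, 64-channel generators, 200 × 6000
iterations) is far beyond a CPU-only NumPy stack, so the two behavioral
studies run at reduced size, chosen once: 32×32 phantoms whose deformation
matches the full-size defaults *in pixels* (coherent translation 0.25
normalized ≈ 4 px, jitter 0.06, local 0.02), thin networks (base 8 channels,
2 residual blocks, 8-channel discriminator, 16-channel transformer reducer),
lr 10⁻³, no augmentation.

* **Alignment-loss evolution** (6 epochs × 50 iterations × 3 seeds): under
  the full model the epoch-mean alignment loss decreases monotonically;
  under the ablated CycleGAN+alignment counterpart it reaches its minimum in
  an early epoch and then rebounds as the generator learns to reproduce the
  domain shift. A phase-correlation probe confirms the mechanism: the
  ablated generator's output is displaced by roughly the true translation,
  the full model's undeformed output is not.
* **E-step recovery** (200 warm-up iterations, then 200 recorded E-steps at
  the standard lr 2·10⁻⁴): after warm-up the adversarial objective, scanned
  along the translation axis, has its minimum at the true shift; with the
  transformers re-initialized to the identity, repeated E-steps move the
  mean predicted control-point displacement monotonically toward the truth.
  The recovered magnitude underestimates the truth (bilinear sampling only
  provides gradient within ~1 px, and the bounded control points cannot
  represent a pure translation exactly), so the check is directional — the
  trajectory climbs toward the true displacement — not metric. The effect
  size depends on how position-sensitive the warmed-up discriminator happens
  to be: across warm-up seeds the step-index correlation ranges from
  strongly positive to a small noise-scale drift, so the test pins one
  documented seed as its study condition.

## Known limitations

* 2-D slices only; single-channel (grayscale) images throughout.
* The TPS head cannot represent warps pushing corner control points outside
  [−1, 1]²; large coherent shifts are recovered in direction but compressed
  in magnitude.
* Bilinear sampling limits the E-step's gradient horizon to about a pixel;
  large deformations are absorbed gradually over training, not in one jump.
* Instance normalization couples border bands into global statistics, so
  latent-space warps equal image-space warps only away from borders and
  exactly only for norm-free stacks (this bounds what "the warp commutes
  with decoding" can mean for this architecture).
* The NumPy engine is single-threaded apart from BLAS; it is sized for the
  desk-scale studies and tests, not for full-resolution training.
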