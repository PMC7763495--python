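# dicyc

Deformation-invariant cycle-consistent GAN for unpaired cross-domain medical
image synthesis — written for researchers who need synthesized images (e.g.
pseudo-CT from MR, or one MR contrast from another) that stay *aligned with
the source*, even when the training domains differ by a systematic geometric
deformation (bed shape, field of view, slice planning).

## The problem and the model

A CycleGAN trained on two such domains learns the relative deformation as a
domain feature and reproduces it in its output. Adding an image alignment
loss does not fix this: for generator parameters θ, the adversarial loss
rewards the deformed-looking output while the alignment loss punishes it —
`sgn ∇_θ L_GAN ≠ sgn ∇_θ L_align` — so quality and alignment trade off.

This model removes the conflict structurally. Each generator is split into
encoder `F`, decoder `G` and a TPS spatial transformer `T`, with the
deformation in its own parameters `θ_T = {θ_T,global, θ_T,local}`:

* undeformed pass  `x̂_B = G(F(x_A))` — scored by the alignment loss
  `L_align = 2 − NMI(x_A, x̂_B) − NMI(x_B, x̂_A)`, NMI ∈ [0, 1];
* deformed pass  `x̂_T,B = G(F_T(x_A) ∘ φ_global)` — the only output the
  discriminators see. `φ_global` is a thin-plate-spline warp of a regular
  6×6 control grid regressed by `T`; `F_T` uses modified deformable
  convolutions whose offset convolution emits **one** shared 2-D field for
  all channels.

The objective is

    L = L_GAN(A→B) + L_GAN(B→A) + 0.9·L_align + 10·L_cyc + 10·L_dicyc

where `L_dicyc` is the L1 round trip through the deformed passes. Training
alternates an E-step (transformer only) with an M-step (synthesis and
discriminator parameters) every iteration. At prediction time only the
undeformed pass runs.

Everything runs on a small NumPy reverse-mode autodiff engine included in
the package (`dicyc._autograd`) — no deep-learning framework required.

## Worked example

Generate a phantom cohort whose domain B carries a known systematic
deformation (~4 px coherent shift + TPS jitter + smooth local field), train
the desk-scale model, and check what the alignment loss did:

```python
import numpy as np, pandas as pd
from dicyc.experiments import desk_scale_phantoms, desk_scale_config
from dicyc.training import dataset_from_pairs, train

pairs = desk_scale_phantoms(seed=100)          # 8 pairs, 32x32
state = train(desk_scale_config(0, "dicyc", epochs=6, iterations=50),
              dataset_from_pairs(pairs))
df = pd.DataFrame(state.loss_history)
print(np.round(df.groupby("epoch")["align"].mean().to_numpy(), 4))
```

prints the epoch-mean alignment loss series

```
[1.8907 1.7761 1.722  1.7075 1.6912 1.6724]
```

— monotonically decreasing: the transformer absorbs the domain shift, so the
undeformed output keeps improving its mutual information with the source.
Running the same data with `mode="cyclegan+align"` (deformation modules and
deformed-cycle term disabled) gives

```
[1.9027 1.8532 1.8415 1.8484 1.8653 1.8647]
```

— the alignment loss bottoms out at epoch 2 and then *rises* as the
adversarial term teaches the generator to reproduce the deformation. This
pair of curves is the conflict, and its removal, in miniature.

Architecture constants:

```python
from dicyc.networks import build_discriminator, build_transformer
from dicyc.evaluation import count_parameters
count_parameters(build_discriminator())   # 2762689  (~2.76M)
build_transformer().grid.n                # 36 control points
```

## Command line

```bash
dicyc simulate --seed 0 --n 10 --size 128 --out data/
dicyc train    --data data/ --out run/ --mode dicyc --align-loss nmi \
               --epochs 4 --iterations 100 --base-channels 8 --resnet-blocks 2
dicyc synth    --checkpoint run/ckpt/final.bin --data data/ --out pred/
dicyc eval     --pred pred/ --ref data/ --out report/
```

`--mode {dicyc,cyclegan,cyclegan+align}` is the ablation switch; every run
dumps its effective configuration and a structured loss CSV into the output
directory.

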