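# blastoseg

Semantic segmentation of human blastocyst components in microscopy images.

In IVF, embryologists assess day-5 embryo (blastocyst) viability from the
morphology of its compartments: the trophectoderm (TE), the zona pellucida
(ZP), the inner cell mass (ICM) and the blastocoel (BL).  These structures
have very similar gray levels and indistinct boundaries under
Hoffman-modulation-contrast microscopy, and the minor classes (ICM, TE, ZP)
occupy far fewer pixels than the background and the blastocoel.  `blastoseg`
implements a lightweight multiscale-aggregation encoder–decoder that labels
every pixel of a 400×400 grayscale micrograph as one of {BG, TE, ZP, ICM,
BL} and emits one binary mask per component for downstream morphometric
analysis.

## The model

A shared stride-2 input convolution produces a 200×200×16 feature `F_i`
that feeds four parallel branches:

* **Scale-8**: 3×3 entry convolution with stride 8 and dilation 8, eight
  depthwise-separable convolutions (DWSC), three 2×2/stride-2 transposed
  convolutions back up to 200×200×32;
* **Scale-2**: stride-2/dilation-2 entry, five plain 3×3 convolutions, the
  network's single max-pooling layer, two DWSC, two transposed convolutions
  (→ 200×200×64);
* **Scale-4**: stride-4/dilation-4 entry, plain convolutions and four DWSC,
  two transposed convolutions (→ 200×200×64);
* **Feature booster block (FBB)**: four 3×3 stride-1 convolutions that keep
  the full 200×200 resolution (→ 200×200×128), preserving minor-class
  detail that strided/pooled paths lose.

The branch outputs are depth-concatenated into the aggregated feature

    S_A = F_S8 ⊕ F_S2 ⊕ F_S4 ⊕ F_FBB       (32+64+64+128 = 288 channels)

which a shallow decoder (three 3×3 convolutions, one transposed convolution,
then a 1×1 five-filter class head) maps to per-pixel class scores at full
input resolution.  Every convolution except the head is followed by batch
normalisation and ReLU.  Training uses the Tversky loss

    TI_c = Σp·g / (Σp·g + α·Σp·(1−g) + β·Σ(1−p)·g),   L = 1 − mean_c TI_c

(α = 0.7 penalising false positives, β = 0.3 false negatives), which handles
the BG/BL-dominated class imbalance; weighted cross-entropy, focal and Dice
losses are included for ablation.  Evaluation reports the per-class Jaccard
index JI = TP/(TP+FP+FN) in percent and its unweighted five-class mean.

Everything — including the convolution forward/backward passes and the Adam
optimizer — is implemented in NumPy (`blastoseg.nn`), so training runs on a
plain CPU with no deep-learning framework installed.

A synthetic **phantom generator** renders blastocyst look-alikes (ZP
annulus, TE annulus, BL cavity, ICM blob attached to the inner TE wall, with
closely spaced gray levels, blur, noise and shading) with exact ground-truth
masks, so the whole pipeline is trainable and testable without microscope
data.

## Worked example

Train on 64 synthetic phantoms (48×48, batch 4, 12 epochs, Tversky loss)
and evaluate on 16 held-out phantoms:

```python
from blastoseg.evaluation import evaluate
from blastoseg.losses import LossConfig
from blastoseg.network import canonical_spec
from blastoseg.phantom import PhantomConfig, generate_phantom
from blastoseg.training import TrainingConfig, train

cfg = PhantomConfig(image_size=48, seed=0)
train_set = [generate_phantom(cfg, i) for i in range(64)]
test_set = [generate_phantom(cfg, 64 + i) for i in range(16)]

config = TrainingConfig(initial_learning_rate=1e-3, batch_size=4,
                        epochs=12, seed=0, loss=LossConfig(kind="tvl"))
net, curve = train(canonical_spec(with_fbb=True), train_set, config)
print(evaluate(net, test_set))
```

prints (about 1–2 minutes on one CPU core):

```
    TE      ZP     ICM      BL      BG  MeanJI
 92.32   95.11   94.22   97.99   98.89   95.71   (n=16)
```

i.e. after ~190 iterations the network recovers all five phantom classes
with a mean Jaccard index of 95.71% on unseen phantoms; repeating the run
with `canonical_spec(with_fbb=False)` drops the mean JI (82.36% on the same
seed/data), the directional effect the feature booster block exists for.

The same pipeline is available from the shell:

```sh
blastoseg phantom --n 235 --size 400 --seed 0 --out data/
blastoseg augment --data data/ --factor 16 --out data_aug/
blastoseg train --data data_aug/ --loss tvl --out run/
blastoseg evaluate --checkpoint run/checkpoint.npz --data data/ --out eval/
blastoseg inspect --with-fbb     # per-layer shape/parameter table
```

`blastoseg inspect` ends with

```
US-Tconv-A            400 x 400 x 32          8288
Class-Mask-Conv       400 x 400 x 5            165
TOTAL                                      2152037  (2.15 M)
```

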