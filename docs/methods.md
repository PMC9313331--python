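# Methods

## Problem and model

The package segments single-blastocyst grayscale micrographs into five
classes — background (BG=0), trophectoderm (TE=1), zona pellucida (ZP=2),
inner cell mass (ICM=3) and blastocoel (BL=4) — with one integer label per
pixel and, equivalently, five mutually exclusive binary masks.  The class
colour convention (TE red, ZP green, ICM blue, BL yellow, BG black) is fixed
in `dataio.CLASS_MAP`; indices are a package choice with BG=0 as the
conventional background index.

The network is a four-branch multiscale encoder–decoder (see `network`
module docstring and the README for the block layout).  Three design
features matter for the minor classes: only one max-pooling layer exists in
the whole network (spatial reduction is otherwise by strided/dilated
convolutions with learned weights); a full-resolution feature booster block
(FBB) carries 200×200 feature maps end to end; and the four scales are
combined by depth-wise concatenation rather than addition, so the decoder
sees all resolutions at once.  Depthwise-separable convolutions (depthwise
3×3 followed by pointwise 1×1, batch-norm + ReLU after the pointwise stage
only) keep the parameter count near 2 M.

### Shape arithmetic

For every 3×3 convolution (plain, dilated entry, depthwise) the padding
equals the dilation factor.  This is the unique rule that reproduces the
canonical per-layer output sizes: a 200×200 input maps to 25×25 under
stride 8/dilation 8, 100×100 under 2/2, and 50×50 under 4/4.  Transposed
convolutions use kernel 2, stride 2, no padding — exact doubling with no
output-padding ambiguity.  One published table entry lists the Scale-2 entry
convolution with stride 8; its printed 100×100 output and the surrounding
text fix stride = dilation = 2, and the package treats the 8 as a typo.

The architecture accepts any square input whose side is a multiple of **16**
(the stride-8 entry maps side/2 to ceil(side/16), and three doublings return
8·ceil(side/16), which equals side/2 only when side ≡ 0 mod 16).  A side of
40 raises a shape error at the aggregation naming both operands; 48, 64 …
400 pass, with output spatial size exactly equal to the input.

### Parameter counting

`network.count_parameters` counts convolution/transposed-convolution
weights, all biases, and the two batch-norm affine terms per normalised
channel.  Under this convention the totals are 2,152,037 (with FBB, 2.15 M
at 3 s.f.) and 1,722,629 (without, 1.72 M); dropping biases and batch-norm
terms gives 2,141,168 / 1,712,624 (2.14 / 1.71 M).  Commonly quoted totals
of 2.06 M / 1.63 M for this architecture are ~4 % lower than any per-layer
tally of the published layer table under either convention; the
with-vs-without-FBB *difference*, 429,408 ≈ 0.43 M, is reproduced exactly
and decomposes into the four FBB convolutions plus the widening of the
first decoder convolution from 160 to 288 input channels.  The package
reports its own faithful count and asserts the difference decomposition.

## NumPy execution engine

No autodiff framework is used: `blastoseg.nn` implements forward and
backward passes analytically for exactly the layer set the architecture
needs.  Convolutions are evaluated as BLAS matrix products over the k²
shifted views of the zero-padded input (an im2col without materialising
per-pixel patches beyond the k² slices); depthwise convolutions as nine
broadcast multiply–adds; 2×2/stride-2 transposed convolutions as a single
(N·H·W, C_in) × (C_in, 4·C_out) product followed by a scatter reshape.
Batch normalisation uses batch statistics in training and running averages
(momentum 0.1, ε = 1e-5) at inference.  All arithmetic is float32; every
backward pass is verified against float64 central differences in
`tests/test_nn.py` (tolerance 1e-7 on tensors of unit scale).

Weights are He-normal initialised from a single seeded generator walked in
fixed layer order; biases and batch-norm offsets start at zero, gains at
one.  Two builds with the same seed are bit-identical, and the whole
training loop (shuffling included) is deterministic given the config seed
on a fixed device.

## Losses

All four losses consume softmax probabilities and average over the five
classes so ablation magnitudes are comparable.  Tversky and Dice pool their
pixel sums over the whole batch.  Defaults: Tversky α = 0.7, β = 0.3 (the
values recommended where the loss was introduced; the choice is surfaced in
`LossConfig`, not hard-coded), focal γ = 2, smoothing stabiliser 1e-6
everywhere.  Weighted cross-entropy defaults to inverse class
pixel-frequency weights normalised to mean 1
(`losses.inverse_frequency_weights`), computed on the training masks.  Note
the Tversky↔Dice identity at α = β = 0.5 holds only up to the stabiliser
(the s-terms scale differently), so tests assert it at absolute tolerance
1e-6.  Gradients with respect to the pre-softmax scores are analytic
(softmax Jacobian applied in closed form) and finite-difference checked.

## Training protocol

Full-scale defaults in `TrainingConfig` mirror the published protocol: Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-6), initial learning rate 1e-4, batch 20,
40 epochs, per-epoch reshuffling.  "Global L2 normalisation" is read as an
L2 weight penalty added to the gradient of all convolution weights
(excluding biases and batch-norm affine terms), default coefficient 1e-4; a
coefficient of 0 disables it.  The iteration count is always derived as
epochs × ⌈N/batch⌉ rather than fixed, since a fixed iteration figure and an
epoch count cannot both be honoured in general.  No learning-rate schedule
and no validation split are used.

## Phantom generator

`phantom.generate_phantom` renders the geometry the segmenter must handle:
a jittered embryo centre, a ZP annulus (outer radius 0.38–0.45 of the image
side, thickness 0.05–0.08), a TE annulus inside it (0.04–0.06), the BL
cavity, and a single 4-connected ICM disk whose centre sits at
r_TE − 0.8·r_ICM so its rim always crosses the inner TE wall before being
clipped to the cavity — guaranteeing ICM–TE contact.  Ring boundaries get a
low-order angular wobble (±15 % of the minimum ZP thickness) so they are not
perfect circles.  Class mean intensities are deliberately close (ICM 0.45,
TE 0.50, BG 0.55, BL 0.60, ZP 0.65): the 0.05 spacing is comparable to the
blur (σ = 0.004·side) plus additive Gaussian noise (σ = 0.02) and a linear
illumination ramp (amplitude 0.05), so class boundaries are
intensity-ambiguous rather than trivially thresholdable.  At these defaults
BG+BL cover ~70 % of pixels and ICM ~5 %, reproducing the strong class
imbalance of real data.  Each sample draws from its own seed stream
(`SeedSequence(seed, spawn_key=(index,))`), so datasets are
order-independent and bit-reproducible.

What the phantoms do **not** emulate: Hoffman-modulation-contrast shading
and halo artefacts, textured cell interiors, TE cell boundaries, partially
collapsed or hatching blastocysts, debris, and multi-embryo frames.
Passing the phantom-learning tests therefore demonstrates that the
architecture, losses, optimiser and evaluation chain are wired correctly
and can fit blastocyst-like geometry under class imbalance — not that the
printed real-data Jaccard indices are reproduced, which would require the
original 235-image microscope dataset and GPU-scale training.

## Augmentation

Transforms apply one geometric map to image (bilinear) and mask
(nearest-neighbour); pixels entering the frame are filled with the
background gray level / BG label, background being the only class that can
surround the embryo.  The expansion factor defaults to 16 (200 → 3200, the
published expansion, with the identity occupying slot 1 of each sample's
16).  The bank contains flips, right-angle rotations, ±15° rotations and
axis/diagonal translations of ~5 % of the image side; slots beyond the bank
are filled with seeded random rotations (±30°) or translations.  The
magnitudes are package choices — only the operation families (flips,
rotations, translations) are prescribed.  Photometric augmentation is
deliberately out of scope.

## Evaluation

Per-class TP/FP/FN are pooled over all evaluated pixels (micro aggregation)
before applying JI = TP/(TP+FP+FN); this is the reading consistent with the
set definition of the index, and a `per_image` averaging mode is provided
for comparison.  The mean JI is the unweighted arithmetic mean of the five
per-class percentages, BG included — the convention under which the
published per-class rows average exactly to their printed means (e.g.
79.08, 84.69, 85.88, 89.28, 96.07 → 87.00).  A class absent from both
prediction and reference would make the index 0/0; it is defined as 100 %
(vacuous perfect match) and flagged in the report.  Values are reported to
two decimals in percent.  Ties in the per-pixel argmax resolve to the
lowest class index, i.e. background.

## Desk-scale study sizes

CPU training in pure NumPy sets the problem sizes used by the test suite,
chosen once as the package's desk-scale conditions: 48×48 phantoms
(smallest side divisible by 16 that keeps the ZP/TE rings ≥ 2 px thick)
with 64 training / 16 held-out samples, batch 4, 12 epochs, Adam at 1e-3
(larger than the full-scale 1e-4 because only ~190 iterations fit a quick
run), Tversky loss, seed 0 — reaching mean JI ≈ 96 % with the FBB and
≈ 82 % without on held-out phantoms, in roughly a minute per run.  The
two-phantom overfitting check runs 300 iterations at 32×32 and requires
> 95 % training pixel accuracy.  Augmentation and architecture checks run
at 32 px and full 400 px respectively (shape inference and parameter
counting are resolution-exact and instant).

## Known limitations

* The engine targets this architecture: convolution kernels of 3 and 1,
  transposed kernel 2/stride 2, pooling 2×2 only; batch-norm backward
  assumes training mode.
* Training at the full 400×400, batch-20 protocol is CPU-bound in NumPy
  (hours, not minutes); the package is correct but not fast at that scale.
* The phantom realism gap listed above; no photometric augmentation.
* Checkpoints are NumPy `.npz` archives keyed by section and parameter
  order; they are not portable to other frameworks.
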