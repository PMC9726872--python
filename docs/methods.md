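# Methods

## Problem and approach

Sleep staging assigns each 30-s epoch of overnight EEG one of the AASM
stages Wake, N1, N2, N3, REM. Stage prevalence is grossly unequal — N2
covers roughly half a night while N1 is a few percent — so a stager trained
on raw epoch counts under-serves the minority stages, N1 most of all.

The package addresses this by *image-space augmentation*: epochs are
rendered as continuous-wavelet time–frequency images, one generative
adversarial network is trained per under-represented stage, and the
training set is topped up with generated images until every class matches
the majority count. The effect is quantified by comparing a CNN stager
trained on the original versus the balanced dataset under identical seeds
and split protocol.

## Preprocessing

1. Butterworth low-pass, 8th order, 35 Hz cut-off. Applied forward–backward
   (zero phase) by default, the standard choice for offline EEG; a causal
   single pass is available for response analysis.
2. Optional 50 Hz notch (2nd-order IIR, quality factor 30, configurable)
   for mains interference. The band 10 Hz away is attenuated by < 5%.
3. R&K → AASM label mapping (3 and 4 merge into N3); MOVEMENT and UNKNOWN
   epochs are excluded.
4. Trimming to the sleep period plus wake margins. The pre-sleep margin is
   a parameter (default 15 min, same as the post-wake margin): how much
   pre-sleep wake to retain is a genuinely open choice, so it is exposed
   rather than fixed.
5. Slicing into 30-s epochs (3000 samples at 100 Hz). When signal and
   hypnogram lengths disagree, the shorter governs and a warning is logged.
6. Complex Morlet CWT (`cmor1.5-1.0`) on 96 logarithmically spaced
   frequencies over 0.5–35 Hz — 96 rows map one-to-one onto image rows and
   the grid ends at the low-pass cut-off.
7. Rendering: time axis bin-averaged from 3000 samples to 96 columns,
   per-epoch min–max normalisation, viridis colormap, rescaled to [−1, 1].
   A constant scalogram maps to the colormap midpoint, which keeps the
   mapping total and deterministic.

Per-epoch min–max normalisation discards absolute amplitude between
epochs; it was chosen because GAN training on a fixed value range is far
more stable than on unbounded µV scales.

## Generator and discriminator

The generator projects 100-d standard-normal noise through a learned dense
layer to (6, 6, 512) — a projection is required because 100 ≠ 6·6·512 —
then applies four stride-2 3×3 transposed convolutions
(512→256→128→64→3 channels) with batch normalisation and ReLU, ending in
Tanh. After the first and second upsampling stages sits a residual dense
network (RDN) of six residual dense blocks (RDBs). One RDB is three
densely connected 3×3 convolutions of growth 32, a 1×1 local-fusion
convolution back to the block width, and a local residual add; the RDN
concatenates all block outputs, fuses them with a 1×1 then a 3×3
convolution, and adds the RDN input (global input–output fusion). Block
depth and growth are configurable; 3 layers × growth 32 keeps the RDB
parameter count moderate next to the transposed convolutions.

The discriminator is DCGAN-style: four 5×5 stride-2 convolutions
(3→64→128→256→512), LeakyReLU(0.2), batch normalisation on all but the
first layer, flatten from (6, 6, 512), and one sigmoid unit.

A *scaled mode* shrinks the identical architecture for CPU-scale work:
`base_size` ∈ {16, 32, 96} sets the output resolution (the initial spatial
size is `base_size/16`), and a `width_factor` multiplies every channel
width. Desk-scale runs therefore exercise the same code path as the
full-size model, just narrower.

## Losses and training

Per iteration, one discriminator update and one generator update:

* Discriminator: cross-entropy `−E[ln D(x)] − E[ln(1−D(G(z)))]` plus
  `λ_gp` (default 10) times a two-sided gradient penalty
  `E[(‖∇_x D(x̂)‖₂ − 1)²]` on interpolates `x̂ = u·x + (1−u)·G(z)`,
  `u ~ U(0,1)`. Combining a gradient penalty with a sigmoid cross-entropy
  discriminator is non-standard (the penalty originates in the Wasserstein
  setting); it is kept configurable and `λ_gp = 0` disables it.
* Generator: adversarial term plus `λ₁ = 0.1` times a perceptual loss —
  the mean squared Frobenius distance between frozen convolutional feature
  maps of generated and real batches, normalised by the feature volume
  w·h·d.

The generator's adversarial term is non-saturating (`−E[ln D(G(z))]`) by
default; the minimax form `E[ln(1−D(G(z)))]` is available behind a flag.
Noise is standard normal; Adam uses β₁ = 0.5, β₂ = 0.999 (the usual DCGAN
settings) with discriminator lr 2·10⁻⁴ and generator lr 5·10⁻⁴; LeakyReLU
α = 0.2; batch-norm momentum 0.9; full-scale defaults are 25 000
iterations at batch 64.

### Perceptual features without pretrained weights

The package bundles no pretrained feature network (its deliverable is pure
text). The default feature extractor is a frozen *random-weight*
convolutional network (three strided 3×3 conv + LeakyReLU stages, fixed
seed). Random convolutional features are a recognised, reproducible
embedding for distance-based criteria; the loss contract is identical to a
pretrained extractor, and any frozen feature map (e.g. a 19-layer
pretrained network, where available) can be dropped in.

### Gradient-penalty parameter gradient

The penalty's own value is computed exactly by backpropagating the
discriminator to its input. Its gradient with respect to discriminator
*parameters* requires second-order backpropagation, which the NumPy engine
does not implement. Instead the update differentiates the surrogate
`s(θ) = (D(x̂+εv) − D(x̂−εv)) / 2ε` with `v` the frozen unit input-gradient
direction and ε = 10⁻³: `s` equals `‖∇_x D(x̂)‖` to O(ε²), and its
parameter gradient needs only first-order backprop through two forward
passes. Penalty passes run the network in inference mode (running
batch-norm statistics) so each sample's gradient is independent of the
rest of the batch.

## Numerical engine

All networks run on a small NumPy engine written for this package —
im2col-based strided convolution and its exact adjoint (transposed
convolution), batch normalisation, pooling, dropout, Adam — with manual
backpropagation verified against central finite differences in the test
suite. Parameters default to float32 (the engine is memory-bandwidth
bound; float32 roughly halves step cost at ample precision for SGD);
float64 is available via a context manager and is used by the
gradient-check tests. All randomness flows through explicit
`numpy.random.Generator` objects, so every training run is bit-reproducible
from one integer seed.

## Fréchet distance

Generated-image quality uses the Fréchet distance between Gaussians fitted
to feature embeddings:

    FD = ‖u_x − u_g‖² + Tr(Σ_x + Σ_g − 2 (Σ_x Σ_g)^{1/2})

Means and covariances use the n−1 denominator (n ≥ 2 per side). The matrix
square root is computed through the symmetric product
`(Σ_x^{1/2} Σ_g Σ_x^{1/2})^{1/2}` so only Hermitian eigendecompositions are
needed; eigenvalues above −10⁻¹⁰ (relative) are clipped to zero and the
result is clamped at 0. Because absolute values depend entirely on the
feature space, every report records the extractor used; values from
different extractors are not comparable.

## Classifier and evaluation protocol

The stager is a plain CNN: four 3×3 convolutions (32, 64, 128, 256
channels by default) with ReLU and 2×2 max pooling, then fully connected
layers 512 → 128 → 5 with dropout 0.5, softmax cross-entropy, Adam at
initial lr 5·10⁻⁵ halved every 10 epochs (the step-decay schedule is
otherwise unspecified, so factor and step are parameters). Conv widths, FC
widths, pooling type and epoch count are defaults, not claims.

Splits are stratified 7:3. The default mode, `augment-train-only`, admits
generated images to the training arm only, so all reported metrics are
computed on real images; a `mixed` mode splits the mixed dataset
as a whole (in which case generated images may be tested on). Neither mode
is claimed to be the historically used protocol — the protocol with mixed
data is ambiguous — and the default avoids train/test leakage.

Metrics follow the standard one-vs-rest definitions: Pre = TP/(TP+FP),
Re = TP/(TP+FN), F1 their harmonic mean, Acc = trace/total. Zero-support
or zero-denominator cases report NaN, never a silent 0. Repeated
evaluation re-splits and re-trains n times (default 6) varying only the
seed and reports per-class mean recall plus the mean and *population*
standard deviation of overall accuracy.

## Balancing and the experiment driver

Balancing tops every class up to the majority count ("same number of each
type") with samples from its stage's GAN; classes already at or above the
target are untouched, and no GAN is trained for them. An optional smaller
target supports desk-scale runs. A single master seed fans out through
`numpy.random.SeedSequence` to per-stage GAN seeds, the balancing seed and
the evaluation seeds, making the whole experiment one-number reproducible.
With balancing disabled the two arms are identical by construction and the
driver reuses the "before" results for the "after" section.

## Synthetic data: what it emulates, and what it does not

**Recordings.** Each stage's 30-s epochs carry the canonical spectral
signature — Wake: 8–12 Hz alpha; N1: low-amplitude 4–7 Hz theta; N2: theta
plus 12–14 Hz spindle bursts (Poisson arrivals, default 4/min × 1 s,
Hann-windowed); N3: high-amplitude 0.5–2 Hz delta; REM: theta plus
low-amplitude 15–30 Hz beta — as a centre-frequency sinusoid plus Gaussian
band-limited noise, over a 1/f background (exponent 1.0, the standard EEG
background model), with optional 50 Hz mains contamination. Amplitudes are
in a µV-like scale (e.g. delta 75, alpha 30). Not modelled: K-complex
morphology, stage transitions within epochs, artifacts, multi-channel
structure.

**Image fixtures.** GAN and classifier tests use class-distinct texture
images (an oriented grating whose orientation/frequency identify the
class, a class-positioned Gaussian blob, pixel noise σ = 0.12) that bypass
the signal path deliberately, so generative tests do not depend on
preprocessing. The classes are linearly separable by construction (a
least-squares probe reaches ≥ 95%), which real sleep spectrograms are not.
Consequently the desk-scale before-arm classifier can sit at or near
ceiling, and the end-to-end criterion is a *non-degradation* check
(balanced ≥ original on minority recall) plus a convergence check
(surrogate Fréchet distance falls from initialisation) — passing them shows
the machinery is sound at desk scale, not that augmentation will improve a
given real dataset.

## Problem sizes used by tests and the acceptance script

Desk-scale settings were chosen so the whole study runs on a single CPU:
GANs in 16- or 32-px mode with width factor 1/8–1/16, one RDB of two
layers (growth 4), batch 8–16, 1000 iterations; the classifier with
8–64-channel convolutions, 20 epochs; the imbalanced fixture has class
counts 80/20/200/80/100. The full-scale architecture (96 px, width 1, six
RDBs) is still constructed and shape-checked in the tests; only training
happens at reduced width.

## Known limitations

* Gradient penalty + sigmoid cross-entropy discriminator is a faithful but
  non-standard combination; no claim is made about its optimality.
* The random-feature Fréchet surrogate ranks distributions consistently
  but its absolute scale is incomparable to pretrained-feature scores.
* The EDF reader (optional `mne` extra) is provided untested here — the
  test suite ships no binary EDF fixtures; CSV round-trips are tested.
* Reported desk-scale numbers characterise the synthetic fixture only.
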