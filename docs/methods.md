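# Methods

`dbtseg` segments bright, low-contrast mass regions in stacks of 2D
grayscale slices — the data layout of reconstructed digital breast
tomosynthesis (DBT) volumes — with a dilated fully-convolutional
network trained on labelled patches. This note records the model, its
assumptions, the numerical choices, and what the bundled synthetic
phantoms can and cannot establish.

## Pipeline

Every slice of a volume is processed independently in 2D; only the
postprocessing and the lesion-level evaluation are 3D. The stages are:

1. **Preprocessing** — per-slice white top-hat, then multiplication by
   an RBF constraint matrix (below).
2. **Patch extraction** — sliding-window patches over every slice, each
   labelled positive iff the ground-truth mask is 1 at the patch centre.
3. **Training** — per-epoch class-balanced resampling, right-angle
   rotation augmentation, Adagrad on the `1 − f_α` overlap loss.
4. **Dense prediction** — per-slice forward pass of the dilated FCN,
   softmax over the two class channels.
5. **Postprocessing** — threshold at 0.5, removal of connected clusters
   with fewer than 50 voxels (strict `< 50`), per-slice 3×3 binary
   median smoothing.
6. **Evaluation** — voxel-level ACC/SEN/SPE and ROC-AUC; lesion-level
   FROC (true-positive rate vs false-positive components per volume).

## Preprocessing

The white top-hat (image minus its grey opening with a disk) extracts
bright structures smaller than the structuring element. The disk radius
must exceed the largest expected in-plane mass radius; defaults are
50 px at full scale and 35 px in the desk profile (0.1 mm/px). We use
scikit-image's sequence decomposition of the disk footprint, which is
near-exact and roughly two orders of magnitude faster than the dense
footprint at these radii.

The constraint matrix is the pointwise **maximum** of isotropic Gaussian
RBFs `exp(−‖p−c‖² / (2δ²))` centred on candidate locations c, with
δ = 5 mm converted to pixels through the in-plane spacing. The maximum
(rather than a sum) keeps values in (0, 1] and treats candidates
independently. Candidates are local maxima of the top-hat response above
the 99.5th percentile of the positive response values, thinned to a
minimum separation of 2δ keeping the strongest peak. Slices with no
candidate receive a configurable floor (default 1.0, i.e. pass-through),
so the constraint step degrades gracefully to top-hat enhancement alone.
The enhanced image is `(normalized input + top-hat)`, rescaled to [0, 1],
then multiplied by the constraint matrix; the same preprocessing is
applied at training and at inference time.

Because the in-plane pixel pitch of a clinical slice is scanner-specific
and cannot be inferred from a TIFF, `pixel_spacing_mm` and
`slice_spacing_mm` are explicit metadata everywhere (defaults 0.1 mm/px
and 1.0 mm); δ is only meaningful through them.

## Network

Eight convolutional layers (all "same" zero padding, no pooling, no
striding):

| layer | kernel | channels | dilation | BN + ReLU |
|------:|:------:|:--------:|:--------:|:---------:|
| 1–7   | 3×3    | 1→32, then 32→32 | 1, 1, 2, 4, 8, 16, 1 | yes |
| 8     | 1×1    | 32→2     | 1        | no        |

A d-dilated convolution spaces the kernel taps d pixels apart:
`(f ∗_d r)(p) = Σ_{s + d·t = p} f(s) r(t)`. The receptive field of one
output pixel is `1 + Σ_i d_i (k_i − 1) = 67` px on each axis, grown
exponentially through the dilation schedule while the output stays at
input resolution — the property that makes dense per-pixel prediction
possible without an encoder–decoder. Class probabilities are the
softmax over the two output channels; the decision threshold (default
0.5) is configurable and swept for ROC/FROC.

The layers compute the framework-standard cross-correlation; this is
equivalent to the literal convolution sum up to a kernel flip, and since
the weights are learned the distinction is immaterial for training. The
literal operator is exposed as `dilated_conv2d` and the test suite pins
the layers to it via kernel flipping and a nested-sum reference.

The implementation is plain NumPy. Forward and backward passes are
hand-written: activations travel in a channels-leading `(C, N, H, W)`
layout so the im2col buffer flattens to a contiguous matrix and each
convolution is a single BLAS GEMM in forward, weight-gradient and
input-gradient directions; batch-norm and ReLU gradients are standard.
Large im2col scratch is allocated once per shape and reused across
steps — repeated page-faulted allocations otherwise dominate the GEMMs.
Everything is seeded (`numpy.random.default_rng`) and bit-deterministic
on CPU.

Batch normalization precedes ReLU in each block, uses ε = 1e−5 and
running-statistic momentum 0.1; inference uses the running statistics.
Weights are He-normal initialized from the model seed; biases start at
zero.

## Loss

`f_α(S, T) = (1 + α²) · Σᵢ sᵢtᵢ / (Σᵢ sᵢ + Σᵢ tᵢ)` over all pixels of a
batch, with the predicted mass-channel probabilities S and the binary
targets T; the training loss is `1 − f_α`. At α = 1 (the default and
the published operating point) this is the Dice coefficient. Note the
denominator is the plain sum of both heatmaps — the α² weighting of the
classical F_α score is deliberately not added; the two coincide at
α = 1.

Two numerical modes exist: a strict mode that raises on the undefined
0/0 case (both heatmaps empty), used for metric evaluation, and a
smoothed mode adding ε = 1e−6 to numerator and denominator, used during
training where all-background batches are legitimate. The loss is
pooled over all pixels of the batch rather than per patch: with masses
occupying a small fraction of any single patch, per-patch pooling makes
the denominator — and hence the gradient scale — extremely noisy.

## Training schedule

Optimizer: Adagrad at learning rate 0.01, with the Keras-style initial
accumulator value 0.1 and ε = 1e−7 (the convention of the framework the
published settings were tuned with). Full-scale defaults: batch 150,
1000 batches per epoch, 1000 epochs, patch 256, stride 28. Each epoch
draws an equal number of positive and negative patches (without
replacement when a class is large enough, with replacement otherwise),
expands the draw by the four right-angle rotations (augmentation after
balancing, so each epoch sees 4× the balanced draw), shuffles, and steps
through minibatches. Epoch seeds derive from the master seed via
`SeedSequence`, so traces are reproducible bit-for-bit.

Only right-angle rotations are used for augmentation — no mirroring, no
elastic or intensity transforms. Translation augmentation is redundant
under dense sliding-window extraction and can change a centre label.

**Desk profile.** The full-scale schedule is far beyond a single CPU.
The desk profile — patch 64, stride 16, batch 16, 30 batches/epoch, 15
epochs (450 Adagrad steps), top-hat radius 35 px — trains in ~7 minutes
on one CPU core and is the configuration exercised by the test suite
and the acceptance script. The architecture, loss, optimizer and all
postprocessing values are unchanged from the full-scale defaults.

## Synthetic phantoms

The generator emulates the statistics the method assumes, not anatomy:

- **Background**: Gaussian-blurred white noise (σ = 8 px in-plane,
  scaled through the spacing ratio along z), mapped to [0.2, 0.6] —
  smooth tissue-like texture with headroom for lesions.
- **Lesions**: non-overlapping ellipsoids, diameters drawn from
  2.5–5 mm in the desk volume (16×128×128 at 0.1 mm/px, 1 mm slices;
  the volume cannot host the largest clinical masses, whose sizes reach
  tens of mm), mild in-plane eccentricity (0.85–1.15), and a
  raised-cosine margin spanning ±30% of the radius. Intensity is
  elevated multiplicatively over the local background by the fractional
  contrast (default 0.4). The binary mask marks the nominal ellipsoid,
  whose surface sits at half the peak elevation — so mask boundaries
  are as diffuse as the masses.
- **Noise**: the clean image is scaled to an expected photon count
  (default 1000 at unit intensity), Poisson counts are drawn, and the
  result rescaled — photon-counting noise without detector physics.
- **Ground truth**: per-voxel binary labels plus per-lesion instance
  ids for lesion-level (FROC) scoring.

Passing the end-to-end tests on these phantoms demonstrates that the
pipeline can learn and recover compact bright objects against textured,
Poisson-corrupted backgrounds, that the loss/optimizer/augmentation
machinery works, and that the whole chain is deterministic. It does
**not** demonstrate clinical performance: real masses are spiculated and
heterogeneous, real backgrounds contain anatomy and reconstruction
artifacts, and real annotation is uncertain.

## Postprocessing and evaluation choices

- Cluster removal is 3D with 26-connectivity by default (the most
  inclusive neighbourhood); 6/18-connectivity and a per-slice 2D mode
  are configurable. The size rule is strict: a 49-voxel component is
  removed, a 50-voxel component survives.
- Removal precedes median smoothing and the mask is not re-filtered, so
  smoothing may shrink a surviving component below the floor.
- The binary median filter uses reflect boundary handling; an all-ones
  mask is a fixed point.
- A lesion counts as detected when any voxel of a predicted component
  overlaps it (`any_overlap`); `overlap_fraction` and `centroid` rules
  are available. FROC applies the full postprocessing chain inside the
  threshold sweep so the curve describes the deployed pipeline.
- Pixel AUC is computed over all voxels of the evaluated set via
  trapezoidal integration of the ROC curve, which equals the
  Mann–Whitney rank statistic; the suite pins this equality to 1e−9.
- Cross-validation splits are by volume, never by patch, in k
  near-equal folds (sizes differ by at most one).

## Known limitations

- The NumPy network is CPU-bound; the full-scale schedule (1000×1000
  batches of 150 patches of 256²) is impractical without an accelerator
  framework and is exposed as configuration only.
- Candidate detection before the network is a heuristic (percentile
  local maxima of the top-hat); a missed candidate attenuates — but
  does not zero — the corresponding region via the constraint floor.
- Batch-norm running statistics come from the balanced, augmented patch
  distribution, which differs from full-slice statistics at inference;
  at desk scale this shows up as a modest threshold sensitivity.
- The phantom's lesion/background model is deliberately simple; see
  above for what that implies about the tests.
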