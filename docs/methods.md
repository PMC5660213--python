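# Methods

## Scientific model

`hsqcnet` learns a metric over 2D HSQC NMR spectra. The premise is that HSQC
cross-peak patterns act as structural fingerprints: compounds of the same
structural family share most peaks, with family-specific variation in a few
positions and experiment-specific variation everywhere. A siamese
convolutional network maps a binarized spectrum raster to a point in a
K-dimensional Euclidean space (K = 10 by default, each coordinate bounded in
[−1, 1] by the final tanh), trained so that same-family spectra lie close
together and different-family spectra lie at least a margin apart.

### Spectrum representation

A spectrum is a binary raster over a fixed chemical-shift window, 0–10 ppm
(¹H, horizontal, plotted right-to-left as in spectroscopy convention) ×
0–182.3 ppm (¹³C, vertical, top-to-bottom). At the reference 512-px raster
this gives 51.2 px/ppm in ¹H and 2.8 px/ppm in ¹³C; the benchmark
configuration uses the same window at 128 px. Inputs are preprocessed by
darkness thresholding (≥ 0.5 by default) and a 5-point cross median filter
that removes isolated speckle while keeping ≥ 3×3 peak footprints intact.
Peak lists (¹H/¹³C ppm pairs in CSV) are rasterized with a 3×3 footprint
per peak and preprocessed identically, so image and peak-list queries share
one pipeline.

### Network

Per branch (both branches share all weights):

| stage | operation | output channels |
|---|---|---|
| 1–4 | 4×4 conv (stride 1, same padding) + 4×4 max-pool (stride 2) | 8, 16, 16, 16 |
| 5–7 | fully connected | 128 each |
| 8 | fully connected embedding | K = 10 |

Every layer uses tanh; batch normalization is applied at every layer except
the embedding output; dropout (p = 0.5) regularizes the three fully
connected layers; weights are Xavier-initialized and biases start at zero.
An input side of 128 yields feature maps of 63 → 30 → 14 → 6, i.e. a
16 × 6 × 6 = 576-dimensional flattened vector entering the FC stack.

### Loss and training

For a pair with embedding distance d and margin m (default 1.0):

- same family: ½·max(0, d − m)²
- different family: ½·max(0, m − d)²

so same-family pairs inside the margin and different-family pairs outside it
contribute nothing. Each minibatch is exactly half positive pairs (a family
chosen with probability proportional to its number of member pairs, then a
distinct pair within it) and half negative pairs (uniform over cross-family
pairs). Optimization is Adagrad (learning rate 0.001). Every
`eval_interval` iterations the validation average precision (PR-AUC of
validation queries against the training corpus, computed in evaluation mode)
is measured; the best weights are kept and training stops after `patience`
evaluations without improvement. Performance is estimated by 10-fold
cross-validation with an 8:1:1 train/validation/test split in which every
spectrum is tested exactly once.

### Evaluation

- **Precision–recall**: per query the corpus is ranked by embedding
  distance (ties broken by spectrum id for determinism); per-query curves
  are interpolated onto a common 101-point recall grid, averaged, and
  integrated by the trapezoid rule.
- **Closest retrieval**: fraction of queries whose true family appears
  within the first k *distinct* families along the ranking, compared
  against the most-occurring-family (MO) baseline that always predicts
  families in descending corpus frequency.
- **Accuracy vs radius**: mean fraction of true co-members captured within
  a growing hypersphere.
- **PCA baseline**: the no-network comparator embeds flattened pixel
  vectors by k = 10 PCA and is scored with the same retrieval metrics.
- **Noise robustness**: a schedule of noise levels (fractions of pixels
  flipped toward a smooth FFT-magnitude white-noise field, `n_reps`
  random repetitions per level; 140 × 100 = 14,000 renderings by default)
  tracks each noisy rendering's embedding distance to its clean original
  and, given a corpus, the family of its rank-1 neighbour.

## Synthetic benchmark design

No public labelled HSQC corpus ships with the package, so correctness and
the learning claims are demonstrated on a synthetic generator whose
structure mirrors the real problem:

- **Family templates**: 5–15 peaks placed uniformly in-window with a
  minimum pixel separation of twice the footprint; family sizes follow a
  right-skewed (truncated geometric) distribution on 5–25 unless fixed.
- **Members** are rendered from the template through a perturbation model:
  per-peak chemical-shift jitter (σ = 0.03 ppm ¹H / 0.3 ppm ¹³C), peak
  dropout (p = 0.1), spurious peak additions (Poisson mean 1), and
  salt-and-pepper pixel noise.
- **Sibling templates** replace a small number of a parent's peaks with
  fresh positions, modelling a structurally related subfamily; they drive
  the novel-category experiment.

### Calibration drift — why the benchmark is non-trivial

With per-peak jitter alone, family members at a 128-px raster are nearly
identical bitmaps and linear pixel PCA solves the task outright, leaving
nothing for a learned metric to demonstrate. Real spectra, however, also
differ by *global* calibration/referencing offsets: every peak in a
spectrum shifts coherently. The benchmark perturbation
(`PerturbationModel.benchmark()`) therefore adds a per-spectrum drift drawn
once per rendering (σ = 0.3 ppm ¹H, 6 ppm ¹³C) and applied to all peaks.
Drift moves many pixels at once, which degrades pixel-space methods badly,
while the convolution/pooling hierarchy is locally translation-tolerant —
exactly the property the siamese network is supposed to exploit. Measured
on the standard benchmark (20 families × 8 members, 128 px, five seeds):
pixel-PCA test PR-AUC ≈ 0.23, untrained network ≈ 0.42, trained network
≈ 0.5, reproducing the qualitative ordering of the full-scale system at
desk scale. Benchmark problem sizes (20 × 8 at 128 px, batch 32, 120
iterations) are the package's own choice, sized to a few minutes of
single-CPU time per seed.

## Numerical implementation

The network is implemented directly in NumPy (float32 forward/backward,
float64 accumulators for Adagrad), with correctness pinned by
finite-difference gradient tests end-to-end and per-primitive. Notable
choices:

- **Convolution** gathers input patches once per layer into a
  `(C·k·k, N·H·W)` matrix so the forward pass and the weight gradient are
  each a single BLAS matrix product; the input gradient accumulates one
  product per kernel shift in a channels-first layout and is skipped
  entirely for the first layer.
- **Max-pooling** (4×4 window, stride 2) is factorized into a
  non-overlapping 2×2 block maximum followed by a stride-1 2×2 maximum
  over blocks — two cheap stages that are exactly equivalent to the direct
  16-shift enumeration (verified bit-for-bit in the tests).
- **tanh/pool commutation**: because tanh is strictly increasing,
  `maxpool(tanh(y))` equals `tanh(maxpool(y))` exactly; the nonlinearity
  therefore runs on the pooled (quarter-size) maps, bit-identically.
- **Batch-norm backward** uses the closed-form per-channel identity
  `dx = γ·inv_std·(dout − mean(dout) − x̂·mean(dout·x̂))`, avoiding
  intermediate full-size temporaries.
- Dropout and batch statistics are active only in training mode; inference
  uses running statistics and no dropout, so embeddings are deterministic.
- All randomness flows from explicit seeds (a single master seed fanned
  out to named sub-seeds in the CLI), and result tables are written with
  round-trip-exact float formatting, so every artifact is byte-reproducible.

## Limitations

- The synthetic generator is a stand-in: peak positions are uniform rather
  than chemically distributed, intensities are binary, and solvent/artifact
  structure is not modelled. Absolute metric values on real corpora will
  differ; the package's claims are about orderings and trends.
- The NumPy implementation targets desk-scale problems (≈ 128-px inputs,
  hundreds of spectra). Full-scale training (512-px inputs, thousands of
  spectra, 2,000+ iterations at batch 256) is supported by the same code
  but is compute-bound on a single CPU.
- The embedding dimension, margin and architecture are fixed to the
  reference design; no hyperparameter search utilities are included.
- Dereplication quality depends entirely on the labelled corpus provided;
  the package does not ship reference spectra.
- Desk-scale training generalizes weakly to *held-out* families: a sibling
  subfamily that is demonstrably closest to its parent in pixel space is
  placed near the parent's cluster on only a minority of benchmark seeds
  after 120 iterations. Placing genuinely novel compounds correctly appears
  to require the full-scale schedule.
- Noise robustness at 128 px is limited by raster sparsity: a rendered
  spectrum carries only ~80 foreground pixels, so a few percent of flipped
  pixels (smooth noise blobs that survive the median filter) already
  dominates the signal and breaks rank-1 retrieval, even though the
  distance-vs-noise trend itself remains positive.
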