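# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the tests do and do not demonstrate.

## Signal representation

Recordings are mono, 300 kHz, 16-bit; any other sample rate is rejected
rather than resampled, because every downstream shape contract assumes this
rate. Bat recordings are cut into non-overlapping 1 s segments covering the
first 80% of their length ("recycling"): the recorder's trigger and
post-trigger behavior guarantee at least one echolocation pulse per second
only there. Noise recordings carry no such structure and are segmented over
their full length.

The spectrogram is a magnitude STFT with a 2048-sample periodic Hann window
(6.8 ms), 75% overlap (hop 512) and centered reflect padding, giving
exactly 1025 frequency bins × 586 frames for a 1 s segment
(586 = 1 + ⌊300000/512⌋). "Linear" refers to the frequency axis.
Amplitudes are taken to dB and min–max normalized per image to [0, 1]; an
all-zero segment maps to an all-zero image. Per-image normalization was
chosen (over a global scheme) because it stabilizes autoencoder training
when recordings differ in level; nothing downstream depends on absolute
amplitude.

MFCC matrices use the same framing: mel power spectrum over a 128-band
triangular filterbank spanning 0–150 kHz (HTK mel scale), log, then an
orthonormal DCT-II over the mel axis keeping the first 20 coefficients —
20 × 586 per segment, a ~98% element reduction relative to the
spectrogram. The coefficient count and filterbank size are package choices
fixed to honor that reduction; classifier inputs are standardized per
matrix (zero mean, unit variance, guarded for constant input).

## Autoencoder

Encoder: three blocks of 3×3 convolution (stride 1, zero padding 1), ReLU,
2×2 max-pooling with stride 2, batch normalization; channel widths
1→16→12→8. Pooling is ceil-mode — the unique simple choice that maps
1025→513→257→129 and 586→293→147→74, producing the 8 × 129 × 74
bottleneck (76,368 values, ~87% smaller than the input). Decoder: three
2×2 stride-2 transposed convolutions (exact 2× upsampling; widths
8→16→16→16), each with ReLU and batch-norm, then a final 4×4 convolution
to one channel and a center crop from the 1029 × 589 overshoot to
1025 × 586. The decoder's pooling-free upsampling overshoots because the
ceil-mode chain is not exactly invertible; cropping is the simplest
consistent closure. Reconstruction loss is mean squared error — consistent
with PSNR-based evaluation — optimized with ADAM at learning rate 1e-4 and
batch size 1; ten epochs suffice for convergence at study scale.

PSNR is 10·log10(1/MSE) for images in [0, 1] (identical images report
infinity); SSIM uses 7×7 windows with the standard stabilizing constants.
Reconstructions of this architecture are visibly blurred at the scale of a
few pixels: PSNR stays respectable while SSIM drops, and features only one
or two pixels wide — such as the thin ridge of a narrowband carrier or a
single short pulse — are not reliably restored at desk-scale training
budgets. Tests therefore assert reconstruction *improvement* and latent
*separability*, not pixel-level ridge recovery.

## Classifier

The CNN takes one 20 × 586 MFCC matrix: conv 3×3/16, conv 3×3/32 (both
padding 1), conv 2×2/32 (asymmetric bottom/right padding to preserve
5 × 146), each followed by ReLU, 2×2 stride-2 floor-mode max-pooling and
batch-norm; feature maps shrink 20×586 → 10×293 → 5×146 → 2×73. The
flattened 4672 features feed a 128-unit ReLU hidden layer and K sigmoid
outputs. Channel widths and the hidden size are the smallest round values
consistent with the architecture's low-complexity intent (~0.6 M
parameters). Loss is per-class binary cross-entropy against one-hot
targets (computed on logits for stability); prediction is the argmax of
the sigmoid scores with exact ties broken toward the lowest class index.
Training uses ADAM at 1e-4, batch 32; standard epoch budgets are 10
(bat/noise), 50 (genus) and 25 (species); reported scores average five
independently seeded runs (fewer at reduced test scale). The bat/noise
task balances its training partition by subsampling the majority class.

Because a 1 s input spans many pulses, the model can exploit interpulse
interval as well as spectral shape; the frequency-sensitivity test
(swapping two classes' bands swaps the predictions) confirms spectral
content is the primary learned cue.

## Clustering

Autoencoder latents are flattened (length 76,368) and projected to 2-D by
UMAP. Its two governing hyperparameters — neighbor count (global vs. local
emphasis) and minimum embedded distance — depend on the data geometry, so
every experiment runs an exhaustive grid search (default n_neighbors ∈
{5, 15, 30, 50, 100} × min_dist ∈ {0.0, 0.1, 0.25, 0.5}). Selection of
the "best" pair is automated with the silhouette score on the known
grouping, ties broken toward smaller n_neighbors then smaller min_dist;
embeddings are exportable for the visual inspection the original workflow
relied on. A fixed `random_state` makes embeddings reproducible (at the
cost of UMAP's parallelism). Grid cells where all group labels coincide
have no defined silhouette and are recorded as skipped.

The noise-by-height runner trains the autoencoder on per-height draws of
noise spectrograms (250 per height at study scale) and embeds a further
disjoint draw per height; the genus-vs-noise runner maps labels to the
four genus-level classes (Nyctaloid is treated as a genus; N_noc folds
into it; B_bar and noise are excluded from genus classification, noise
being kept as the fifth group of the joint embedding). Pools smaller than
the requested draw are sampled with replacement under a warning.

## Evaluation harnesses

Per-class F1 = 2·TP/(2·TP + FP + FN) is computed from confusion-matrix
margins, with 0/0 scored as 0. Classes with zero support in a partition
are reported as absent rather than as F1 = 0, to avoid artificial
deflation. Confusion matrices are exported in absolute form (log color
normalization) and row-normalized form.

Directed cross-collection validation enumerates all ordered pairs of
collections sharing a location or a year (8 for a 2×2 location–year
design; ids follow `location_year`). For a pair A→B the model trains on
A's 60% partition, validates on A's 20%, and is tested on B's 20% *test
partition* — so cross-collection numbers are computed on the same held-out
subsets as within-collection numbers. Averaged tables pool per-class F1
over pairs and runs jointly; classes missing on either side of a pair are
skipped for that pair with a warning. Splits are made at recording
granularity so recycled segments of one recording can never straddle
partitions, and are stratified per class with largest-remainder rounding,
preserving the natural imbalance.

Joined-data and hybrid-class runs draw a fresh stratified split for every
run (seeded from the run seed), while cross-collection runs pin one split
per pair. At reduced corpus sizes a single fixed split leaves the reported
run-to-run spread blind to split sampling variance — a test partition of
~100 segments carries F1 noise of a few hundredths on its own — so
re-splitting per run is what makes "validation and test agree within the
run spread" a statistically meaningful robustness statement. At field
scale (thousands of segments per partition) the two designs coincide.

The hybrid-class experiment trains species models with and without P_low
on a shared split and reports both F1 tables and the P_pip↔P_low /
P_nat↔P_low confusion mass on the test partition (summed over runs).

## Synthetic soundscapes

The generator reproduces the statistical structure the pipeline assumes,
not bat acoustics. A pulse is a linear FM down-sweep under a Hann
envelope; because the envelope peaks mid-sweep, the frequency of maximum
energy is the sweep midpoint, which is drawn per pulse from the class's
diagnostic band with a small absolute margin (≥0.25 kHz) that absorbs
windowing wobble. The margin is deliberately small so that classes whose
bands touch — the species bands at 40 and 42 kHz and the P_low hybrid band
between them — remain nearly adjacent: a hybrid class separated from its
parents by a clear spectral gap would be trivially classifiable and could
not reproduce the confusion structure that motivates the hybrid-class
experiment. Hybrid recordings additionally borrow their full temporal
parameter set (duration, interval, sweep width) from one parent species at
random, so only the peak band distinguishes them.

Pulse trains place pulses on an interpulse-interval grid with ±20% uniform
jitter, capped so consecutive starts can never exceed one second of
separation; with the first pulse near t = 0 this guarantees at least one
pulse per 1 s window over the whole recording, hence over the recycled
80%. Per-class durations and intervals are field-plausible defaults
(short fast Pipistrellus sweeps, long slow low-frequency Nyctaloid
pulses). Classes without published peak bands (Myotis, Plecotus,
Nyctaloid group, B_bar) use documented generator defaults inside their
typical ranges.

Noise recordings are one of three structural types over a white Gaussian
floor (RMS 0.003): a persistent narrowband carrier with slow AM and
frequency wander (stationary tonal, e.g. ~30 kHz), periodic short
broadband clicks with 5% timing jitter (stationary pulsed — the type that
visually mimics pulse trains), and Poisson-timed broadband transients
(non-stationary). Pulse amplitude is set by an SNR in dB relative to the
floor (default 30 dB). Collections differ by their mixture weights over
these profiles, optionally per measurement height — emulating the
empirical finding that noise structure varies by site, year and height —
and by class counts, which can be scaled from realistic imbalance profiles
with largest-remainder rounding.

What the generator does **not** emulate: atmospheric attenuation and
spreading loss, microphone directivity, social calls, overlapping
individuals, real call-shape variation (hockey-stick FM-CF morphology),
and noise whose spectra drift over months. Passing tests therefore show
that the pipeline's machinery — shapes, training dynamics, experiment
logic, separability and confusion signatures — behaves as designed on
data with the assumed structure; they do not certify field performance.

## Numerical and scale choices

The networks are NumPy arrays driven by single-pass Numba kernels
(channels-last layout); on one CPU core an autoencoder training step on a
full-resolution spectrogram takes ~0.7 s, which sets the test-scale
choices below. Training is bit-reproducible for a fixed seed; every
public entry point derives its randomness from an explicit seed or
generator, and the pipeline fans one global seed out to per-stage seeds
via a stable hash. Batch normalization with batch size 1 normalizes over
the spatial axes; running statistics are used in inference mode, which
makes encoding and prediction deterministic.

Test and acceptance runs use reduced problem sizes chosen to preserve each
experiment's signature: species-classifier checks use three well-separated
classes at ~200 segments each with 8 training epochs and 3 runs (the
25-epoch budget is unnecessary at synthetic separability); the
hybrid-class comparison uses 4 epochs and 2 runs; the autoencoder suite
trains on 250 noise spectrograms for one epoch per seed across three
seeds, which is ample for the reconstruction-improvement and
latent-separability properties (full 10-epoch convergence is reserved for
real use). The joined-split agreement check compares |val − test| F1
against the pooled run-to-run std with a 0.02 floor guarding the
degenerate zero-spread estimate that three runs can produce.

## Known limitations

- Pixel-scale features are not preserved by the autoencoder at reduced
  training budgets (see above); species-level clustering of latents is
  accordingly not a supported feature — consistent with the documented
  failure of unsupervised separation within a genus.
- The directed cross-collection design assumes `location_year` collection
  ids; other naming schemes require explicit pair lists.
- The pulse model's spectra are symmetric around the peak; real calls
  concentrate energy near their terminal frequency. Band adjacency, not
  call morphology, carries the class structure here.
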