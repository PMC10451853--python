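# batpipe

Automated analysis of ultrasonic bat-monitoring recordings: detect
echolocation sound in noisy triggered recordings and identify the genus or
species that produced it, with an unsupervised stage that makes the noise
structure of a monitoring site visible before any classifier is trained.

Passive acoustic monitoring stations near wind-energy sites record at
300 kHz around the clock and accumulate far more triggered audio than human
experts can label. The recordings mix echolocation pulse trains with
stationary interference (persistent narrowband carriers, periodic click
trains that mimic bat pulses) and broadband transients, and both the class
balance and the noise structure differ between locations and years. This
package implements a complete two-stage pipeline for such data, together
with a synthetic soundscape generator that reproduces its statistical
structure, so every stage is testable without access to restricted field
recordings.

## The pipeline

**Unsupervised stage.** Each 1 s segment becomes a linear-frequency
magnitude spectrogram (STFT, 2048-sample Hann window = 6.8 ms at 300 kHz,
75% overlap → 1025 × 586, dB-scaled and min–max normalized). A
convolutional autoencoder — encoder 3 × (3×3 conv, ReLU, 2×2 max-pool,
batch-norm), widths 1→16→12→8 — compresses each image to an 8 × 129 × 74
latent tensor (~87% fewer values); reconstruction quality is scored with
PSNR and SSIM. The flattened latents are projected to 2-D with UMAP under
an exhaustive grid search over the neighbor count and minimum distance,
scored by the silhouette of the known grouping (measurement height,
collection, genus vs. noise). This shows, before any supervised training,
which heights and collections share noise structure and how bat calls sit
relative to noise.

**Supervised stage.** Each segment also becomes a 20 × 586 MFCC matrix
(same framing, 128-band mel filterbank over 0–150 kHz, first 20 DCT
coefficients — ~98% smaller than the spectrogram). A compact CNN (3×3/16,
3×3/32, 2×2/32 convolutions with pooling and batch-norm, a 128-unit hidden
layer, K sigmoid outputs) is trained with per-class binary cross-entropy,
ADAM at learning rate 1e-4, batch size 32 — for bat/noise detection (10
epochs), genus identification (50) and species identification (25).
Scores are per-class F1 = 2·TP / (2·TP + FP + FN), reported as mean ± std
over five independently seeded runs.

Experiment harnesses reproduce the three study designs: directed
cross-collection validation (train/validate on one location–year, test on
another; all ordered pairs sharing a location or year), joined-data
training with a stratified 60:20:20 split preserving class imbalance, and
a hybrid-class comparison that trains species models with and without the
P_low class (calls in the 40–42 kHz band shared by *P. pipistrellus* and
*P. nathusii*) and quantifies the confusion it induces.

**Synthetic soundscapes.** The generator emulates triggered field
recordings: linear FM down-sweep pulse trains whose frequency of maximum
energy falls in each class's diagnostic band (e.g. P_pip 42–50 kHz, P_nat
35–40 kHz, N_noc below 20 kHz), interpulse-interval jitter, a recycling
guarantee of at least one pulse per second in the first 80% of a recording,
three structural noise types with per-collection (and per-height) mixtures,
and class imbalance scaled from realistic counts by largest-remainder
rounding.

## Worked example

```python
import numpy as np
from batpipe.synthetic import CollectionConfig, synth_corpus
from batpipe.evaluation import dataset_from_recordings, joined_eval
from batpipe.classifier import ClfTrainConfig

config = CollectionConfig(
    "east_2019", {"P_pip": 70, "P_nat": 70, "P_pyg": 70},
    seed=11, bat_duration_range_s=(2.0, 6.0))
recordings, catalog = synth_corpus(config)
dataset = dataset_from_recordings(recordings)          # ~590 segments
report = joined_eval(dataset, "species",
                     ClfTrainConfig(epochs=8, n_runs=1, seed=0))
print(report.table[["class", "partition", "f1_mean", "f1_std"]])
```

Output (one run, a few minutes on one CPU core):

```
   class partition   f1_mean  f1_std
0  P_nat      test  0.988764     0.0
1  P_nat     train  1.000000     0.0
2  P_nat       val  0.984127     0.0
3  P_pip      test  0.986667     0.0
4  P_pip     train  1.000000     0.0
5  P_pip       val  0.987342     0.0
```

Validation and test F1 agree closely — the model generalizes to unseen
recordings drawn from the same corpus — and both species are identified
with F1 ≈ 0.99 on this cleanly separable synthetic corpus. (P_pyg rows are
analogous; real field data is harder than this synthetic baseline.)

The command line exposes the same flow:

```
batpipe simulate --config collection.yaml --out data/east_2019 --seed 1
batpipe train-ae --data data --out models
batpipe cluster --task noise-by-height --data data --out plots
batpipe train-clf --task species --data data --out reports
batpipe evaluate --mode hybrid --data data --out reports
batpipe run-all --config pipeline.yaml
```

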