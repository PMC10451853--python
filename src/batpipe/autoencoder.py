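"""Convolutional autoencoder for linear spectrograms.

The encoder stacks three blocks of (3x3 conv, ReLU, 2x2 max-pool,
batch-norm) with channel widths 1 -> 16 -> 12 -> 8, compressing a
1025 x 586 spectrogram to an 8 x 129 x 74 bottleneck (76,368 values, a
~87% reduction). Pooling uses ceil mode — the unique simple choice that
maps 1025 -> 513 -> 257 -> 129 and 586 -> 293 -> 147 -> 74 exactly. The
decoder mirrors it with three stride-2 transposed convolutions (widths
8 -> 16 -> 16 -> 16, each followed by ReLU and batch-norm), a final 4x4
convolution back to one channel, and a center crop from the overshoot
resolution (1029 x 589) to the input size.

Training minimizes mean squared reconstruction error with ADAM at learning
rate 1e-4 and batch size 1; the model converges adequately within 10
epochs. Reconstruction quality is scored with PSNR and SSIM.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.metrics import structural_similarity

from . import nn
from .preprocessing import SPECTROGRAM_SHAPE

__all__ = [
    "BOTTLENECK_SHAPE",
    "LATENT_SIZE",
    "AeTrainConfig",
    "ConvAutoencoder",
    "build_autoencoder",
    "train_autoencoder",
    "encode",
    "encode_batch",
    "psnr",
    "ssim",
]

BOTTLENECK_SHAPE = (8, 129, 74)  # channels, frequency, time
LATENT_SIZE = int(np.prod(BOTTLENECK_SHAPE))  # 76,368


@dataclasses.dataclass
class AeTrainConfig:
    """Training settings; the defaults are the reference settings."""

    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ConvAutoencoder:
    """Encoder/decoder pair over (1025, 586) spectrogram images."""

    input_shape = SPECTROGRAM_SHAPE
    bottleneck_shape = BOTTLENECK_SHAPE

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = nn.Sequential(
            nn.Conv2d(1, 16, 3, 1, rng, input_grad=False),
            nn.ReLU(), nn.MaxPool2d(ceil_mode=True), nn.BatchNorm2d(16),
            nn.Conv2d(16, 12, 3, 1, rng),
            nn.ReLU(), nn.MaxPool2d(ceil_mode=True), nn.BatchNorm2d(12),
            nn.Conv2d(12, 8, 3, 1, rng),
            nn.ReLU(), nn.MaxPool2d(ceil_mode=True), nn.BatchNorm2d(8),
        )
        self.decoder = nn.Sequential(
            nn.ConvTranspose2d(8, 16, rng), nn.ReLU(), nn.BatchNorm2d(16),
            nn.ConvTranspose2d(16, 16, rng), nn.ReLU(), nn.BatchNorm2d(16),
            nn.ConvTranspose2d(16, 16, rng), nn.ReLU(), nn.BatchNorm2d(16),
            nn.Conv2d(16, 1, 4, 0, rng),
            nn.CenterCrop2d(*SPECTROGRAM_SHAPE),
        )
        self.model = nn.Sequential(*self.encoder.layers, *self.decoder.layers)

    # -- plumbing ---------------------------------------------------------

    def params(self):
        return self.model.params()

    def train(self, mode: bool = True):
        self.model.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @staticmethod
    def _to_nhwc(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.shape[-2:] != SPECTROGRAM_SHAPE:
            raise ValueError(
                f"expected spectrograms of shape {SPECTROGRAM_SHAPE}, "
                f"got {x.shape}")
        if x.ndim == 2:
            x = x[None]
        elif x.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D input, got {x.ndim}-D")
        return x[..., None]

    # -- forward passes ---------------------------------------------------

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        """Reconstruction(s) of one (1025, 586) image or a batch of them."""
        squeeze = np.asarray(images).ndim == 2
        out = self.model.forward(self._to_nhwc(images))[..., 0].copy()
        return out[0] if squeeze else out

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Bottleneck representation, (8, 129, 74) per image."""
        squeeze = np.asarray(images).ndim == 2
        z = self.encoder.forward(self._to_nhwc(images))
        z = np.transpose(z, (0, 3, 1, 2)).copy()  # -> (batch, C, H, W)
        return z[0] if squeeze else z

    # -- serialization ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i}"] = p.value
        for i, layer in enumerate(self.model.layers):
            if isinstance(layer, nn.BatchNorm2d):
                state[f"bn_{i}_mean"] = layer.running_mean
                state[f"bn_{i}_var"] = layer.running_var
        return state

    def load_state_dict(self, state) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, layer in enumerate(self.model.layers):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = np.asarray(state[f"bn_{i}_mean"])
                layer.running_var = np.asarray(state[f"bn_{i}_var"])

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    @classmethod
    def load(cls, path, seed: int = 0) -> "ConvAutoencoder":
        model = cls(seed=seed)
        with np.load(path) as state:
            model.load_state_dict(state)
        return model


def build_autoencoder(seed: int = 0) -> ConvAutoencoder:
    """Construct the autoencoder with seed-determined initial weights."""
    return ConvAutoencoder(seed=seed)


def train_autoencoder(model: ConvAutoencoder, spectrograms,
                      config: AeTrainConfig | None = None) -> list[float]:
    """Train for reconstruction; returns the mean loss per epoch.

    ``spectrograms`` is a sequence of (1025, 586) images. Training shuffles
    the images each epoch and aborts with diagnostics if the loss turns
    non-finite.
    """
    config = config or AeTrainConfig()
    images = [np.asarray(s, dtype=np.float32) for s in spectrograms]
    if len(images) < 2:
        raise ValueError("need at least 2 training images")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    model.train()
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [images[i] for i in order[start:start + config.batch_size]]
            x = model._to_nhwc(np.stack(batch))
            opt.zero_grad()
            recon = model.model.forward(x)
            loss, grad = nn.mse_loss(recon, x)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite reconstruction loss {loss} at epoch "
                    f"{epoch + 1}, step {start // config.batch_size}")
            model.model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.eval()
    return history


def encode(model: ConvAutoencoder, spectrogram: np.ndarray) -> np.ndarray:
    """Bottleneck tensor (8, 129, 74) of one spectrogram (inference mode)."""
    model.eval()
    return model.encode(spectrogram)


def encode_batch(model: ConvAutoencoder, spectrograms,
                 flatten: bool = True) -> np.ndarray:
    """Encode many spectrograms; (n, 76368) if ``flatten`` else (n, 8, 129, 74)."""
    model.eval()
    out = [model.encode(np.asarray(s)) for s in spectrograms]
    z = np.stack(out)
    return z.reshape(len(out), -1) if flatten else z


def _check_pair(reference, reconstruction):
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(reconstruction, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(reference: np.ndarray, reconstruction: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for images in [0, 1] (peak = 1).

    ``10 * log10(1 / MSE)``; identical images return ``inf``.
    """
    a, b = _check_pair(reference, reconstruction)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def ssim(reference: np.ndarray, reconstruction: np.ndarray) -> float:
    """Structural similarity index (7x7 windows, data range 1); 1 is ideal."""
    a, b = _check_pair(reference, reconstruction)
    return float(structural_similarity(a, b, data_range=1.0, win_size=7))
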