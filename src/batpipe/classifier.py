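"""Compact CNN classifier over MFCC matrices.

Three convolutional blocks (3x3/16, 3x3/32, 2x2/32 channels, stride 1, each
followed by ReLU, 2x2 stride-2 max pooling and batch normalization) feed a
128-unit fully connected hidden layer and a K-way output with sigmoid
activations. On the (20, 586) MFCC input the feature maps shrink
20x586 -> 10x293 -> 5x146 -> 2x73, giving a 4672-dimensional flattened
feature vector — a deliberately small model.

Training uses per-class binary cross-entropy against one-hot targets with
ADAM at learning rate 1e-4 and batch size 32. The standard epoch budgets
are 10 for bat/noise detection, 50 for genus and 25 for species
identification. Reported scores average five independently seeded runs.
Prediction takes the argmax of the sigmoid scores, breaking exact ties
toward the lowest class index.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .preprocessing import MFCC_SHAPE

__all__ = [
    "TASK_EPOCHS",
    "ClfTrainConfig",
    "Prediction",
    "CnnClassifier",
    "build_classifier",
    "train_classifier",
    "train_runs",
    "predict",
    "normalize_mfcc",
]

#: standard epoch budgets per classification task
TASK_EPOCHS = {"batnoise": 10, "genus": 50, "species": 25}

_HIDDEN = 128
_FLAT = 32 * 2 * 73  # feature maps flattened after the third pooling


@dataclasses.dataclass
class ClfTrainConfig:
    """Training settings; the defaults are the reference settings."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 25
    n_runs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "ClfTrainConfig":
        if task not in TASK_EPOCHS:
            raise ValueError(f"unknown task {task!r}; "
                             f"expected one of {sorted(TASK_EPOCHS)}")
        overrides.setdefault("epochs", TASK_EPOCHS[task])
        return cls(**overrides)


@dataclasses.dataclass
class Prediction:
    """Per-class sigmoid scores and the argmax label index."""

    scores: np.ndarray
    label: int


def normalize_mfcc(mfcc: np.ndarray) -> np.ndarray:
    """Standardize one MFCC matrix to zero mean / unit variance (guarded)."""
    m = np.asarray(mfcc, dtype=np.float32)
    std = float(m.std())
    if std < 1e-8:
        return np.zeros_like(m)
    return (m - m.mean()) / std


class CnnClassifier:
    """The compact CNN over (20, 586) MFCC inputs."""

    input_shape = MFCC_SHAPE

    def __init__(self, n_classes: int, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 output classes")
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.model = nn.Sequential(
            nn.Conv2d(1, 16, 3, 1, rng, input_grad=False),
            nn.ReLU(), nn.MaxPool2d(), nn.BatchNorm2d(16),
            nn.Conv2d(16, 32, 3, 1, rng),
            nn.ReLU(), nn.MaxPool2d(), nn.BatchNorm2d(32),
            # 2x2 kernel keeps 5x146 via asymmetric (bottom/right) padding
            nn.Conv2d(32, 32, (2, 2), (0, 1, 0, 1), rng),
            nn.ReLU(), nn.MaxPool2d(), nn.BatchNorm2d(32),
            nn.Flatten(),
            nn.Linear(_FLAT, _HIDDEN, rng),
            nn.ReLU(),
            nn.Linear(_HIDDEN, n_classes, rng),
        )

    def params(self):
        return self.model.params()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def train(self, mode: bool = True):
        self.model.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @staticmethod
    def _to_nhwc(mfccs: np.ndarray) -> np.ndarray:
        x = np.asarray(mfccs, dtype=np.float32)
        if x.shape[-2:] != MFCC_SHAPE:
            raise ValueError(
                f"expected MFCC input of shape {MFCC_SHAPE}, got {x.shape}")
        if x.ndim == 2:
            x = x[None]
        elif x.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D input, got {x.ndim}-D")
        return x[..., None]

    def logits(self, mfccs: np.ndarray) -> np.ndarray:
        return self.model.forward(self._to_nhwc(mfccs))

    def scores(self, mfccs: np.ndarray) -> np.ndarray:
        """Per-class sigmoid scores, shape (batch, K), each in (0, 1)."""
        return nn.sigmoid(self.logits(mfccs))

    def feature_map_shapes(self) -> list[tuple[int, int]]:
        """Spatial shape after each pooling stage (small-model audit)."""
        shapes = []
        h, w = MFCC_SHAPE
        for layer in self.model.layers:
            if isinstance(layer, nn.Conv2d):
                h, w = layer.out_shape(h, w)
            elif isinstance(layer, nn.MaxPool2d):
                h, w = layer.out_shape(h, w)
                shapes.append((h, w))
        return shapes

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"n_classes": np.array(self.n_classes)}
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
    def load(cls, path) -> "CnnClassifier":
        with np.load(path) as state:
            model = cls(int(state["n_classes"]))
            model.load_state_dict(state)
        return model


def build_classifier(n_classes: int, seed: int = 0) -> CnnClassifier:
    return CnnClassifier(n_classes, seed=seed)


def train_classifier(model: CnnClassifier, mfccs: np.ndarray,
                     labels: np.ndarray,
                     config: ClfTrainConfig | None = None) -> list[float]:
    """Train one model; returns the mean loss per epoch.

    ``mfccs`` is (n, 20, 586) (normalize with :func:`normalize_mfcc`
    beforehand); ``labels`` are integer class indices. Every class in
    ``range(n_classes)`` must be present.
    """
    config = config or ClfTrainConfig()
    x = np.asarray(mfccs, dtype=np.float32)
    y = np.asarray(labels)
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(model.n_classes)) - present)
    if missing:
        raise ValueError(f"classes absent from the training data: {missing}")
    if not present <= set(range(model.n_classes)):
        raise ValueError(f"label outside [0, {model.n_classes}): "
                         f"{sorted(present - set(range(model.n_classes)))}")
    onehot = np.eye(model.n_classes, dtype=np.float32)[y]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    model.train()
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.logits(x[idx])
            loss, grad = nn.bce_with_logits(logits, onehot[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss {loss}")
            model.model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.eval()
    return history


def train_runs(mfccs: np.ndarray, labels: np.ndarray, n_classes: int,
               config: ClfTrainConfig | None = None
               ) -> list[tuple[CnnClassifier, list[float]]]:
    """Train ``config.n_runs`` independently seeded models on one dataset."""
    config = config or ClfTrainConfig()
    results = []
    for run in range(config.n_runs):
        run_seed = (config.seed + 7919 * run) % (2 ** 31)
        model = build_classifier(n_classes, seed=run_seed)
        run_config = dataclasses.replace(config, seed=run_seed)
        history = train_classifier(model, mfccs, labels, run_config)
        results.append((model, history))
    return results


def predict(model: CnnClassifier, mfccs: np.ndarray) -> list[Prediction]:
    """Predictions for a batch (order-preserving, deterministic).

    The label is the argmax of the sigmoid scores; exact ties resolve to
    the lowest class index.
    """
    model.eval()
    scores = model.scores(mfccs)
    return [Prediction(scores=s.copy(), label=int(np.argmax(s)))
            for s in scores]


def predict_labels(model: CnnClassifier, mfccs: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Argmax labels for a large batch, evaluated in chunks."""
    model.eval()
    x = np.asarray(mfccs, dtype=np.float32)
    out = []
    for start in range(0, len(x), batch_size):
        out.append(np.argmax(model.scores(x[start:start + batch_size]), axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)
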