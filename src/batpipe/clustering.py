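"""UMAP embedding of autoencoder latents, with hyperparameter grid search.

The two UMAP hyperparameters that matter here are the neighbor count
(emphasis on global vs. local structure) and the minimum distance between
embedded points. Because the right pair depends on the geometry of each
dataset composition, every experiment runs an exhaustive grid search. The
reference workflow selected the best pair visually; here selection is
automated with the silhouette score on the known grouping (height,
collection, genus or noise family), and the embeddings remain exportable
for visual inspection.

Latent vectors are the flattened (76,368-value) autoencoder bottlenecks;
their reduced size relative to raw spectrograms (~87%) is what keeps the
grid search affordable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .autoencoder import AeTrainConfig, build_autoencoder, encode_batch, \
    train_autoencoder
from .preprocessing import compute_spectrogram, recycle_segments
from .taxonomy import EXCLUDED, NOISE, map_to_genus

__all__ = [
    "UmapConfig",
    "Embedding2D",
    "GridSearchResult",
    "DEFAULT_GRID",
    "embed_latents",
    "grid_search_umap",
    "run_noise_by_height",
    "run_noise_by_collection",
    "run_genus_vs_noise",
]

#: default hyperparameter grid (neighbor counts x minimum distances)
DEFAULT_GRID = {
    "n_neighbors": (5, 15, 30, 50, 100),
    "min_dist": (0.0, 0.1, 0.25, 0.5),
}


@dataclasses.dataclass(frozen=True)
class UmapConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not (0.0 <= self.min_dist < 1.0):
            raise ValueError("min_dist must be in [0, 1)")


@dataclasses.dataclass
class Embedding2D:
    """2-D coordinates plus the group label of every embedded sample."""

    coords: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) group labels
    config: UmapConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "label": self.labels,
            "n_neighbors": self.config.n_neighbors,
            "min_dist": self.config.min_dist,
        })

    def silhouette(self) -> float | None:
        """Silhouette of the known grouping; None if undefined (one group)."""
        if len(np.unique(self.labels)) < 2:
            return None
        return float(silhouette_score(self.coords, self.labels))

    def save_plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        for label in np.unique(self.labels):
            mask = self.labels == label
            ax.scatter(self.coords[mask, 0], self.coords[mask, 1],
                       s=6, alpha=0.7, label=str(label))
        ax.legend(markerscale=2, fontsize=8)
        ax.set_title(f"n_neighbors={self.config.n_neighbors}, "
                     f"min_dist={self.config.min_dist}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclasses.dataclass
class GridSearchResult:
    """All grid-cell embeddings with scores, and the winning configuration."""

    embeddings: list[Embedding2D]
    scores: list[float | None]
    best_index: int

    @property
    def best(self) -> Embedding2D:
        return self.embeddings[self.best_index]

    @property
    def best_score(self) -> float:
        return self.scores[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (emb, score) in enumerate(zip(self.embeddings, self.scores)):
            rows.append({
                "n_neighbors": emb.config.n_neighbors,
                "min_dist": emb.config.min_dist,
                "silhouette": np.nan if score is None else score,
                "best": i == self.best_index,
            })
        return pd.DataFrame(rows)


def embed_latents(latents: np.ndarray, config: UmapConfig) -> np.ndarray:
    """UMAP 2-D projection of latent vectors; deterministic under the seed."""
    import umap  # deferred: the import JIT-compiles and is slow

    x = np.asarray(latents, dtype=np.float32)
    if x.ndim != 2:
        x = x.reshape(len(x), -1)
    if len(x) < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {config.n_neighbors + 1} "
            f"samples, got {len(x)}")
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # determinism is exactly what we want
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=config.n_neighbors,
                            min_dist=config.min_dist, n_components=2,
                            random_state=config.seed)
        coords = reducer.fit_transform(x)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return np.asarray(coords, dtype=np.float64)


def _iter_grid(grid) -> list[tuple[int, float]]:
    cells = [(int(k), float(d)) for k in grid["n_neighbors"]
             for d in grid["min_dist"]]
    if not cells:
        raise ValueError("empty hyperparameter grid")
    return cells


def grid_search_umap(latents: np.ndarray, labels: np.ndarray,
                     grid=None, seed: int = 0) -> GridSearchResult:
    """Evaluate every grid cell; best = highest silhouette on the labels.

    Ties break toward smaller ``n_neighbors``, then smaller ``min_dist``
    (the iteration order). Cells where the silhouette is undefined (all
    labels identical) are recorded with a ``None`` score and skipped.
    """
    labels = np.asarray(labels)
    embeddings, scores = [], []
    for n_neighbors, min_dist in _iter_grid(grid or DEFAULT_GRID):
        config = UmapConfig(n_neighbors=n_neighbors, min_dist=min_dist,
                            seed=seed)
        coords = embed_latents(latents, config)
        emb = Embedding2D(coords=coords, labels=labels, config=config)
        embeddings.append(emb)
        scores.append(emb.silhouette())
    valid = [i for i, s in enumerate(scores) if s is not None]
    if not valid:
        raise ValueError("silhouette undefined for every grid cell "
                         "(all group labels identical)")
    best = max(valid, key=lambda i: scores[i])
    return GridSearchResult(embeddings=embeddings, scores=scores,
                            best_index=best)


def _noise_spectrograms_by_height(recordings, rng):
    by_height: dict[int, list] = {}
    for rec in recordings:
        if rec.class_label != NOISE:
            continue
        for seg in recycle_segments(rec):
            by_height.setdefault(rec.height_m, []).append(seg)
    return by_height


def _sample(pool, n, rng, what):
    idx = np.arange(len(pool))
    if len(pool) >= n:
        pick = rng.choice(idx, size=n, replace=False)
    else:
        warnings.warn(f"only {len(pool)} {what} available; sampling "
                      f"{n} with replacement")
        pick = rng.choice(idx, size=n, replace=True)
    return [pool[i] for i in pick]


def run_noise_by_height(recordings, n_train: int = 250, n_embed: int = 250,
                        seed: int = 0, ae_config: AeTrainConfig | None = None,
                        grid=None) -> GridSearchResult:
    """Noise-structure clustering across measurement heights.

    For each height, ``n_train`` random noise spectrograms train the
    autoencoder and ``n_embed`` further spectrograms (disjoint from the
    training draw when enough data exist) are encoded and embedded, grouped
    by height. Heights with no noise segments are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    by_height = _noise_spectrograms_by_height(recordings, rng)
    if not by_height:
        raise ValueError("no noise segments in the supplied recordings")
    train_specs, embed_specs, heights = [], [], []
    for height in sorted(by_height):
        pool = by_height[height]
        if not pool:  # pragma: no cover - empty keys are never created
            warnings.warn(f"height {height} m has no noise segments; omitted")
            continue
        picked = _sample(pool, n_train + n_embed, rng,
                         f"noise segments at {height} m")
        train_part, embed_part = picked[:n_train], picked[n_train:]
        train_specs += [compute_spectrogram(s.samples) for s in train_part]
        embed_specs += [compute_spectrogram(s.samples) for s in embed_part]
        heights += [height] * len(embed_part)
    ae = build_autoencoder(seed=seed)
    train_autoencoder(ae, train_specs, ae_config or AeTrainConfig(seed=seed))
    latents = encode_batch(ae, embed_specs)
    return grid_search_umap(latents, np.asarray(heights), grid=grid, seed=seed)


def run_noise_by_collection(recordings, n_train: int = 250,
                            n_embed: int = 250, seed: int = 0,
                            ae_config: AeTrainConfig | None = None,
                            grid=None) -> GridSearchResult:
    """Noise-structure clustering across collections (heights combined).

    Same protocol as :func:`run_noise_by_height`, but the grouping is the
    location-year collection id: per collection, ``n_train`` noise
    spectrograms train the autoencoder and a further ``n_embed`` are
    encoded and embedded. This is the view that shows which collections
    share a noise signature.
    """
    rng = np.random.default_rng(seed)
    by_collection: dict[str, list] = {}
    for rec in recordings:
        if rec.class_label != NOISE:
            continue
        for seg in recycle_segments(rec):
            by_collection.setdefault(rec.collection, []).append(seg)
    if not by_collection:
        raise ValueError("no noise segments in the supplied recordings")
    train_specs, embed_specs, groups = [], [], []
    for cid in sorted(by_collection):
        picked = _sample(by_collection[cid], n_train + n_embed, rng,
                         f"noise segments in collection {cid!r}")
        train_specs += [compute_spectrogram(s.samples)
                        for s in picked[:n_train]]
        embed_part = picked[n_train:]
        embed_specs += [compute_spectrogram(s.samples) for s in embed_part]
        groups += [cid] * len(embed_part)
    ae = build_autoencoder(seed=seed)
    train_autoencoder(ae, train_specs, ae_config or AeTrainConfig(seed=seed))
    latents = encode_batch(ae, embed_specs)
    return grid_search_umap(latents, np.asarray(groups), grid=grid, seed=seed)


def run_genus_vs_noise(recordings, per_class_n: int = 250, seed: int = 0,
                       ae_config: AeTrainConfig | None = None,
                       grid=None) -> GridSearchResult:
    """Joint clustering of the four genus-level classes against noise.

    Bat recordings are mapped to genus-level classes; ``per_class_n``
    segments per group (genera + noise) are drawn, the autoencoder is
    trained on all of them, and the same spectrograms are encoded and
    embedded with 5 group labels. The reference range for ``per_class_n``
    is 100-500; values outside it trigger a warning. Genera with no data
    are omitted with a warning; an empty noise pool is an error.
    """
    if not (100 <= per_class_n <= 500):
        warnings.warn(f"per_class_n={per_class_n} is outside the standard "
                      "range [100, 500]")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list] = {}
    for rec in recordings:
        group = NOISE if rec.class_label == NOISE \
            else map_to_genus(rec.class_label)
        if group == EXCLUDED:
            continue
        for seg in recycle_segments(rec):
            by_group.setdefault(group, []).append(seg)
    if NOISE not in by_group:
        raise ValueError("no noise segments available")
    for genus in ("Pipistrellus", "Nyctaloid", "Myotis", "Plecotus"):
        if genus not in by_group:
            warnings.warn(f"genus {genus} has no recordings; omitted")
    specs, groups = [], []
    for group in sorted(by_group):
        picked = _sample(by_group[group], per_class_n, rng,
                         f"{group} segments")
        specs += [compute_spectrogram(s.samples) for s in picked]
        groups += [group] * len(picked)
    ae = build_autoencoder(seed=seed)
    train_autoencoder(ae, specs, ae_config or AeTrainConfig(seed=seed))
    latents = encode_batch(ae, specs)
    return grid_search_umap(latents, np.asarray(groups), grid=grid, seed=seed)
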