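"""Pipeline configuration, validation and orchestration.

A pipeline run goes simulate -> preprocess -> train-ae -> cluster ->
train-clf -> evaluate. Configuration is a plain nested mapping (usually
parsed from YAML); unset keys take the reference defaults (ADAM at 1e-4,
autoencoder batch 1 / 10 epochs, classifier batch 32 with per-task epoch
budgets 10/50/25, split 60:20:20). One global seed fans out to per-stage
seeds through a stable hash, so every stage is independently reproducible.

Each output directory receives a run manifest recording the config
snapshot, package version, derived seeds and produced artifacts; re-running
with an unchanged config skips stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .audio_io import read_catalog
from .autoencoder import AeTrainConfig, build_autoencoder, encode_batch, \
    train_autoencoder
from .classifier import ClfTrainConfig, TASK_EPOCHS
from .clustering import DEFAULT_GRID, grid_search_umap
from .evaluation import SegmentDataset, dataset_from_recordings, joined_eval
from .preprocessing import compute_spectrogram, recycle_segments
from .synthetic import CollectionConfig, scale_class_mix, synth_collection, \
    synth_corpus
from .taxonomy import NOISE

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigError",
    "validate_config",
    "load_config",
    "stage_seed",
    "run_pipeline",
]


class ConfigError(ValueError):
    """A configuration value failed validation."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


_SIM_DEFAULTS = {
    "collections": {
        "east_2019": {"P_pip": 20, "P_nat": 10, "N_noc": 10, "noise": 20},
        "west_2019": {"P_pip": 20, "P_nat": 10, "N_noc": 10, "noise": 20},
    },
    "scale": 1.0,
    "bat_duration_range_s": [2.0, 6.0],
    "noise_duration_range_s": [1.0, 4.0],
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    data_dir: str = "data"
    out_dir: str = "outputs"
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    simulate: dict = dataclasses.field(
        default_factory=lambda: json.loads(json.dumps(_SIM_DEFAULTS)))
    ae: AeTrainConfig = dataclasses.field(default_factory=AeTrainConfig)
    clf: ClfTrainConfig = dataclasses.field(default_factory=ClfTrainConfig)
    clf_task: str = "species"
    ae_train_images: int = 250
    umap_grid: dict = dataclasses.field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    cluster_samples: int = 250

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratios"] = list(self.split_ratios)
        return d


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig`, injecting defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key. An empty mapping yields the full default config.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key in ("data_dir", "out_dir", "clf_task"):
        if key in raw:
            kwargs[key] = str(raw[key])
    if kwargs.get("clf_task", "species") not in TASK_EPOCHS:
        raise ConfigError(f"clf_task must be one of {sorted(TASK_EPOCHS)}")
    if "seed" in raw:
        seed = int(raw["seed"])
        if seed < 0:
            raise ConfigError("seed must be >= 0")
        kwargs["seed"] = seed
    if "split_ratios" in raw:
        ratios = tuple(float(r) for r in raw["split_ratios"])
        if len(ratios) != 3 or any(r < 0 for r in ratios) \
                or abs(sum(ratios) - 1.0) > 1e-9:
            raise ConfigError(
                f"split_ratios must be three non-negative values summing "
                f"to 1, got {ratios}")
        kwargs["split_ratios"] = ratios
    for key, cls in (("ae", AeTrainConfig), ("clf", ClfTrainConfig)):
        section = dict(raw.get(key, {}))
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ConfigError(f"unknown {key} keys: {sorted(unknown)}")
        if key == "clf":
            # unset epochs default to the task's standard budget
            section.setdefault(
                "epochs", TASK_EPOCHS[kwargs.get("clf_task", "species")])
        try:
            kwargs[key] = cls(**section)
        except ValueError as exc:
            raise ConfigError(f"invalid {key} configuration: {exc}") from exc
    for key in ("ae_train_images", "cluster_samples"):
        if key in raw:
            value = int(raw[key])
            if value < 2:
                raise ConfigError(f"{key} must be >= 2")
            kwargs[key] = value
    if "simulate" in raw:
        kwargs["simulate"] = dict(raw["simulate"])
    if "umap_grid" in raw:
        grid = dict(raw["umap_grid"])
        if set(grid) != {"n_neighbors", "min_dist"}:
            raise ConfigError(
                "umap_grid must define n_neighbors and min_dist lists")
        kwargs["umap_grid"] = grid
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, artifacts, timings."""

    config: dict
    version: str
    seeds: dict
    artifacts: dict
    timings_s: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _config_digest(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage_cached(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / "stage.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("digest") == digest
    except (ValueError, OSError):
        return False


def _mark_stage(stage_dir: Path, digest: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "stage.json").write_text(json.dumps({"digest": digest}))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis flow on a simulated corpus.

    Stages: simulate the configured collections; featurize; train the
    autoencoder on noise spectrograms; grid-search a UMAP embedding of the
    latents; train and evaluate the configured classifier task on the
    joined data. Cached stages (same config digest) are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage)
             for stage in ("simulate", "split", "ae", "cluster", "clf")}
    artifacts: dict = {}
    timings: dict = {}

    # -- simulate ---------------------------------------------------------
    t0 = time.time()
    sim = config.simulate
    sim_digest = _config_digest([sim, seeds["simulate"]])
    data_dir = Path(config.data_dir)
    catalogs = {}
    recordings = {}
    for i, (cid, mix) in enumerate(sorted(sim["collections"].items())):
        mix = scale_class_mix(mix, float(sim.get("scale", 1.0)))
        cc = CollectionConfig(
            collection_id=cid, class_mix=mix,
            seed=(seeds["simulate"] + i) % 2 ** 31,
            bat_duration_range_s=tuple(sim.get("bat_duration_range_s",
                                               (2.0, 6.0))),
            noise_duration_range_s=tuple(sim.get("noise_duration_range_s",
                                                 (1.0, 4.0))),
        )
        col_dir = data_dir / cid
        if _stage_cached(col_dir, sim_digest):
            catalogs[cid] = read_catalog(col_dir / cid / "manifest.csv") \
                if (col_dir / cid / "manifest.csv").exists() \
                else read_catalog(col_dir / "manifest.csv")
            recordings[cid], _ = synth_corpus(cc)  # deterministic re-synthesis
        else:
            recordings[cid], _ = synth_corpus(cc)
            catalogs[cid] = synth_collection(cc, col_dir)
            _mark_stage(col_dir, sim_digest)
        artifacts[f"catalog_{cid}"] = str(col_dir / "manifest.csv")
    timings["simulate"] = time.time() - t0

    # -- preprocess (featurize) ------------------------------------------
    t0 = time.time()
    all_recs = [r for cid in sorted(recordings) for r in recordings[cid]]
    dataset = dataset_from_recordings(all_recs)
    timings["preprocess"] = time.time() - t0
    artifacts["n_segments"] = len(dataset)

    # -- autoencoder on noise spectrograms -------------------------------
    t0 = time.time()
    rng = np.random.default_rng(seeds["ae"])
    noise_segments = []
    for rec in all_recs:
        if rec.class_label == NOISE:
            noise_segments.extend(recycle_segments(rec))
    if len(noise_segments) < 2:
        raise RuntimeError("pipeline stage train-ae: no noise segments "
                           "in the simulated corpus")
    n_train = min(config.ae_train_images, len(noise_segments))
    pick = rng.choice(len(noise_segments), size=n_train, replace=False)
    specs = [compute_spectrogram(noise_segments[i].samples) for i in pick]
    ae = build_autoencoder(seed=seeds["ae"])
    ae_config = dataclasses.replace(config.ae, seed=seeds["ae"])
    history = train_autoencoder(ae, specs, ae_config)
    ae_path = out / "autoencoder.npz"
    ae.save(ae_path)
    artifacts["autoencoder"] = str(ae_path)
    artifacts["ae_loss_history"] = history
    timings["train_ae"] = time.time() - t0

    # -- clustering -------------------------------------------------------
    t0 = time.time()
    n_embed = min(config.cluster_samples, len(noise_segments))
    pick = rng.choice(len(noise_segments), size=n_embed, replace=False)
    latents = encode_batch(
        ae, [compute_spectrogram(noise_segments[i].samples) for i in pick])
    groups = np.asarray([noise_segments[i].collection for i in pick])
    if len(np.unique(groups)) < 2:
        groups = np.asarray([noise_segments[i].height_m for i in pick])
    search = grid_search_umap(latents, groups, grid=config.umap_grid,
                              seed=seeds["cluster"])
    emb_path = out / "embedding.csv"
    search.best.to_frame().to_csv(emb_path, index=False)
    search.to_frame().to_csv(out / "umap_grid.csv", index=False)
    artifacts["embedding"] = str(emb_path)
    artifacts["umap_best"] = {
        "n_neighbors": search.best.config.n_neighbors,
        "min_dist": search.best.config.min_dist,
        "silhouette": search.best_score,
    }
    timings["cluster"] = time.time() - t0

    # -- classification ---------------------------------------------------
    t0 = time.time()
    clf_config = dataclasses.replace(config.clf, seed=seeds["clf"])
    report = joined_eval(dataset, config.clf_task, clf_config,
                         seed=seeds["split"])
    report_path = out / f"report_{config.clf_task}.json"
    report.to_json(report_path)
    report.to_csv(out / f"report_{config.clf_task}.csv")
    artifacts["report"] = str(report_path)
    timings["train_clf"] = time.time() - t0

    manifest = RunManifest(
        config=config.to_dict(), version=__version__, seeds=seeds,
        artifacts=artifacts, timings_s=timings)
    manifest.save(out / "manifest.json")
    return manifest
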