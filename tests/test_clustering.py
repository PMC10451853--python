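"""UMAP embedding determinism, grid search and the clustering runners."""

import numpy as np
import pytest

from batpipe import synthetic as syn
from batpipe.autoencoder import AeTrainConfig
from batpipe.clustering import (Embedding2D, GridSearchResult, UmapConfig,
                                embed_latents, grid_search_umap,
                                run_genus_vs_noise, run_noise_by_height)

TINY_GRID = {"n_neighbors": (5,), "min_dist": (0.1,)}


def _two_blobs(rng, n=60, dim=20, separation=8.0):
    a = rng.standard_normal((n // 2, dim))
    b = rng.standard_normal((n // 2, dim)) + separation / np.sqrt(dim)
    labels = np.repeat(["a", "b"], n // 2)
    return np.concatenate([a, b]), labels


class TestEmbedLatents:
    def test_deterministic_under_seed(self, rng):
        x, _ = _two_blobs(np.random.default_rng(0))
        config = UmapConfig(n_neighbors=10, min_dist=0.1, seed=3)
        np.testing.assert_array_equal(embed_latents(x, config),
                                      embed_latents(x, config))

    def test_separated_groups_have_positive_silhouette(self):
        x, labels = _two_blobs(np.random.default_rng(1))
        coords = embed_latents(x, UmapConfig(n_neighbors=10, seed=0))
        emb = Embedding2D(coords, labels, UmapConfig(n_neighbors=10, seed=0))
        assert emb.silhouette() > 0

    def test_too_few_samples_rejected(self):
        x = np.zeros((5, 10))
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_latents(x, UmapConfig(n_neighbors=10))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UmapConfig(n_neighbors=1)
        with pytest.raises(ValueError):
            UmapConfig(min_dist=1.0)


class TestGridSearch:
    def test_grid_cardinality_and_best_selection(self):
        x, labels = _two_blobs(np.random.default_rng(2))
        grid = {"n_neighbors": (5, 10), "min_dist": (0.0, 0.25)}
        result = grid_search_umap(x, labels, grid=grid, seed=0)
        assert len(result.embeddings) == 4
        valid = [s for s in result.scores if s is not None]
        assert result.best_score == max(valid)
        frame = result.to_frame()
        assert frame["best"].sum() == 1

    def test_identical_labels_rejected(self):
        x, _ = _two_blobs(np.random.default_rng(3))
        with pytest.raises(ValueError, match="identical"):
            grid_search_umap(x, np.zeros(len(x)), grid=TINY_GRID, seed=0)

    def test_empty_grid_rejected(self):
        x, labels = _two_blobs(np.random.default_rng(4))
        with pytest.raises(ValueError, match="empty"):
            grid_search_umap(x, labels,
                             grid={"n_neighbors": (), "min_dist": ()})

    def test_best_beats_permutation_null(self):
        """Constructed group structure scores above chance: the best
        silhouette exceeds that of a random label permutation."""
        rng = np.random.default_rng(5)
        x, labels = _two_blobs(rng)
        result = grid_search_umap(x, labels, grid=TINY_GRID, seed=0)
        permuted = rng.permutation(labels)
        null = Embedding2D(result.best.coords, permuted,
                           result.best.config).silhouette()
        assert result.best_score > null


def _noise_collection(tonal_heights=(10,), broadband_heights=(35,),
                      n_per_height=8, seed=0):
    """Noise recordings with height-specific structural profiles."""
    rng = np.random.default_rng(seed)
    recordings = []
    for height in tonal_heights:
        for _ in range(n_per_height):
            recordings.append(syn.synth_noise(
                syn.tonal_profile(30.0), 2.0, rng,
                collection="east_2019", height_m=height))
    for height in broadband_heights:
        for _ in range(n_per_height):
            recordings.append(syn.synth_noise(
                syn.transient_profile(8.0), 2.0, rng,
                collection="east_2019", height_m=height))
    return recordings


class TestRunners:
    def test_noise_by_height_separates_distinct_profiles(self):
        """Heights with different noise structure separate in the embedding
        (positive silhouette on height labels)."""
        recordings = _noise_collection(n_per_height=8, seed=7)
        result = run_noise_by_height(
            recordings, n_train=6, n_embed=10, seed=0,
            ae_config=AeTrainConfig(epochs=1, seed=0), grid=TINY_GRID)
        assert isinstance(result, GridSearchResult)
        emb = result.best
        assert sorted(set(emb.labels)) == [10, 35]
        assert len(emb.coords) == 20
        assert result.best_score > 0

    def test_noise_by_collection_separates_distinct_signatures(self):
        """Collections with different noise mixtures separate in the
        cross-collection embedding."""
        from batpipe.clustering import run_noise_by_collection
        rng = np.random.default_rng(21)
        recordings = [syn.synth_noise(syn.tonal_profile(30.0), 2.0, rng,
                                      collection="east_2019")
                      for _ in range(8)]
        recordings += [syn.synth_noise(syn.transient_profile(8.0), 2.0, rng,
                                       collection="west_2020")
                       for _ in range(8)]
        result = run_noise_by_collection(
            recordings, n_train=6, n_embed=10, seed=0,
            ae_config=AeTrainConfig(epochs=1, seed=0), grid=TINY_GRID)
        assert sorted(set(result.best.labels)) == ["east_2019", "west_2020"]
        assert len(result.best.coords) == 20
        assert result.best_score > 0

    def test_noise_by_height_requires_noise(self):
        rng = np.random.default_rng(0)
        bats = [syn.synth_pulse_train("P_pip", 2.0, rng)]
        with pytest.raises(ValueError, match="no noise"):
            run_noise_by_height(bats, n_train=2, n_embed=2,
                                ae_config=AeTrainConfig(epochs=1))

    def test_small_pool_warns_and_samples_with_replacement(self):
        recordings = _noise_collection(n_per_height=2, seed=1)
        with pytest.warns(UserWarning, match="with replacement"):
            run_noise_by_height(
                recordings, n_train=4, n_embed=6, seed=0,
                ae_config=AeTrainConfig(epochs=1, seed=0), grid=TINY_GRID)

    def test_genus_vs_noise_groups_and_warnings(self):
        rng = np.random.default_rng(9)
        recordings = [syn.synth_pulse_train("P_pip", 2.0, rng,
                                            collection="east_2019")
                      for _ in range(6)]
        recordings += _noise_collection(n_per_height=6, seed=10)[:6]
        with pytest.warns(UserWarning) as record:
            result = run_genus_vs_noise(
                recordings, per_class_n=10, seed=0,
                ae_config=AeTrainConfig(epochs=1, seed=0), grid=TINY_GRID)
        messages = " ".join(str(w.message) for w in record)
        assert "outside the standard range" in messages  # per_class_n < 100
        assert "Myotis" in messages  # missing genus warning
        assert set(result.best.labels) == {"Pipistrellus", "noise"}

    def test_genus_vs_noise_requires_noise(self):
        rng = np.random.default_rng(2)
        bats = [syn.synth_pulse_train("P_pip", 2.0, rng) for _ in range(3)]
        with pytest.raises(ValueError, match="noise"):
            run_genus_vs_noise(bats, per_class_n=100,
                               ae_config=AeTrainConfig(epochs=1))
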