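import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # compile the numba kernels once so individual test timings are honest
    from batpipe import nn
    nn.warmup_kernels()


@pytest.fixture(scope="session")
def species_corpus():
    """Three well-separated Pipistrellus-task classes plus the P_low hybrid.

    Roughly 200 one-second segments per species class (about 70 recordings
    of 2-6 s each under the 80% recycling rule) and a smaller hybrid pool.
    Shared across the supervised-learning tests; generated once per session.
    """
    from batpipe.evaluation import dataset_from_recordings
    from batpipe.synthetic import CollectionConfig, synth_corpus

    config = CollectionConfig(
        "east_2019",
        {"P_pip": 70, "P_nat": 70, "P_pyg": 70, "P_low": 40},
        seed=20240901,
        bat_duration_range_s=(2.0, 6.0),
    )
    recordings, catalog = synth_corpus(config)
    return dataset_from_recordings(recordings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_ae_bundle():
    """Autoencoders trained on 250 noise spectrograms, plus latent pools.

    Reproduces the unsupervised study conditions at reduced scale: a mixed
    noise corpus (tonal carriers, click trains, broadband transients) is
    segmented and 250 random spectrograms train the autoencoder (ADAM,
    lr 1e-4, batch 1) for one epoch under three seeds. Held-out PSNR before
    and after training is recorded per seed. The seed-0 model encodes two
    structurally distinct noise families (and a pair of identically
    generated families) for the clustering checks.
    """
    from batpipe import synthetic as syn
    from batpipe.autoencoder import (AeTrainConfig, build_autoencoder,
                                     encode_batch, psnr, train_autoencoder)
    from batpipe.preprocessing import compute_spectrogram, recycle_segments

    rng = np.random.default_rng(777)

    def noise_segments(profile, n_recordings, duration=3.0):
        segs = []
        for _ in range(n_recordings):
            rec = syn.synth_noise(profile, duration, rng)
            segs.extend(s.samples for s in recycle_segments(rec))
        return segs

    tonal = noise_segments(syn.tonal_profile(30.0), 30)
    clicks = noise_segments(syn.click_profile(10.0), 30)
    broadband = noise_segments(syn.transient_profile(5.0), 36)
    pool = tonal + clicks + broadband
    order = rng.permutation(len(pool))
    train_specs = [compute_spectrogram(pool[i]) for i in order[:250]]
    heldout = [compute_spectrogram(pool[i]) for i in order[250:262]]

    psnr_pairs = {}
    model0 = None
    for seed in (0, 1, 2):
        model = build_autoencoder(seed=seed)
        initial = np.mean([psnr(s, model.reconstruct(s)) for s in heldout])
        train_autoencoder(model, train_specs,
                          AeTrainConfig(epochs=1, seed=seed))
        trained = np.mean([psnr(s, model.reconstruct(s)) for s in heldout])
        psnr_pairs[seed] = (float(initial), float(trained))
        if seed == 0:
            model0 = model

    def latents_of(segments):
        return encode_batch(model0, [compute_spectrogram(s)
                                     for s in segments])

    fam_tonal = noise_segments(syn.tonal_profile(30.0), 20, duration=2.0)[:40]
    fam_broad = noise_segments(syn.transient_profile(8.0), 20,
                               duration=2.0)[:40]
    ident_a = noise_segments(syn.transient_profile(5.0), 20,
                             duration=2.0)[:40]
    ident_b = noise_segments(syn.transient_profile(5.0), 20,
                             duration=2.0)[:40]
    return {
        "psnr_pairs": psnr_pairs,
        "model": model0,
        "separable_latents": np.concatenate([latents_of(fam_tonal),
                                             latents_of(fam_broad)]),
        "separable_labels": np.repeat(["tonal", "broadband"], 40),
        "identical_latents": np.concatenate([latents_of(ident_a),
                                             latents_of(ident_b)]),
        "identical_labels": np.repeat(["group_a", "group_b"], 40),
    }
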