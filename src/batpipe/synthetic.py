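"""Synthetic ultrasonic soundscape generator.

Emulates the statistical structure of triggered 300 kHz field recordings
from an acoustic bat-monitoring station: frequency-modulated echolocation
pulse trains whose frequency of maximum energy falls inside the class's
diagnostic band, plus the noise typology seen in such data — persistent
narrowband tones (e.g. a ~30 kHz carrier), periodic click trains that
visually mimic pulse trains, and non-stationary broadband transients — with
per-collection noise mixtures and class imbalance.

Pulse model: a linear FM down-sweep under a Hann amplitude envelope. The
envelope maximum sits mid-sweep, so the frequency of maximum spectral
energy is the sweep midpoint; each pulse draws that midpoint uniformly from
the interior of the class band, which keeps the measured peak inside the
band while providing intra-class variation. This is a deliberately simple
morphological stand-in, not a physically accurate call model.

Pulse trains place pulses on an interpulse-interval grid with uniform
timing jitter. The jitter amplitude is +/-20% of the interval, capped so
that consecutive pulses can never drift more than one second apart — the
generated trains therefore satisfy the one-pulse-per-second property that
the segmentation stage relies on.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import (HEIGHTS_M, SAMPLE_RATE, Recording, save_recording,
                       write_catalog)
from .taxonomy import NOISE, PEAK_BAND_KHZ, TaxonomyError

__all__ = [
    "FLOOR_RMS",
    "PulseParams",
    "NoiseProfile",
    "CollectionConfig",
    "default_pulse_params",
    "synth_pulse",
    "synth_pulse_train",
    "synth_noise",
    "synth_recording",
    "synth_corpus",
    "synth_collection",
    "scale_class_mix",
    "peak_frequency_khz",
    "tonal_profile",
    "click_profile",
    "transient_profile",
]

#: RMS of the white Gaussian noise floor every recording sits on
FLOOR_RMS = 0.003

NYQUIST_KHZ = SAMPLE_RATE / 2000.0


def _check_finite(name, value):
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclasses.dataclass
class PulseParams:
    """Waveform parameters of one echolocation pulse type."""

    class_label: str
    peak_band_khz: tuple[float, float]
    sweep_start_khz: float
    sweep_end_khz: float
    pulse_dur_ms: float
    ipi_ms: float
    snr_db: float = 30.0

    def __post_init__(self):
        lo, hi = self.peak_band_khz
        if not (0.0 < lo < hi < NYQUIST_KHZ):
            raise ValueError(
                f"peak band {self.peak_band_khz} must lie inside "
                f"(0, {NYQUIST_KHZ}) kHz with lo < hi")
        if self.sweep_start_khz < self.sweep_end_khz:
            raise ValueError("expected a down-sweep (sweep_start >= sweep_end)")
        if self.pulse_dur_ms <= 0:
            raise ValueError("pulse_dur_ms must be positive")
        if self.ipi_ms < self.pulse_dur_ms:
            raise ValueError("ipi_ms must be >= pulse_dur_ms")
        _check_finite("snr_db", self.snr_db)


#: per-class pulse duration, interpulse interval and sweep half-width.
#: Pipistrellus species emit short steep FM sweeps at fast repetition rates;
#: N. noctula and the Nyctaloid group use long shallow low-frequency pulses
#: at slow rates; Myotis uses very short broadband sweeps.
_PULSE_DEFAULTS = {  # label: (dur_ms, ipi_ms, sweep_halfwidth_khz)
    "P_pip": (5.0, 90.0, 15.0),
    "P_nat": (6.0, 110.0, 12.0),
    "P_pyg": (5.0, 80.0, 15.0),
    "N_noc": (15.0, 300.0, 5.0),
    "B_bar": (4.0, 120.0, 10.0),
    "Myotis": (3.0, 80.0, 25.0),
    "Plecotus": (4.0, 150.0, 10.0),
    "Nyctaloid": (12.0, 250.0, 7.0),
    "P_low": (5.0, 100.0, 13.0),
    "P_high": (5.0, 85.0, 14.0),
}


def default_pulse_params(class_label: str) -> PulseParams:
    """Default pulse parameters for a bat class, centered on its peak band."""
    if class_label not in _PULSE_DEFAULTS:
        raise TaxonomyError(f"no pulse model for class {class_label!r}")
    dur, ipi, half = _PULSE_DEFAULTS[class_label]
    lo, hi = PEAK_BAND_KHZ[class_label]
    center = 0.5 * (lo + hi)
    return PulseParams(
        class_label=class_label,
        peak_band_khz=(lo, hi),
        sweep_start_khz=center + half,
        sweep_end_khz=center - half,
        pulse_dur_ms=dur,
        ipi_ms=ipi,
    )


def synth_pulse(params: PulseParams, rng: np.random.Generator) -> np.ndarray:
    """Generate one FM down-sweep pulse as a float32 waveform segment.

    The sweep midpoint (= frequency of maximum energy under the Hann
    envelope) is drawn uniformly from the central 60% of the class's peak
    band, so the measured peak always falls inside the band.
    """
    n = max(8, round(params.pulse_dur_ms / 1000.0 * SAMPLE_RATE))
    lo, hi = params.peak_band_khz
    # small absolute margin: just enough to absorb windowing wobble, so
    # classes whose bands touch (species vs. hybrid) stay nearly adjacent
    margin = min(max(0.25, 0.05 * (hi - lo)), 0.45 * (hi - lo))
    f_mid = rng.uniform(lo + margin, hi - margin)
    half = 0.5 * (params.sweep_start_khz - params.sweep_end_khz)
    freqs_khz = np.linspace(f_mid + half, f_mid - half, n)
    freqs_hz = np.clip(freqs_khz, 0.5, NYQUIST_KHZ - 0.5) * 1000.0
    phase = 2.0 * np.pi * np.cumsum(freqs_hz) / SAMPLE_RATE
    envelope = np.hanning(n)
    amp = FLOOR_RMS * 10.0 ** (params.snr_db / 20.0)
    return (amp * envelope * np.sin(phase)).astype(np.float32)


def _jitter_amplitude(ipi_ms: float) -> float:
    # +/-20% of the interval, capped so consecutive pulse starts can never
    # exceed one second of separation (ipi + 2*jitter <= 1000 ms)
    return min(0.2 * ipi_ms, max(0.0, (1000.0 - ipi_ms) / 2.0))


#: hybrid labels hold calls of two species in the shared band; a hybrid
#: recording uses one parent's full pulse parameters with only the peak
#: band restricted to the overlap
_HYBRID_PARENTS = {"P_low": ("P_pip", "P_nat"), "P_high": ("P_pip", "P_pyg")}


def _hybrid_pulse_params(class_label: str,
                         rng: np.random.Generator) -> PulseParams:
    parent = _HYBRID_PARENTS[class_label][rng.integers(0, 2)]
    params = default_pulse_params(parent)
    return dataclasses.replace(params, class_label=class_label,
                               peak_band_khz=PEAK_BAND_KHZ[class_label])


def synth_pulse_train(class_label: str, duration_s: float,
                      rng: np.random.Generator,
                      params: PulseParams | None = None,
                      collection: str = "", height_m: int = 10) -> Recording:
    """Generate a triggered bat recording: a pulse train over a noise floor."""
    if not (1.0 <= duration_s <= 16.0):
        raise ValueError("duration_s must be in [1, 16]")
    if params is None:
        params = _hybrid_pulse_params(class_label, rng) \
            if class_label in _HYBRID_PARENTS \
            else default_pulse_params(class_label)
    if params.ipi_ms > 1000.0:
        raise ValueError(
            "ipi_ms > 1000 would violate the one-pulse-per-second guarantee")
    n = round(duration_s * SAMPLE_RATE)
    x = rng.normal(0.0, FLOOR_RMS, n).astype(np.float32)
    t0 = 0.002
    ipi_s = params.ipi_ms / 1000.0
    jitter_s = _jitter_amplitude(params.ipi_ms) / 1000.0
    dur_s = params.pulse_dur_ms / 1000.0
    k = 0
    while True:
        nominal = t0 + k * ipi_s
        if nominal + dur_s > duration_s:
            break
        start = nominal + rng.uniform(-jitter_s, jitter_s)
        start = min(max(start, 0.0), duration_s - dur_s)
        pulse = synth_pulse(params, rng)
        i0 = round(start * SAMPLE_RATE)
        x[i0:i0 + pulse.size] += pulse[:n - i0]
        k += 1
    return Recording(samples=np.clip(x, -1.0, 1.0), class_label=class_label,
                     collection=collection, height_m=height_m)


_NOISE_KINDS = ("stationary_tonal", "stationary_pulsed",
                "nonstationary_broadband")


@dataclasses.dataclass
class NoiseProfile:
    """One structural noise type; exactly the fields of its kind are set."""

    kind: str
    band_khz: tuple[float, float] | None = None  # (center, wander width)
    click_rate_hz: float | None = None
    transient_rate_hz: float | None = None
    level_db: float = 20.0

    def __post_init__(self):
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        _check_finite("level_db", self.level_db)
        required = {
            "stationary_tonal": "band_khz",
            "stationary_pulsed": "click_rate_hz",
            "nonstationary_broadband": "transient_rate_hz",
        }[self.kind]
        for field in ("band_khz", "click_rate_hz", "transient_rate_hz"):
            value = getattr(self, field)
            if field == required:
                if value is None:
                    raise ValueError(f"{self.kind} requires {field}")
            elif value is not None:
                raise ValueError(f"{self.kind} must not set {field}")
        if self.kind == "stationary_tonal":
            center, width = self.band_khz
            if not (0.0 < center < NYQUIST_KHZ) or width < 0:
                raise ValueError(f"invalid tonal band {self.band_khz}")
        else:
            rate = self.click_rate_hz if self.kind == "stationary_pulsed" \
                else self.transient_rate_hz
            _check_finite("rate", rate)
            if rate < 0:
                raise ValueError("rates must be >= 0")


def tonal_profile(center_khz: float = 30.0, width_khz: float = 0.5,
                  level_db: float = 20.0) -> NoiseProfile:
    return NoiseProfile("stationary_tonal", band_khz=(center_khz, width_khz),
                        level_db=level_db)


def click_profile(rate_hz: float = 10.0, level_db: float = 25.0) -> NoiseProfile:
    return NoiseProfile("stationary_pulsed", click_rate_hz=rate_hz,
                        level_db=level_db)


def transient_profile(rate_hz: float = 3.0,
                      level_db: float = 25.0) -> NoiseProfile:
    return NoiseProfile("nonstationary_broadband", transient_rate_hz=rate_hz,
                        level_db=level_db)


def _burst(n: int, rng: np.random.Generator) -> np.ndarray:
    return (rng.standard_normal(n) * np.hanning(n)).astype(np.float32)


def synth_noise(profile: NoiseProfile, duration_s: float,
                rng: np.random.Generator, collection: str = "",
                height_m: int = 10) -> Recording:
    """Generate a noise recording of one structural type over the floor."""
    if duration_s < 1.0:
        raise ValueError("duration_s must be >= 1")
    n = round(duration_s * SAMPLE_RATE)
    x = rng.normal(0.0, FLOOR_RMS, n).astype(np.float32)
    amp = FLOOR_RMS * 10.0 ** (profile.level_db / 20.0)

    if profile.kind == "stationary_tonal":
        center, width = profile.band_khz
        t = np.arange(n) / SAMPLE_RATE
        # slow sinusoidal frequency wander inside the band, slow AM
        wander = 0.5 * width * np.sin(2 * np.pi * 0.5 * t
                                      + rng.uniform(0, 2 * np.pi))
        freq_hz = (center + wander) * 1000.0
        phase = 2 * np.pi * np.cumsum(freq_hz) / SAMPLE_RATE
        am = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t
                                + rng.uniform(0, 2 * np.pi))
        x += (amp * am * np.sin(phase)).astype(np.float32)
    elif profile.kind == "stationary_pulsed":
        rate = profile.click_rate_hz
        if rate > 0:
            period = 1.0 / rate
            click_n = round(0.0015 * SAMPLE_RATE)
            t0 = rng.uniform(0, period)
            k = 0
            while True:
                start = t0 + k * period + rng.uniform(-0.05, 0.05) * period
                i0 = round(start * SAMPLE_RATE)
                if i0 + click_n > n:
                    break
                if i0 >= 0:
                    x[i0:i0 + click_n] += amp * _burst(click_n, rng)
                k += 1
    else:  # nonstationary_broadband
        rate = profile.transient_rate_hz
        n_events = rng.poisson(rate * duration_s) if rate > 0 else 0
        for _ in range(n_events):
            length = round(rng.uniform(0.010, 0.040) * SAMPLE_RATE)
            i0 = rng.integers(0, max(1, n - length))
            gain = amp * 10.0 ** (rng.uniform(-6, 6) / 20.0)
            x[i0:i0 + length] += gain * _burst(length, rng)

    return Recording(samples=np.clip(x, -1.0, 1.0), class_label=NOISE,
                     collection=collection, height_m=height_m)


NoiseMix = list[tuple[NoiseProfile, float]]


def _default_noise_mix() -> NoiseMix:
    return [(tonal_profile(), 0.4), (click_profile(), 0.3),
            (transient_profile(), 0.3)]


@dataclasses.dataclass
class CollectionConfig:
    """One location-year unit of the monitoring design.

    ``class_mix`` gives per-class recording counts; ``noise_mix`` weights
    the structural noise profiles (optionally per measurement height via
    ``noise_mix_by_height``, which is what gives collections - and heights -
    their distinct noise signatures). A fixed seed reproduces the corpus
    byte for byte.
    """

    collection_id: str
    class_mix: dict[str, int]
    noise_mix: NoiseMix = dataclasses.field(default_factory=_default_noise_mix)
    noise_mix_by_height: dict[int, NoiseMix] | None = None
    heights_m: tuple[int, ...] = HEIGHTS_M
    seed: int = 0
    bat_duration_range_s: tuple[float, float] = (2.0, 16.0)
    noise_duration_range_s: tuple[float, float] = (1.0, 5.0)

    def __post_init__(self):
        for label, count in self.class_mix.items():
            if count < 0:
                raise ValueError(f"negative count for class {label!r}")
        if not set(self.heights_m) <= set(HEIGHTS_M):
            raise ValueError(f"heights must be a subset of {HEIGHTS_M}")
        for mix in [self.noise_mix] + list(
                (self.noise_mix_by_height or {}).values()):
            total = sum(w for _, w in mix)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"noise mix weights sum to {total}, not 1")


def _pick_profile(mix: NoiseMix, rng: np.random.Generator) -> NoiseProfile:
    weights = np.array([w for _, w in mix])
    idx = rng.choice(len(mix), p=weights / weights.sum())
    return mix[idx][0]


def synth_recording(class_label: str, duration_s: float,
                    rng: np.random.Generator, config: CollectionConfig,
                    height_m: int) -> Recording:
    if class_label == NOISE:
        mix = config.noise_mix
        if config.noise_mix_by_height is not None:
            mix = config.noise_mix_by_height.get(height_m, mix)
        profile = _pick_profile(mix, rng)
        return synth_noise(profile, duration_s, rng,
                           collection=config.collection_id, height_m=height_m)
    return synth_pulse_train(class_label, duration_s, rng,
                             collection=config.collection_id,
                             height_m=height_m)


def synth_corpus(config: CollectionConfig
                 ) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings of a collection in memory, plus its catalog."""
    rng = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    rows = []
    heights = list(config.heights_m)
    for label in sorted(config.class_mix):
        lo_d, hi_d = (config.noise_duration_range_s if label == NOISE
                      else config.bat_duration_range_s)
        for i in range(config.class_mix[label]):
            height = heights[rng.integers(0, len(heights))]
            duration = round(rng.uniform(lo_d, hi_d), 2)
            rec = synth_recording(label, duration, rng, config, height)
            recordings.append(rec)
            rows.append({
                "file": f"{config.collection_id}/{label}_{i:04d}.wav",
                "class": label,
                "collection": config.collection_id,
                "height_m": height,
                "duration_s": rec.duration_s,
            })
    return recordings, pd.DataFrame(rows, columns=[
        "file", "class", "collection", "height_m", "duration_s"])


def synth_collection(config: CollectionConfig, out_dir) -> pd.DataFrame:
    """Write a collection to disk as WAV files plus a ``manifest.csv``."""
    out = Path(out_dir)
    recordings, catalog = synth_corpus(config)
    try:
        for rec, file in zip(recordings, catalog["file"]):
            path = out / file
            path.parent.mkdir(parents=True, exist_ok=True)
            save_recording(path, rec)
        write_catalog(catalog, out / "manifest.csv")
    except OSError as exc:
        raise OSError(f"failed to write collection catalog under {out}: {exc}"
                      ) from exc
    return catalog


def scale_class_mix(class_mix: dict[str, int], factor: float
                    ) -> dict[str, int]:
    """Scale per-class counts by ``factor`` with largest-remainder rounding.

    The scaled total is ``round(total * factor)``; each class gets the floor
    of its scaled count and the leftover units go to the classes with the
    largest fractional remainders (ties broken by label order), preserving
    the imbalance profile as exactly as integer counts allow.
    """
    if factor < 0:
        raise ValueError("factor must be >= 0")
    labels = sorted(class_mix)
    exact = {c: class_mix[c] * factor for c in labels}
    target = round(sum(exact.values()))
    scaled = {c: int(math.floor(exact[c])) for c in labels}
    leftover = target - sum(scaled.values())
    by_remainder = sorted(labels, key=lambda c: (scaled[c] - exact[c], c))
    for c in by_remainder[:leftover]:
        scaled[c] += 1
    return scaled


def peak_frequency_khz(samples: np.ndarray,
                       sample_rate_hz: int = SAMPLE_RATE) -> float:
    """Frequency of maximum spectral energy of a waveform, in kHz."""
    spectrum = np.abs(np.fft.rfft(np.asarray(samples, dtype=np.float64)))
    freqs = np.fft.rfftfreq(len(samples), d=1.0 / sample_rate_hz)
    return float(freqs[int(np.argmax(spectrum))] / 1000.0)
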