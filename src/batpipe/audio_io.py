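"""Reading and writing ultrasonic recordings and catalog manifests.

A recording is mono audio sampled at 300 kHz; recordings at any other rate
are rejected outright rather than resampled, because every downstream shape
contract (1025x586 spectrograms, 20x586 MFCC matrices) assumes this rate.
Catalogs are plain CSV manifests with one row per WAV file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .taxonomy import GENUS_LABELS, SPECIES_LABELS, TaxonomyError, is_bat_label

__all__ = [
    "SAMPLE_RATE",
    "HEIGHTS_M",
    "Recording",
    "SampleRateError",
    "load_recording",
    "save_recording",
    "read_catalog",
    "write_catalog",
    "CATALOG_COLUMNS",
]

SAMPLE_RATE = 300_000
#: microphone mounting heights on the measuring masts, metres
HEIGHTS_M = (10, 35, 65, 95)

CATALOG_COLUMNS = ["file", "class", "collection", "height_m", "duration_s"]


class SampleRateError(ValueError):
    """Audio was not sampled at the required 300 kHz."""


@dataclasses.dataclass
class Recording:
    """Mono waveform plus the catalog metadata attached to it."""

    samples: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE
    class_label: str = "noise"
    collection: str = ""
    height_m: int = 10

    def __post_init__(self):
        if self.sample_rate_hz != SAMPLE_RATE:
            raise SampleRateError(
                f"expected {SAMPLE_RATE} Hz, got {self.sample_rate_hz} Hz")
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValueError("recordings must be mono (1-D sample array)")
        if self.class_label not in SPECIES_LABELS \
                and self.class_label not in GENUS_LABELS:
            raise TaxonomyError(f"unknown class label: {self.class_label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def is_bat(self) -> bool:
        return is_bat_label(self.class_label)


def save_recording(path, recording: Recording) -> None:
    """Write a recording as 16-bit PCM WAV (the acquisition bit depth)."""
    x = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), recording.sample_rate_hz, pcm)


def load_recording(path, *, class_label: str = "noise", collection: str = "",
                   height_m: int = 10) -> Recording:
    """Load a WAV file, normalizing samples to [-1, 1].

    Rejects any sample rate other than 300 kHz and any non-mono stream; no
    silent resampling is ever performed.
    """
    rate, data = wavfile.read(str(path))
    if rate != SAMPLE_RATE:
        raise SampleRateError(
            f"{path}: expected {SAMPLE_RATE} Hz, got {rate} Hz")
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float32) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float32) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float32)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float32) - 128.0) / 127.0
    else:
        raise ValueError(f"{path}: unsupported WAV dtype {data.dtype}")
    return Recording(samples=np.clip(samples, -1.0, 1.0),
                     class_label=class_label, collection=collection,
                     height_m=height_m)


def load_catalog_recording(catalog_row: pd.Series, root=".") -> Recording:
    """Load the WAV referenced by one catalog row, joining its metadata."""
    return load_recording(
        Path(root) / catalog_row["file"],
        class_label=catalog_row["class"],
        collection=catalog_row["collection"],
        height_m=int(catalog_row["height_m"]),
    )


def write_catalog(catalog: pd.DataFrame, path) -> None:
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog is missing columns: {missing}")
    if catalog["file"].duplicated().any():
        dupes = catalog.loc[catalog["file"].duplicated(), "file"].tolist()
        raise ValueError(f"duplicate file paths in catalog: {dupes[:3]}")
    bad = set(catalog["class"]) - set(SPECIES_LABELS) - set(GENUS_LABELS)
    if bad:
        raise TaxonomyError(f"unknown class labels in catalog: {sorted(bad)}")
    catalog.to_csv(path, index=False)


def read_catalog(path) -> pd.DataFrame:
    catalog = pd.read_csv(
        path,
        dtype={"file": str, "class": str, "collection": str},
    )
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog is missing columns: {missing}")
    catalog["height_m"] = catalog["height_m"].astype(int)
    catalog["duration_s"] = catalog["duration_s"].astype(float)
    bad = set(catalog["class"]) - set(SPECIES_LABELS) - set(GENUS_LABELS)
    if bad:
        raise TaxonomyError(f"unknown class labels in catalog: {sorted(bad)}")
    return catalog
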