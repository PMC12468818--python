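"""Corpus metadata and audio I/O.

The on-disk corpus layout is a metadata CSV (columns clip_id, speaker_id,
pain, intensity, thermal, duration, path) next to a directory of 16-bit
PCM mono WAV files; ``path`` entries are relative to the metadata file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import Waveform
from .synth import INTENSITIES, THERMALS

__all__ = ["REQUIRED_COLUMNS", "read_corpus", "load_waveform", "load_clips"]

REQUIRED_COLUMNS = ("clip_id", "speaker_id", "pain", "intensity", "thermal", "duration", "path")


def read_corpus(metadata_path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Read and validate a corpus metadata table.

    Checks columns, label vocabulary, the pain/intensity alignment
    (intensity is 'none' exactly for non-pain clips), clip_id uniqueness,
    and (optionally) that every referenced WAV exists.
    """
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise FileNotFoundError(f"metadata file not found: {metadata_path}")
    table = pd.read_csv(metadata_path)
    if len(table) == 0:
        raise ValueError(f"empty corpus: {metadata_path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata {metadata_path} missing columns {missing}")
    if table["clip_id"].duplicated().any():
        dupes = table.loc[table["clip_id"].duplicated(), "clip_id"].tolist()
        raise ValueError(f"duplicate clip_ids: {dupes[:5]}")
    bad_pain = set(table["pain"]) - {"pain", "non-pain"}
    if bad_pain:
        raise ValueError(f"unknown pain labels {sorted(bad_pain)}")
    bad_int = set(table["intensity"]) - set(INTENSITIES)
    if bad_int:
        raise ValueError(f"unknown intensity labels {sorted(bad_int)}")
    bad_thermal = set(table["thermal"]) - set(THERMALS)
    if bad_thermal:
        raise ValueError(f"unknown thermal labels {sorted(bad_thermal)}")
    misaligned = (table["intensity"] == "none") != (table["pain"] == "non-pain")
    if misaligned.any():
        rows = table.loc[misaligned, "clip_id"].tolist()
        raise ValueError(
            f"intensity must be 'none' exactly for non-pain clips; violated by {rows[:5]}"
        )
    if check_files:
        root = metadata_path.parent
        for rel in table["path"]:
            if not (root / rel).exists():
                raise FileNotFoundError(f"audio file listed in metadata not found: {root / rel}")
    table.attrs["root"] = str(metadata_path.parent)
    return table


def load_waveform(path: str | Path) -> Waveform:
    """Read a WAV file to a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:  # scipy returns (n_samples, n_channels)
        samples = samples.T
    return Waveform(samples, rate)


def load_clips(table: pd.DataFrame, root: str | Path | None = None) -> list[Waveform]:
    """Load every clip referenced by a (validated) metadata table."""
    root = Path(root if root is not None else table.attrs.get("root", "."))
    return [load_waveform(root / rel) for rel in table["path"]]
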