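"""Waveform standardization: mono mixdown, resampling, fixed-length framing.

Every clip entering the classifier is reduced to the same shape: a mono
waveform at a fixed sampling rate (default 8 kHz) spanning a fixed duration
(default 3 s, i.e. 24,000 samples).  Shorter clips are zero-padded at the
tail; longer clips are truncated to the first ``target_length`` samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

__all__ = ["Waveform", "PreprocConfig", "to_mono", "resample", "fix_length", "preprocess"]


@dataclass(frozen=True)
class Waveform:
    """A sampled audio signal.

    samples
        1-D float array (amplitude, nominal range [-1, 1]); a 2-D array is
        interpreted as ``(channels, n_samples)`` and only accepted by
        :func:`to_mono`.
    sample_rate
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate


@dataclass(frozen=True)
class PreprocConfig:
    """Target shape of a standardized clip.

    ``target_length`` is always ``round(target_rate * target_duration)``;
    8 kHz x 3 s = 24,000 samples under the defaults.
    """

    target_rate: int = 8000
    target_duration: float = 3.0
    target_length: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.target_duration <= 0:
            raise ValueError("target_duration must be positive")
        expected = round(self.target_rate * self.target_duration)
        if self.target_length is None:
            object.__setattr__(self, "target_length", expected)
        elif self.target_length != expected:
            raise ValueError(
                f"target_length={self.target_length} inconsistent with "
                f"round({self.target_rate} * {self.target_duration}) = {expected}"
            )


def to_mono(w: Waveform) -> Waveform:
    """Average channels of a multichannel waveform; mono passes through."""
    if w.samples.ndim == 1:
        return w
    if w.samples.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D samples, got ndim={w.samples.ndim}")
    n_channels = w.samples.shape[0]
    if n_channels == 0:
        raise ValueError("waveform has zero channels")
    return Waveform(w.samples.mean(axis=0), w.sample_rate)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited (polyphase) resampling to ``target_rate``.

    Output length is ``round(len * target/orig)`` within one sample.  When
    the rates already match the samples are returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if w.samples.ndim != 1:
        raise ValueError("resample expects a mono waveform; call to_mono first")
    if w.sample_rate == target_rate:
        return w
    ratio = Fraction(int(target_rate), int(round(w.sample_rate)))
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(w.samples, up, down)
    expected = w.samples.shape[0] * target_rate / w.sample_rate
    if abs(out.shape[0] - expected) > 1:
        raise AssertionError(
            f"resampler produced {out.shape[0]} samples, expected ~{expected:.1f}"
        )
    return Waveform(out, target_rate)


def fix_length(w: Waveform, config: PreprocConfig | None = None) -> Waveform:
    """Zero-pad at the tail or truncate to exactly ``target_length`` samples."""
    config = config or PreprocConfig()
    if round(w.sample_rate) != config.target_rate:
        raise ValueError(
            f"fix_length requires sample_rate == {config.target_rate}, "
            f"got {w.sample_rate}; resample first"
        )
    n = config.target_length
    x = w.samples
    if x.shape[0] >= n:
        out = x[:n]
    else:
        out = np.zeros(n, dtype=np.float64)
        out[: x.shape[0]] = x
    return Waveform(out, config.target_rate)


def preprocess(w: Waveform, config: PreprocConfig | None = None) -> Waveform:
    """Full standardization: mono -> resample -> fixed length.

    Idempotent: a second application returns the same samples (exactly, since
    the rates then already match and the length is already the target).
    """
    config = config or PreprocConfig()
    return fix_length(resample(to_mono(w), config.target_rate), config)
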