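"""Log-Mel spectrogram extraction.

The standardized waveform is cut into overlapping Hann-windowed frames
(no centering: every frame lies fully inside the signal), each frame is
transformed to a one-sided power spectrum, projected onto a bank of
triangular Mel filters (HTK mel scale, peaks normalized to 1), and
log-compressed with a small floor ``log_epsilon``.

For a 24,000-sample clip with ``n_fft=1024`` and ``hop=256`` this yields a
90 x 64 matrix of natural-log Mel energies.

A deliberately slow reference path (:func:`naive_power_spectrum`,
:func:`naive_logmel`) evaluates the defining DFT sum directly and serves as
the test oracle for the fast rFFT pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Waveform

__all__ = [
    "SpectrogramConfig",
    "LogMelSpectrogram",
    "hann_window",
    "frame_signal",
    "power_spectrum",
    "naive_power_spectrum",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "logmel",
    "naive_logmel",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    n_fft: int = 1024
    hop: int = 256
    n_mels: int = 64
    sample_rate: int = 8000
    f_min: float = 0.0
    f_max: float = field(default=None)  # type: ignore[assignment]
    log_epsilon: float = 1e-9
    center: bool = False  # zero-pad n_fft//2 on both ends before framing

    def __post_init__(self) -> None:
        if self.f_max is None:
            object.__setattr__(self, "f_max", self.sample_rate / 2)
        if not 0 < self.hop <= self.n_fft:
            raise ValueError("require 0 < hop <= n_fft")
        if self.n_fft % 2 != 0:
            raise ValueError("n_fft must be even")
        if not 0 <= self.f_min < self.f_max <= self.sample_rate / 2:
            raise ValueError("require 0 <= f_min < f_max <= Nyquist")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")

    @property
    def frame_rate(self) -> float:
        return self.sample_rate / self.hop


@dataclass(frozen=True)
class LogMelSpectrogram:
    """T x n_mels matrix of natural-log Mel-band energies."""

    values: np.ndarray
    config: SpectrogramConfig

    @property
    def frame_rate(self) -> float:
        return self.config.frame_rate

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def hann_window(n_fft: int) -> np.ndarray:
    """Periodic Hann window w[n] = 0.5 (1 - cos(2 pi n / n_fft))."""
    if n_fft < 2:
        raise ValueError("n_fft must be >= 2")
    n = np.arange(n_fft)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / n_fft))


def _maybe_center(x: np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    if config.center:
        pad = config.n_fft // 2
        return np.pad(x, (pad, pad))
    return x


def frame_signal(x: Waveform | np.ndarray, config: SpectrogramConfig | None = None) -> np.ndarray:
    """Windowed analysis frames: row m = x[mH .. mH+n_fft-1] * w.

    No partial frames are produced; T = floor((N - n_fft)/hop) + 1.
    """
    config = config or SpectrogramConfig()
    samples = x.samples if isinstance(x, Waveform) else np.asarray(x, dtype=np.float64)
    samples = _maybe_center(samples, config)
    n = samples.shape[0]
    if n < config.n_fft:
        raise ValueError(f"signal length {n} shorter than n_fft={config.n_fft}")
    n_frames = (n - config.n_fft) // config.hop + 1
    idx = np.arange(config.n_fft)[None, :] + config.hop * np.arange(n_frames)[:, None]
    return samples[idx] * hann_window(config.n_fft)[None, :]


def power_spectrum(frames: np.ndarray) -> np.ndarray:
    """One-sided power spectrum |DFT|^2, bins k = 0 .. n_fft/2."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n_fft = frames.shape[1]
    if n_fft % 2 != 0:
        raise ValueError("n_fft must be even")
    spec = np.fft.rfft(frames, n=n_fft, axis=1)
    return np.abs(spec) ** 2


def naive_power_spectrum(frames: np.ndarray) -> np.ndarray:
    """Direct O(n^2) evaluation of the DFT sum; test oracle for power_spectrum."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n_fft = frames.shape[1]
    k = np.arange(n_fft // 2 + 1)
    n = np.arange(n_fft)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / n_fft)  # (n_fft/2+1, n_fft)
    spec = frames @ dft.T
    return np.abs(spec) ** 2


def hz_to_mel(f):
    """HTK mel scale: 2595 log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(config: SpectrogramConfig | None = None) -> np.ndarray:
    """Triangular Mel filters, shape (n_mels, n_fft/2 + 1).

    Filter centers are equally spaced on the mel axis between f_min and
    f_max (n_mels + 2 boundary points); each triangle peaks at 1 and is
    evaluated on the actual FFT bin frequencies.  A filter too narrow to
    cover any bin is a configuration error.
    """
    config = config or SpectrogramConfig()
    n_bins = config.n_fft // 2 + 1
    bin_freqs = np.arange(n_bins) * config.sample_rate / config.n_fft
    mel_pts = np.linspace(hz_to_mel(config.f_min), hz_to_mel(config.f_max), config.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((config.n_mels, n_bins))
    for j in range(config.n_mels):
        left, center, right = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        rise = (bin_freqs - left) / (center - left)
        fall = (right - bin_freqs) / (right - center)
        fb[j] = np.maximum(0.0, np.minimum(rise, fall))
        if not np.any(fb[j] > 0):
            raise ValueError(
                f"mel filter {j} covers no FFT bin; reduce n_mels or increase n_fft"
            )
    return fb


def logmel(x: Waveform | np.ndarray, config: SpectrogramConfig | None = None) -> LogMelSpectrogram:
    """Full pipeline: frames -> power spectrum -> Mel filterbank -> ln(. + eps)."""
    config = config or SpectrogramConfig()
    frames = frame_signal(x, config)
    power = power_spectrum(frames)
    mel = power @ mel_filterbank(config).T
    return LogMelSpectrogram(np.log(mel + config.log_epsilon), config)


def naive_logmel(x: Waveform | np.ndarray, config: SpectrogramConfig | None = None) -> LogMelSpectrogram:
    """Reference pipeline using the direct DFT sum; test oracle for logmel."""
    config = config or SpectrogramConfig()
    frames = frame_signal(x, config)
    power = naive_power_spectrum(frames)
    mel = power @ mel_filterbank(config).T
    return LogMelSpectrogram(np.log(mel + config.log_epsilon), config)
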