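"""Synthetic vocalization corpus generator.

Emulates the statistical shape of a pain-speech corpus collected in a
cold-pressor protocol: ~51 speakers, ~138 clips per speaker, mean clip
length around 2.6 s, and four-way aligned labels per clip (pain/non-pain,
graded intensity, thermal condition).

Each clip is a harmonic source: a jittered pulse train at the speaker's
fundamental frequency with >= 8 harmonics rolled off by a per-speaker
spectral tilt, amplitude-modulated at a thermal-condition-specific rate,
scaled by a pain-intensity energy gain, and mixed with white noise at a
configured SNR.  Pain raises both the fundamental frequency and the
acoustic energy, the direction reported for vocal pain responses; the
per-intensity effect sizes are explicit configuration, not estimates of
any real corpus.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import Waveform

__all__ = [
    "INTENSITIES",
    "THERMALS",
    "SynthConfig",
    "SpeakerProfile",
    "make_speakers",
    "synth_clip",
    "draw_intensities",
    "synth_corpus",
]

INTENSITIES = ("none", "mild", "moderate", "severe")
THERMALS = ("cold", "warm")

_AM_DEPTH = 0.9          # amplitude-modulation depth for the thermal marker
_F0_WOBBLE_SD = 0.08     # log-scale utterance-to-utterance F0 variation
_MAX_HARMONICS = 12
_MIN_HARMONICS = 8
_FADE_S = 0.02           # raised-cosine fade at both ends, avoids clicks


def _frozen(d: dict) -> Mapping:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; identical config => bit-identical corpus."""

    n_speakers: int = 51
    clips_per_speaker: int = 138
    sample_rate: int = 8000
    duration_mean: float = 2.6
    duration_sd: float = 0.6
    duration_range: tuple[float, float] = (0.5, 6.0)
    base_f0_range: tuple[float, float] = (110.0, 220.0)
    intensity_f0_gain: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"none": 0.00, "mild": 0.10, "moderate": 0.20, "severe": 0.35})
    )
    intensity_energy_gain_db: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"none": 0.0, "mild": 2.0, "moderate": 4.0, "severe": 7.0})
    )
    jitter_pct: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"none": 0.3, "mild": 0.8, "moderate": 1.3, "severe": 2.0})
    )
    thermal_am_rate: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"cold": 6.0, "warm": 3.0})
    )
    noise_snr_db: float = 25.0
    pain_fraction: float = 0.5
    intensity_mix: Mapping[str, float] = field(
        default_factory=lambda: _frozen({"mild": 0.6, "moderate": 0.25, "severe": 0.15})
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_speakers < 1:
            raise ValueError("n_speakers must be >= 1")
        if self.clips_per_speaker < 1:
            raise ValueError("clips_per_speaker must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid duration_range")
        if not 0 < self.base_f0_range[0] <= self.base_f0_range[1]:
            raise ValueError("invalid base_f0_range")
        if not 0 <= self.pain_fraction <= 1:
            raise ValueError("pain_fraction must be in [0, 1]")
        gains = [self.intensity_f0_gain[k] for k in INTENSITIES]
        if any(b < a for a, b in zip(gains, gains[1:])):
            raise ValueError("intensity_f0_gain must be non-decreasing none -> severe")
        for rate in self.thermal_am_rate.values():
            if rate <= 0:
                raise ValueError("thermal AM rates must be positive")
        mix = sum(self.intensity_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("intensity_mix must sum to 1")

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.__dataclass_fields__}
        for key, value in d.items():
            if isinstance(value, Mapping):
                d[key] = dict(value)
            elif isinstance(value, tuple):
                d[key] = list(value)
        return d


@dataclass(frozen=True)
class SpeakerProfile:
    speaker_id: str
    base_f0: float
    spectral_tilt_db_per_octave: float
    amplitude_scale: float


def make_speakers(config: SynthConfig) -> list[SpeakerProfile]:
    """Draw speaker profiles from the config's seeded generator."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = config.base_f0_range
    profiles = []
    for i in range(config.n_speakers):
        profiles.append(
            SpeakerProfile(
                speaker_id=f"spk{i:03d}",
                base_f0=float(rng.uniform(lo, hi)),
                spectral_tilt_db_per_octave=float(rng.uniform(-12.0, -9.0)),
                # close-talk mic at controlled gain: ~±1 dB speaker level
                # spread; base kept small so the severe energy gain stays
                # far from full scale (no clipping)
                amplitude_scale=float(rng.uniform(0.077, 0.083)),
            )
        )
    return profiles


def _clip_seed(corpus_seed: int, speaker_id: str, clip_index: int) -> int:
    """Stable per-clip seed (< 2**31) from corpus seed + clip identity."""
    key = f"{corpus_seed}:{speaker_id}:{clip_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def synth_clip(
    profile: SpeakerProfile,
    intensity: str,
    thermal: str,
    duration: float,
    config: SynthConfig,
    seed: int,
) -> Waveform:
    """Render one labelled clip as a mono waveform at ``config.sample_rate``."""
    if intensity not in INTENSITIES:
        raise ValueError(f"unknown intensity {intensity!r}; expected one of {INTENSITIES}")
    if thermal not in THERMALS:
        raise ValueError(f"unknown thermal {thermal!r}; expected one of {THERMALS}")
    if duration <= 0:
        raise ValueError("duration must be positive")

    rng = np.random.default_rng(seed)
    sr = config.sample_rate
    n = int(round(duration * sr))
    t = np.arange(n) / sr

    f0 = profile.base_f0 * (1.0 + config.intensity_f0_gain[intensity])
    jitter = config.jitter_pct[intensity] / 100.0

    # cycle-level jitter: each glottal cycle gets its own frequency
    n_cycles = int(np.ceil(duration * f0 * 1.5)) + 2
    cycle_f = f0 * (1.0 + jitter * rng.standard_normal(n_cycles))
    cycle_f = np.clip(cycle_f, 0.5 * f0, 1.5 * f0)
    cycle_starts = np.concatenate([[0.0], np.cumsum(1.0 / cycle_f)])
    cycle_idx = np.searchsorted(cycle_starts, t, side="right") - 1
    f_inst = cycle_f[np.minimum(cycle_idx, n_cycles - 1)]
    phase = 2.0 * np.pi * np.cumsum(f_inst) / sr

    nyquist = sr / 2.0
    # >= _MIN_HARMONICS for any F0 the default config can produce; capped by
    # Nyquist so no partial aliases
    n_harm = int(max(1, min(_MAX_HARMONICS, np.floor(0.95 * nyquist / f0))))
    harmonics = np.arange(1, n_harm + 1)
    # spectral tilt in dB per octave -> linear harmonic amplitudes
    amps = 10.0 ** (profile.spectral_tilt_db_per_octave * np.log2(harmonics) / 20.0)
    signal = np.sin(np.outer(harmonics, phase)) .T @ amps

    am_rate = config.thermal_am_rate[thermal]
    signal *= 1.0 + _AM_DEPTH * np.sin(2.0 * np.pi * am_rate * t)

    fade = min(int(_FADE_S * sr), n // 2)
    if fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(fade) / fade))
        signal[:fade] *= ramp
        signal[-fade:] *= ramp[::-1]

    gain = 10.0 ** (config.intensity_energy_gain_db[intensity] / 20.0)
    signal *= profile.amplitude_scale * gain

    if np.isfinite(config.noise_snr_db):
        sig_rms = float(np.sqrt(np.mean(signal**2)))
        noise_rms = sig_rms * 10.0 ** (-config.noise_snr_db / 20.0)
        signal = signal + noise_rms * rng.standard_normal(n)

    return Waveform(signal, sr)


def draw_intensities(n: int, config: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Sample pain-clip intensities from the configured categorical mix."""
    levels = list(config.intensity_mix.keys())
    probs = np.array([config.intensity_mix[k] for k in levels])
    return [levels[i] for i in rng.choice(len(levels), size=n, p=probs)]


def _write_wav(path: Path, w: Waveform) -> None:
    """16-bit PCM mono; 0.9-full-scale normalization only as a clipping guard."""
    x = w.samples
    peak = float(np.max(np.abs(x))) if len(x) else 0.0
    if peak > 0.9:
        x = x * (0.9 / peak)
    wavfile.write(path, int(w.sample_rate), np.round(x * 32767.0).astype(np.int16))


def synth_corpus(config: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate the full corpus: one WAV per clip plus a metadata table.

    Per speaker, ``round(pain_fraction * clips_per_speaker)`` clips are pain
    (so corpus-level proportions match within one clip per speaker), with
    intensities drawn from ``intensity_mix`` and thermal labels drawn
    independently with equal probability.  Returns the metadata table, also
    written to ``out_dir/metadata.csv``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "clips").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create corpus directory {out_dir}: {exc}") from exc

    speakers = make_speakers(config)
    lo, hi = config.duration_range
    records = []
    for profile in speakers:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1, int(profile.speaker_id[3:])])
        )
        m = config.clips_per_speaker
        n_pain = int(round(config.pain_fraction * m))
        pain_flags = np.array([True] * n_pain + [False] * (m - n_pain))
        rng.shuffle(pain_flags)
        pain_intensities = iter(draw_intensities(n_pain, config, rng))
        for j in range(m):
            pain = bool(pain_flags[j])
            intensity = next(pain_intensities) if pain else "none"
            thermal = THERMALS[int(rng.integers(2))]
            # truncated-normal duration via rejection
            duration = float(rng.normal(config.duration_mean, config.duration_sd))
            while not lo <= duration <= hi:
                duration = float(rng.normal(config.duration_mean, config.duration_sd))
            clip_id = f"{profile.speaker_id}_c{j:03d}"
            seed = _clip_seed(config.seed, profile.speaker_id, j)
            # utterance-level prosodic variation: each clip is phonated at a
            # pitch near, not at, the speaker's habitual F0
            clip_profile = replace(
                profile, base_f0=profile.base_f0 * float(np.exp(_F0_WOBBLE_SD * rng.standard_normal()))
            )
            clip = synth_clip(clip_profile, intensity, thermal, duration, config, seed)
            path = out_dir / "clips" / f"{clip_id}.wav"
            try:
                _write_wav(path, clip)
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
            records.append(
                {
                    "clip_id": clip_id,
                    "speaker_id": profile.speaker_id,
                    "pain": "pain" if pain else "non-pain",
                    "intensity": intensity,
                    "thermal": thermal,
                    "duration": round(duration, 6),
                    "path": str(Path("clips") / f"{clip_id}.wav"),
                }
            )
    table = pd.DataFrame.from_records(records)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table
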