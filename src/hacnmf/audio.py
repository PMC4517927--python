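"""Waveform container and WAV (RIFF PCM16) input/output.

All audio in the package is mono float64 in [-1, 1] at a fixed sample rate
(16 kHz by default, 8 kHz in reduced mode). Files are read and written
through :mod:`scipy.io.wavfile` as 16-bit PCM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 16_000

__all__ = ["AudioSignal", "read_wav", "write_wav", "DEFAULT_SAMPLE_RATE"]


@dataclass
class AudioSignal:
    """A sampled mono waveform with its sample rate."""

    samples: np.ndarray
    rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal is mono: expected a 1-D sample array")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono PCM WAV file into a float64 signal in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:  # float WAVs pass through
        samples = data.astype(np.float64)
    return AudioSignal(samples, rate)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM, clipping to the representable range."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = (clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), signal.rate, pcm)
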