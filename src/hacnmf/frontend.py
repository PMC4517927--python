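"""Mel-cepstral acoustic front end (13 static + delta + delta-delta, 100 frames/s).

The waveform is cut into 20-ms slices shifted in 10-ms steps, so one second
of audio yields exactly 100 spectral envelopes. Each slice is pre-emphasised,
Hamming-windowed, and passed through 30 triangular band-pass filters equally
spaced on the Mel scale; a type-II DCT reduces the 30 log energies to 13
largely decorrelated cepstral coefficients (c0, the energy term, is kept).
First- and second-order regression differences over a +/-2-frame window add
the speed (delta) and acceleration (delta-delta) streams.

No cepstral mean normalisation, vocal-tract-length normalisation or any
noise-robust processing is applied: the front end is deliberately plain, so
any noise in the signal propagates into the representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from .audio import AudioSignal

__all__ = ["FrameSpec", "FeatureMatrix", "mel_spectra", "to_cepstra", "add_deltas", "extract_features"]

PRE_EMPHASIS = 0.97
LOG_FLOOR_REL = 1e-10  # per-utterance floor relative to the spectral maximum


@dataclass(frozen=True)
class FrameSpec:
    """Framing and filterbank geometry."""

    window: float = 0.020  # s
    shift: float = 0.010  # s
    n_mel: int = 30
    n_cep: int = 13

    def __post_init__(self) -> None:
        if self.shift > self.window:
            raise ValueError("frame shift must not exceed the window length")
        if self.n_cep > self.n_mel:
            raise ValueError("cannot keep more cepstra than Mel channels")


@dataclass
class FeatureMatrix:
    """Per-frame static cepstra with delta and delta-delta streams."""

    static: np.ndarray
    delta: np.ndarray
    deltadelta: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.static.shape == self.delta.shape == self.deltadelta.shape
        ):
            raise ValueError("all three feature streams must share one shape")
        for name in ("static", "delta", "deltadelta"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name} stream")

    @property
    def n_frames(self) -> int:
        return self.static.shape[0]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mel: int, n_fft: int, rate: int) -> np.ndarray:
    """Triangular filters equally spaced on the Mel scale, 0 Hz to Nyquist."""
    edges_mel = np.linspace(0.0, _hz_to_mel(rate / 2.0), n_mel + 2)
    edges_hz = _mel_to_hz(edges_mel)
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fbank = np.zeros((n_mel, len(bin_freqs)))
    for m in range(n_mel):
        lo, mid, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        rising = (bin_freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - bin_freqs) / max(hi - mid, 1e-12)
        fbank[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fbank


def mel_spectra(signal: AudioSignal, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Log-Mel energies, one row per 10-ms frame.

    Centered framing with reflection padding, so a T-second signal yields
    round(T * 100) frames regardless of content.
    """
    x = signal.samples
    if len(x) == 0:
        raise ValueError("cannot analyse an empty signal")
    rate = signal.rate
    win = int(round(spec.window * rate))
    hop = int(round(spec.shift * rate))
    n_frames = max(int(round(len(x) / hop)), 1)

    y = np.empty_like(x)
    y[0] = x[0] * (1.0 - PRE_EMPHASIS)
    y[1:] = x[1:] - PRE_EMPHASIS * x[:-1]
    pad = win // 2
    x = np.pad(y, pad, mode="reflect") if len(y) > 1 else np.pad(y, pad)

    starts = np.arange(n_frames) * hop
    idx = starts[:, None] + np.arange(win)[None, :]
    idx = np.minimum(idx, len(x) - 1)
    frames = x[idx] * np.hamming(win)

    n_fft = 1 << (win - 1).bit_length()
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fbank = mel_filterbank(spec.n_mel, n_fft, rate)
    energies = power @ fbank.T
    floor = max(energies.max() * LOG_FLOOR_REL, 1e-12)
    return np.log(np.maximum(energies, floor))


def to_cepstra(mel: np.ndarray, n_cep: int = 13) -> np.ndarray:
    """Orthonormal type-II DCT across channels, keeping the first n_cep."""
    mel = np.asarray(mel)
    if mel.ndim != 2 or mel.shape[1] != 30:
        raise ValueError(f"expected frames x 30 Mel energies, got {mel.shape}")
    return dct(mel, type=2, norm="ortho", axis=1)[:, :n_cep]


def add_deltas(static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regression deltas over a +/-2-frame window, edges replicated.

    delta_t = sum_{n=1..2} n * (c_{t+n} - c_{t-n}) / (2 * sum n^2);
    the delta-delta stream applies the same operator to the deltas.
    """
    static = np.asarray(static)
    if static.shape[0] < 5:
        raise ValueError("need at least 5 frames for delta features")
    delta = _regression_delta(static)
    return delta, _regression_delta(delta)


def _regression_delta(x: np.ndarray, width: int = 2) -> np.ndarray:
    padded = np.pad(x, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(x, dtype=np.float64)
    for n in range(1, width + 1):
        out += n * (padded[width + n : width + n + len(x)] - padded[width - n : width - n + len(x)])
    return out / denom


def extract_features(
    signal: AudioSignal, spec: FrameSpec = FrameSpec()
) -> FeatureMatrix:
    """Full front end: waveform -> static + delta + delta-delta cepstra."""
    static = to_cepstra(mel_spectra(signal, spec), spec.n_cep)
    delta, deltadelta = add_deltas(static)
    return FeatureMatrix(static, delta, deltadelta)
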