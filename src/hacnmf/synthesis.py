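"""Deterministic parallel-formant speech synthesis.

Stands in for a recorded infant-directed speech corpus. Each phone is either
a voiced segment (impulse-train excitation at the speaker's fundamental
frequency, shaped by a glottal low-pass and three parallel formant
resonators) or an unvoiced noise burst band-filtered to a phone-specific
band. Speaker identity is carried by four parameters: base f0, a global
formant scale factor, a speaking-rate scale and a spectral tilt. Per-token
natural variability is emulated by small seeded jitter on phone durations
(±10%), f0 (±5%) and formant frequencies (±3%).

The goal is controllable speaker identity and word discriminability, not
natural-sounding or phonetically faithful English speech.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter

from .audio import DEFAULT_SAMPLE_RATE, AudioSignal
from .lexicon import Lexicon, LexiconError, load_lexicon

__all__ = [
    "SpeakerProfile",
    "SentenceSpec",
    "make_speaker",
    "synthesize_sentence",
    "generate_babble",
    "short_time_level_variation",
]

# Jitter magnitudes (fractions) applied per token, driven only by token_seed.
DURATION_JITTER = 0.10
F0_JITTER = 0.05
FORMANT_JITTER = 0.03

# Speaker-idiosyncratic per-phone formant colouring (fraction). Real speakers
# differ not only by a global vocal-tract scale but in the detailed layout of
# their vowel space; this fixed, speaker-specific perturbation is what makes
# speech from one speaker an imperfect model for another's.
SPEAKER_PHONE_IDIOSYNCRASY = 0.06

_FORMANT_BANDWIDTHS = (90.0, 110.0, 160.0)
_FORMANT_GAINS = (1.0, 0.55, 0.28)
_EDGE_RAMP = 0.005  # s, raised-cosine on/offset per phone
_WORD_GAP = 0.030  # s
_SENTENCE_PAD = 0.050  # s


@dataclass(frozen=True)
class SpeakerProfile:
    """Extra-linguistic identity parameters of one synthetic speaker."""

    speaker_id: str
    f0_base: float  # Hz
    formant_scale: float  # multiplies all formant targets
    duration_scale: float  # multiplies all phone durations
    spectral_tilt: float  # dB/octave, more negative = darker voice
    sex: str  # 'female' | 'male'

    def __post_init__(self) -> None:
        if not 70.0 <= self.f0_base <= 400.0:
            raise ValueError("f0_base outside the plausible 70-400 Hz range")
        if not 0.8 <= self.formant_scale <= 1.25:
            raise ValueError("formant_scale outside [0.8, 1.25]")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex: {self.sex!r}")


@dataclass(frozen=True)
class SentenceSpec:
    """Everything needed to (re)synthesize one utterance deterministically."""

    speaker_id: str
    keyword: str | None
    keyword_position: str  # 'initial' | 'final'
    carrier_id: str
    token_seed: int


# Parameter ranges per sex. Female and male f0 ranges are disjoint; the
# formant ranges overlap only at their shared boundary.
_SEX_RANGES = {
    "female": {"f0": (180.0, 260.0), "formant": (1.00, 1.15)},
    "male": {"f0": (90.0, 140.0), "formant": (0.85, 1.00)},
}


def make_speaker(seed: int, sex: str, speaker_id: str | None = None) -> SpeakerProfile:
    """Draw a deterministic speaker profile for the given seed and sex."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if sex not in _SEX_RANGES:
        raise ValueError(f"unknown sex: {sex!r}")
    rng = np.random.default_rng([int(seed), 0 if sex == "female" else 1])
    rr = _SEX_RANGES[sex]
    f0 = rng.uniform(*rr["f0"])
    fsc = rng.uniform(*rr["formant"])
    dsc = rng.uniform(0.9, 1.1)
    tilt = rng.uniform(-12.0, -6.0)
    if speaker_id is None:
        speaker_id = f"spk-{sex[0]}{seed:04d}"
    return SpeakerProfile(speaker_id, f0, fsc, dsc, tilt, sex)


def _phone_colour(speaker_id: str, symbol: str, k: int) -> float:
    """Fixed speaker-specific formant multiplier for one phone and formant.

    Deterministic in (speaker_id, phone, formant index) across processes.
    """
    key = f"{speaker_id}:{symbol}:{k}".encode()
    u = (zlib.crc32(key) % 10_000) / 10_000.0  # uniform-ish in [0, 1)
    return 1.0 + SPEAKER_PHONE_IDIOSYNCRASY * (2.0 * u - 1.0)


def _ramp(segment: np.ndarray, rate: int) -> np.ndarray:
    n = min(int(_EDGE_RAMP * rate), len(segment) // 2)
    if n > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / n))
        segment[:n] *= win
        segment[-n:] *= win[::-1]
    return segment


def _glottal_alpha(tilt: float) -> float:
    # Map tilt in [-12, -6] dB/oct to a one-pole low-pass coefficient;
    # steeper (more negative) tilt -> pole closer to the unit circle.
    t = np.clip((-tilt - 6.0) / 6.0, 0.0, 1.0)
    return 0.85 + 0.13 * t


def _voiced_segment(
    n: int, f0: float, formants, rate: int, tilt: float
) -> np.ndarray:
    exc = np.zeros(n)
    period = rate / f0
    idx = np.arange(0.0, n, period).astype(int)
    exc[idx[idx < n]] = 1.0
    alpha = _glottal_alpha(tilt)
    src = lfilter([1.0 - alpha], [1.0, -alpha], exc)
    out = np.zeros(n)
    for freq, bw, gain in zip(formants, _FORMANT_BANDWIDTHS, _FORMANT_GAINS):
        freq = min(freq, 0.45 * rate)
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * freq / rate
        out += gain * lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], src)
    return out


def _noise_segment(n: int, band, rate: int, rng: np.random.Generator) -> np.ndarray:
    lo = max(band[0], 60.0)
    hi = min(band[1], 0.47 * rate)
    if hi <= lo:  # band collapsed at a low sample rate
        hi, lo = 0.47 * rate, 0.47 * rate * 0.5
    b, a = butter(4, [lo / (rate / 2), hi / (rate / 2)], btype="band")
    return lfilter(b, a, rng.standard_normal(n))


def synthesize_sentence(
    spec: SentenceSpec,
    speaker: SpeakerProfile,
    lexicon: Lexicon | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioSignal:
    """Render one carrier sentence (with optional embedded keyword) to audio.

    Bit-identical output for identical ``(spec, speaker)``: all randomness
    comes from ``spec.token_seed``.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    try:
        carrier = lexicon.carriers[spec.carrier_id]
    except KeyError:
        raise LexiconError(f"unknown carrier: {spec.carrier_id!r}") from None
    if spec.keyword is not None and spec.keyword_position != carrier.position:
        raise ValueError(
            f"keyword_position {spec.keyword_position!r} does not match "
            f"carrier {spec.carrier_id!r} ({carrier.position})"
        )
    words = carrier.sentence_words(spec.keyword)
    rng = np.random.default_rng(int(spec.token_seed))

    phone_lists = [lexicon.phone_string([w]) for w in words]
    n_phones = max(sum(len(pl) for pl in phone_lists), 1)
    pad = np.zeros(int(_SENTENCE_PAD * sample_rate))
    gap = np.zeros(int(_WORD_GAP * sample_rate))
    pieces = [pad]
    phone_pos = 0
    for wi, plist in enumerate(phone_lists):
        if wi > 0:
            pieces.append(gap)
        for phone in plist:
            dur = (
                phone.duration
                * speaker.duration_scale
                * (1.0 + rng.uniform(-DURATION_JITTER, DURATION_JITTER))
            )
            n = max(int(dur * sample_rate), 8)
            if phone.closure > 0:
                pieces.append(np.zeros(int(phone.closure * speaker.duration_scale * sample_rate)))
            if phone.voiced:
                # shallow f0 declination over the sentence
                decl = 1.12 - 0.24 * phone_pos / n_phones
                f0 = (
                    speaker.f0_base
                    * decl
                    * (1.0 + rng.uniform(-F0_JITTER, F0_JITTER))
                )
                formants = [
                    f * speaker.formant_scale
                    * _phone_colour(speaker.speaker_id, phone.symbol, k)
                    * (1.0 + rng.uniform(-FORMANT_JITTER, FORMANT_JITTER))
                    for k, f in enumerate(phone.formants)
                ]
                seg = _voiced_segment(n, f0, formants, sample_rate, speaker.spectral_tilt)
            else:
                seg = _noise_segment(n, phone.band, sample_rate, rng)
            rms = np.sqrt(np.mean(seg**2))
            if rms > 0:
                seg = seg * (phone.amplitude / rms)
            pieces.append(_ramp(seg, sample_rate))
            phone_pos += 1
    pieces.append(pad)
    x = np.concatenate(pieces)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (0.3 / peak)
    return AudioSignal(x, sample_rate)


def generate_babble(
    duration: float,
    n_talkers: int = 8,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    lexicon: Lexicon | None = None,
) -> AudioSignal:
    """Multi-talker babble: the sum of independent synthetic sentence streams.

    Babble talkers are dedicated speakers, disjoint from all corpus speakers.
    Each stream is a concatenation of random sentences; streams are RMS
    equalised before summing, so no single talker dominates. Averaging across
    talkers makes the short-time level of the mix flatter than that of any
    constituent stream.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_talkers < 1:
        raise ValueError("need at least one babble talker")
    if lexicon is None:
        lexicon = load_lexicon()
    rng = np.random.default_rng([int(seed), 0xBABB1E])
    n_total = int(round(duration * sample_rate))
    slot_words = sorted(
        w for w, e in lexicon.words.items() if e.role in ("keyword", "foil")
    )
    carrier_ids = lexicon.carrier_ids
    mix = np.zeros(n_total)
    for t in range(n_talkers):
        sex = "female" if t % 2 == 0 else "male"
        speaker = make_speaker(
            int(rng.integers(2**31)), sex, speaker_id=f"babble-{t:02d}"
        )
        stream_parts: list[np.ndarray] = []
        n_have = 0
        margin = sample_rate  # extra second so the start offset can vary
        while n_have < n_total + margin:
            cid = carrier_ids[int(rng.integers(len(carrier_ids)))]
            word = slot_words[int(rng.integers(len(slot_words)))]
            spec = SentenceSpec(
                speaker_id=speaker.speaker_id,
                keyword=word,
                keyword_position=lexicon.carriers[cid].position,
                carrier_id=cid,
                token_seed=int(rng.integers(2**31)),
            )
            seg = synthesize_sentence(spec, speaker, lexicon, sample_rate).samples
            stream_parts.append(seg)
            n_have += len(seg)
        stream = np.concatenate(stream_parts)
        offset = int(rng.integers(max(len(stream) - n_total, 1)))
        stream = stream[offset : offset + n_total]
        rms = np.sqrt(np.mean(stream**2))
        if rms > 0:
            stream = stream / rms
        mix += stream
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = mix * (0.5 / peak)
    return AudioSignal(mix, sample_rate)


def short_time_level_variation(signal: AudioSignal, frame: float = 0.1) -> float:
    """Relative short-time power variation: std/mean of 100-ms frame RMS."""
    n = int(frame * signal.rate)
    n_frames = len(signal.samples) // n
    if n_frames < 2:
        raise ValueError("signal too short for short-time level analysis")
    frames = signal.samples[: n_frames * n].reshape(n_frames, n)
    levels = np.sqrt(np.mean(frames**2, axis=1))
    return float(np.std(levels) / np.mean(levels))
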