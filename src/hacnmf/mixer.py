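"""SNR-controlled mixing of speech and babble noise.

Noisy test stimuli are built by scaling a noise excerpt of the same duration
as the speech so that its average root-mean-square power sits exactly
``snr_db`` decibels below the speech power, then adding the two signals.
The SNR is defined over the whole utterance; because speech has much larger
short-time power variation than multi-talker babble, louder speech intervals
end up with a local SNR above the average and softer intervals below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal

__all__ = ["MixInfo", "rms_power", "mix_at_snr"]


@dataclass
class MixInfo:
    """Book-keeping for one mixing operation."""

    snr_db: float
    noise_scale: float
    noise_offset: int
    clipped: bool  # True if the mixture was jointly rescaled to avoid clipping


def rms_power(signal: AudioSignal) -> float:
    """Average power: mean of squared samples over the full utterance."""
    if len(signal) == 0:
        raise ValueError("cannot compute power of an empty signal")
    return float(np.mean(signal.samples**2))


def mix_at_snr(
    speech: AudioSignal,
    noise: AudioSignal,
    snr_db: float,
    offset_seed: int | None = None,
    return_info: bool = False,
):
    """Add noise to speech at an exact whole-utterance SNR.

    ``snr_db = inf`` is the clean passthrough. The noise is cropped to the
    speech length starting at a seeded random offset (same seed, same
    excerpt), scaled so ``10 log10(P_speech / P_noise) = snr_db`` exactly,
    and added. If the sum would clip, speech and noise are rescaled jointly,
    which preserves the SNR.
    """
    if np.isinf(snr_db) and snr_db > 0:
        mix = AudioSignal(speech.samples.copy(), speech.rate)
        info = MixInfo(snr_db, 0.0, 0, False)
        return (mix, info) if return_info else mix
    if speech.rate != noise.rate:
        raise ValueError("speech and noise sample rates differ")
    if len(noise) < len(speech):
        raise ValueError("noise must be at least as long as the speech")

    slack = len(noise) - len(speech)
    if slack > 0:
        rng = np.random.default_rng(offset_seed)
        offset = int(rng.integers(slack + 1))
    else:
        offset = 0
    excerpt = noise.samples[offset : offset + len(speech)]

    p_speech = rms_power(speech)
    p_noise = float(np.mean(excerpt**2))
    if p_speech <= 0 or p_noise <= 0:
        raise ValueError("speech and noise must both have non-zero power")
    scale = np.sqrt(p_speech / (p_noise * 10.0 ** (snr_db / 10.0)))

    mix = speech.samples + scale * excerpt
    peak = np.max(np.abs(mix))
    clipped = bool(peak > 1.0)
    if clipped:
        mix = mix * (0.99 / peak)
    out = AudioSignal(mix, speech.rate)
    info = MixInfo(float(snr_db), float(scale), offset, clipped)
    return (out, info) if return_info else out
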