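"""Simulated listening preferences from keyword activations.

Two readings of what drives infant listening behaviour are implemented:

* **matching** — the score of a test sentence is the highest activation of
  *any* keyword; the identity of that keyword is ignored. No attention to a
  specific word is assumed.
* **recognition** — the score is the activation of one attended target
  keyword, for target and foil sentences alike (for a foil, the activation
  of the keyword the foil "impersonates").

The listening preference of a condition is the mean score over the 20
target-word sentences minus the mean score over the 60 foil sentences
(3 foils x 20). Preferences are unitless: activation scales depend on the
normalisation chosen and cannot be mapped to absolute listening times, so
only the sign and ordering of preferences are interpreted. Significance of
"preference above zero" uses an uncorrected one-sided one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .memory import ActivationRecord

__all__ = [
    "MEASURES",
    "PreferenceResult",
    "matching_score",
    "recognition_score",
    "listening_preference",
    "preference_positive_test",
]

MEASURES = ("matching", "recognition")


@dataclass
class PreferenceResult:
    """Per-condition simulated listening preference."""

    preference: float
    target_word: str | None = None
    measure: str | None = None
    condition: tuple | None = None  # (learning condition, test speaker, snr)
    seed: int | None = None
    sampling_point: int | None = None
    target_scores: np.ndarray = field(default=None, repr=False)
    foil_scores: np.ndarray = field(default=None, repr=False)


def _check_normalised(a: ActivationRecord) -> None:
    if not a.normalised:
        raise ValueError("scores are defined on normalised activation records")


def matching_score(a: ActivationRecord) -> float:
    """Highest activation across all keywords; the argmax identity is ignored."""
    _check_normalised(a)
    return float(np.max(a.a))


def recognition_score(a: ActivationRecord, target: str) -> float:
    """Activation of the attended target keyword, whatever the sentence holds."""
    _check_normalised(a)
    if target not in a.keywords:
        raise KeyError(f"unknown target keyword: {target!r}")
    return float(a.a[a.keywords.index(target)])


def listening_preference(
    scores_target, scores_foils, **metadata
) -> PreferenceResult:
    """mean(target scores) - mean(foil scores).

    Expects three equal-sized foil sets pooled into ``scores_foils``
    (``len(scores_foils) == 3 * len(scores_target)``); with equal-sized sets
    the pooled mean equals the mean of the per-foil-set means.
    """
    t = np.asarray(scores_target, dtype=np.float64)
    f = np.asarray(scores_foils, dtype=np.float64)
    if len(t) == 0 or len(f) != 3 * len(t):
        raise ValueError(
            f"expected n target and 3n foil scores, got {len(t)} and {len(f)}"
        )
    pref = float(t.mean() - f.mean())
    if not np.isfinite(pref):
        raise ValueError("non-finite preference")
    return PreferenceResult(
        preference=pref, target_scores=t, foil_scores=f, **metadata
    )


def preference_positive_test(preferences) -> tuple[float, float]:
    """Uncorrected one-sided one-sample t-test of mean preference > 0.

    Returns ``(t, p)``. Degenerate zero-variance input is reported without a
    test: a constant positive sample is maximally significant, a constant
    zero or negative sample is not significant.
    """
    x = np.asarray(preferences, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 replicates for the t-test")
    if np.std(x) == 0.0:
        m = x.mean()
        if m > 0:
            return float("inf"), 0.0
        if m < 0:
            return float("-inf"), 1.0
        return 0.0, 0.5
    t, p = stats.ttest_1samp(x, popmean=0.0, alternative="greater")
    return float(t), float(p)
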