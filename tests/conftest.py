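"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hacnmf.lexicon import load_lexicon
from hacnmf.synthesis import SentenceSpec, make_speaker, synthesize_sentence


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def caregiver():
    return make_speaker(1, "female", "caregiver")


@pytest.fixture(scope="session")
def sentence(caregiver, lexicon):
    """One deterministic caregiver sentence ('this is a nice banana')."""
    spec = SentenceSpec("caregiver", "banana", "final", "c1", token_seed=42)
    return synthesize_sentence(spec, caregiver, lexicon)


def brute_force_pair_counts(stream, k, lag):
    """Independent HAC oracle: count ordered label pairs at one lag."""
    counts = {}
    for t in range(len(stream) - lag):
        key = int(stream[t]) * k + int(stream[t + lag])
        counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
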