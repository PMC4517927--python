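"""Corpus design: speaker roster, learning/test/codebook manifests.

Emulates the structure of the learning-condition design:

========================  ======================  ======================
condition                 utterances              speakers
========================  ======================  ======================
baseline                  30 blocks x 15 = 450    primary caregiver only
frequency                 30 blocks x 16 = 480    primary caregiver only
multispeaker              30 blocks x 16 = 480    caregiver + 6 extras
========================  ======================  ======================

Every block contains one token of each of the 15 keywords; in the
``frequency`` condition the target keyword appears twice per block (both by
the caregiver); in ``multispeaker`` the extra target token per block comes
from one of six additional speakers (3 female, 3 male), each contributing
five sentences in total. Test corpora hold 80 sentences: 20 with the target
word and 20 with each of its three matched foils, spoken either by the
caregiver ("known") or by a held-out female speaker ("unknown") who appears
in no learning material. The sentence specs for foils shared between targets
(robin, airplane) are identical across the mummy and banana test corpora.

Manifests are :class:`pandas.DataFrame` objects carrying, besides the
six-column external CSV schema (utterance_id, wav_path, speaker_id, keyword,
condition_tag, block_index), the synthesis columns (carrier_id,
keyword_position, token_seed) needed to regenerate each waveform
deterministically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .audio import DEFAULT_SAMPLE_RATE, AudioSignal
from .lexicon import FOILS, KEYWORDS, Lexicon, load_lexicon
from .synthesis import SentenceSpec, SpeakerProfile, make_speaker, synthesize_sentence

__all__ = [
    "MANIFEST_COLUMNS",
    "speaker_roster",
    "generate_learning_corpus",
    "generate_test_corpus",
    "generate_codebook_corpus",
    "synthesize_row",
    "write_manifest",
]

#: External manifest schema (CSV header).
MANIFEST_COLUMNS = (
    "utterance_id",
    "wav_path",
    "speaker_id",
    "keyword",
    "condition_tag",
    "block_index",
)

_ALL_COLUMNS = MANIFEST_COLUMNS + ("carrier_id", "keyword_position", "token_seed")

LEARNING_CONDITIONS = ("baseline", "frequency", "multispeaker")

# Tags keep the seed streams of the different corpus parts independent.
_TAG_ROSTER, _TAG_BASE, _TAG_EXTRA, _TAG_TEST, _TAG_CODEBOOK = 11, 12, 13, 14, 15


def _derived_seed(*key: int) -> int:
    """Deterministic sub-seed (< 2^31) from a tuple of integers."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % 2**31)


def speaker_roster(master_seed: int) -> dict[str, SpeakerProfile]:
    """All named corpus speakers for one replicate.

    caregiver         the primary caregiver (female); all baseline speech
    unknown           held-out female test speaker, absent from learning
    extra-f1..3/m1..3 the six additional learning speakers
    cb-00..cb-09      ten held-out speakers for codebook training (5 f, 5 m)
    """
    roster: dict[str, SpeakerProfile] = {}

    def add(name: str, sex: str, tag: int) -> None:
        roster[name] = make_speaker(
            _derived_seed(master_seed, _TAG_ROSTER, tag), sex, speaker_id=name
        )

    add("caregiver", "female", 0)
    add("unknown", "female", 1)
    for i in range(3):
        add(f"extra-f{i + 1}", "female", 10 + i)
        add(f"extra-m{i + 1}", "male", 20 + i)
    for i in range(10):
        add(f"cb-{i:02d}", "female" if i < 5 else "male", 30 + i)
    return roster


def _pick_carrier(rng: np.random.Generator, lexicon: Lexicon) -> tuple[str, str]:
    cids = lexicon.carrier_ids
    cid = cids[int(rng.integers(len(cids)))]
    return cid, lexicon.carriers[cid].position


def _base_blocks(master_seed: int, lexicon: Lexicon) -> list[list[dict]]:
    """The 450-sentence caregiver corpus: 30 blocks, one token per keyword.

    Shared by all three learning conditions, so the extended corpora are
    true supersets of the baseline.
    """
    rng = np.random.default_rng([master_seed, _TAG_BASE])
    blocks = []
    for b in range(1, 31):
        order = [KEYWORDS[i] for i in rng.permutation(len(KEYWORDS))]
        rows = []
        for kw in order:
            cid, pos = _pick_carrier(rng, lexicon)
            rows.append(
                dict(
                    speaker_id="caregiver",
                    keyword=kw,
                    carrier_id=cid,
                    keyword_position=pos,
                    token_seed=int(rng.integers(2**31)),
                    block_index=b,
                )
            )
        blocks.append(rows)
    return blocks


def generate_learning_corpus(
    condition: str, target_word: str, master_seed: int
) -> pd.DataFrame:
    """Build the learning manifest for one condition and target word.

    Deterministic in ``(condition, target_word, master_seed)``; the 450
    baseline rows are identical across conditions for a given seed.
    """
    if condition not in LEARNING_CONDITIONS:
        raise ValueError(
            f"unknown learning condition {condition!r}; "
            f"expected one of {LEARNING_CONDITIONS}"
        )
    if target_word not in KEYWORDS:
        raise ValueError(f"target word {target_word!r} is not one of the 15 keywords")
    lexicon = load_lexicon()
    blocks = _base_blocks(master_seed, lexicon)

    if condition != "baseline":
        widx = KEYWORDS.index(target_word)
        rng = np.random.default_rng([master_seed, _TAG_EXTRA, widx])
        if condition == "multispeaker":
            extras = [f"extra-{s}{i + 1}" for s in ("f", "m") for i in range(3)]
            # each extra speaker covers five of the 30 blocks
            speaker_of_block = [extras[j // 5] for j in rng.permutation(30)]
        for b, rows in enumerate(blocks):
            cid, pos = _pick_carrier(rng, lexicon)
            extra = dict(
                speaker_id="caregiver"
                if condition == "frequency"
                else speaker_of_block[b],
                keyword=target_word,
                carrier_id=cid,
                keyword_position=pos,
                token_seed=int(rng.integers(2**31)),
                block_index=b + 1,
            )
            rows.insert(int(rng.integers(len(rows) + 1)), extra)

    records = []
    for rows in blocks:
        records.extend(rows)
    df = pd.DataFrame.from_records(records)
    tag = f"learn-{condition}-{target_word}"
    df["condition_tag"] = tag
    df["utterance_id"] = [
        f"{tag}-s{master_seed}-b{r.block_index:02d}-{i:03d}"
        for i, r in enumerate(df.itertuples())
    ]
    df["wav_path"] = df["utterance_id"] + ".wav"
    if df["utterance_id"].duplicated().any():
        raise AssertionError("duplicate utterance ids in manifest")
    return df[list(_ALL_COLUMNS)]


def _word_tag(word: str, lexicon: Lexicon) -> int:
    return sorted(lexicon.words).index(word)


def generate_test_corpus(
    target_word: str, speaker: str, master_seed: int
) -> pd.DataFrame:
    """Build one 80-sentence test manifest (20 target + 3 x 20 foils).

    Sentence specs depend only on ``(master_seed, word, index)``, never on
    the target they are tested against, so foils shared between targets use
    identical specs.
    """
    if target_word not in FOILS:
        raise ValueError(
            f"no foils defined for {target_word!r}; "
            f"test targets are {tuple(FOILS)}"
        )
    if speaker not in ("known", "unknown"):
        raise ValueError("test speaker must be 'known' or 'unknown'")
    lexicon = load_lexicon()
    speaker_id = "caregiver" if speaker == "known" else "unknown"
    words = (target_word,) + FOILS[target_word]
    records = []
    for word in words:
        wtag = _word_tag(word, lexicon)
        for i in range(20):
            rng = np.random.default_rng([master_seed, _TAG_TEST, wtag, i])
            cid, pos = _pick_carrier(rng, lexicon)
            records.append(
                dict(
                    speaker_id=speaker_id,
                    keyword=word,
                    carrier_id=cid,
                    keyword_position=pos,
                    token_seed=int(rng.integers(2**31)),
                    block_index=0,
                )
            )
    df = pd.DataFrame.from_records(records)
    tag = f"test-{target_word}-{speaker}"
    df["condition_tag"] = tag
    df["utterance_id"] = [
        f"{tag}-s{master_seed}-{i:03d}" for i in range(len(df))
    ]
    df["wav_path"] = df["utterance_id"] + ".wav"
    return df[list(_ALL_COLUMNS)]


def generate_codebook_corpus(
    master_seed: int, n_sentences: int = 200
) -> pd.DataFrame:
    """Held-out clean-speech corpus for codebook training.

    Ten dedicated speakers (disjoint from all learning and test speakers)
    produce ``n_sentences`` sentences in total, cycling through the keyword
    and foil vocabulary. Mirrors learning the auditory clusters from
    speakers unrelated to the corpus proper.
    """
    lexicon = load_lexicon()
    rng = np.random.default_rng([master_seed, _TAG_CODEBOOK])
    slot_words = sorted(
        w for w, e in lexicon.words.items() if e.role in ("keyword", "foil")
    )
    records = []
    for i in range(n_sentences):
        cid, pos = _pick_carrier(rng, lexicon)
        records.append(
            dict(
                speaker_id=f"cb-{i % 10:02d}",
                keyword=slot_words[i % len(slot_words)],
                carrier_id=cid,
                keyword_position=pos,
                token_seed=int(rng.integers(2**31)),
                block_index=0,
            )
        )
    df = pd.DataFrame.from_records(records)
    df["condition_tag"] = "codebook"
    df["utterance_id"] = [f"codebook-s{master_seed}-{i:03d}" for i in range(len(df))]
    df["wav_path"] = df["utterance_id"] + ".wav"
    return df[list(_ALL_COLUMNS)]


def synthesize_row(
    row,
    roster: dict[str, SpeakerProfile],
    lexicon: Lexicon | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioSignal:
    """Regenerate the waveform for one manifest row."""
    spec = SentenceSpec(
        speaker_id=row.speaker_id,
        keyword=row.keyword if row.keyword else None,
        keyword_position=row.keyword_position,
        carrier_id=row.carrier_id,
        token_seed=int(row.token_seed),
    )
    return synthesize_sentence(spec, roster[row.speaker_id], lexicon, sample_rate)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    """Write the six-column external manifest CSV."""
    df[list(MANIFEST_COLUMNS)].to_csv(path, index=False)
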