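"""Orchestration of the full factorial simulation.

Design factors: learning condition (baseline / frequency / multispeaker) x
test speaker (known / unknown) x noise level (clean / 10 dB / 5 dB SNR) x
preference measure (matching / recognition), for three target words (cat,
mummy, banana), probed at ten sampling points spread over the 30 learning
blocks, replicated over independent seeds.

For each seed the pipeline trains codebooks on a held-out clean corpus,
synthesises the learning material, learns the memory incrementally in block
order, and at every sampling point freezes the memory and decodes all 80
test sentences of each test corpus (mixed with babble at the cell's SNR)
into keyword activations, from which both preference measures are computed.

The output is a tidy results table (one row per word x condition x speaker
x SNR x measure x sampling point x seed) plus a summary aggregated the way
the headline figures are drawn: means with standard deviations across words
and measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import (
    LEARNING_CONDITIONS,
    generate_codebook_corpus,
    generate_learning_corpus,
    generate_test_corpus,
    speaker_roster,
    synthesize_row,
)
from .frontend import FrameSpec, extract_features
from .hac import HACEncoder
from .lexicon import TARGET_WORDS, load_lexicon
from .memory import decode, init_memory, learn_utterance
from .mixer import mix_at_snr
from .preference import MEASURES, listening_preference, matching_score, recognition_score
from .synthesis import generate_babble
from .vq import quantize, train_codebooks

__all__ = [
    "ExperimentConfig",
    "PipelineResources",
    "build_resources",
    "prepare_test_bank",
    "run_condition",
    "run_full_design",
    "summarise",
    "directional_patterns",
    "snr_label",
]

_TAG_CB_SEED, _TAG_BABBLE, _TAG_MEMORY, _TAG_MIX = 21, 22, 23, 24


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunable parameters of the simulation (units in field comments)."""

    sample_rate: int = 16_000  # Hz; 8_000 is the reduced mode
    r_primitives: int = 70  # memory columns
    eta: float = 0.4  # cap on the per-utterance, per-primitive step size
    inner_iters_learn: int = 25  # h updates per learning utterance
    inner_iters_decode: int = 50  # h updates per test decode
    acoustic_mass: float = 100.0  # normalised acoustic mass per utterance
    meaning_mass: float = 10.0  # supervision mass (10:1 acoustic:meaning)
    codebook_sizes: tuple[int, int, int] = (150, 150, 100)
    lags: tuple[int, ...] = (2, 5)  # frames (20 ms, 50 ms)
    n_codebook_sentences: int = 200
    babble_talkers: int = 8
    babble_duration: float = 30.0  # s of babble generated per seed
    snr_levels: tuple[float, ...] = (math.inf, 10.0, 5.0)  # dB; inf = clean
    target_words: tuple[str, ...] = TARGET_WORDS
    learning_conditions: tuple[str, ...] = LEARNING_CONDITIONS
    test_speakers: tuple[str, ...] = ("known", "unknown")
    sampling_interval: int = 3  # probe after every 3rd block -> 10 points
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)

    @classmethod
    def reduced(cls, **overrides) -> "ExperimentConfig":
        """8-kHz reduced mode: identical design, cheaper audio."""
        return cls(sample_rate=8_000, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in (
            "codebook_sizes", "lags", "snr_levels", "target_words",
            "learning_conditions", "test_speakers", "seeds",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "snr_levels" in raw:
            raw["snr_levels"] = tuple(
                math.inf if v in ("clean", "inf", None) else float(v)
                for v in raw["snr_levels"]
            )
        return cls(**raw)


def snr_label(snr: float) -> str:
    return "clean" if math.isinf(snr) else f"{snr:g}dB"


def _seed_of(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % 2**31)


@dataclass
class PipelineResources:
    """Per-seed shared artefacts: roster, codebooks, babble, encoder."""

    seed: int
    roster: dict
    lexicon: object
    codebook: object
    encoder: HACEncoder
    babble: object
    frame_spec: FrameSpec = field(default_factory=FrameSpec)


def build_resources(seed: int, cfg: ExperimentConfig) -> PipelineResources:
    """Train codebooks on the held-out corpus and render the babble bed."""
    roster = speaker_roster(seed)
    lexicon = load_lexicon()
    spec = FrameSpec()
    cb_manifest = generate_codebook_corpus(seed, cfg.n_codebook_sentences)
    feats = [
        extract_features(
            synthesize_row(row, roster, lexicon, cfg.sample_rate), spec
        )
        for row in cb_manifest.itertuples()
    ]
    codebook = train_codebooks(
        feats, seed=_seed_of(seed, _TAG_CB_SEED), sizes=cfg.codebook_sizes
    )
    encoder = HACEncoder(cfg.codebook_sizes, cfg.lags)
    babble = generate_babble(
        cfg.babble_duration,
        cfg.babble_talkers,
        seed=_seed_of(seed, _TAG_BABBLE),
        sample_rate=cfg.sample_rate,
        lexicon=lexicon,
    )
    return PipelineResources(seed, roster, lexicon, codebook, encoder, babble)


def _encode_signal(signal, res: PipelineResources, cfg: ExperimentConfig):
    feats = extract_features(signal, res.frame_spec)
    return res.encoder.encode(quantize(feats, res.codebook))


def prepare_test_bank(seed: int, res: PipelineResources, cfg: ExperimentConfig):
    """HAC+M vectors (zero meaning block) for every test cell.

    Returns ``{(word, speaker, snr): (contained_words, [vectors])}``; clean
    and noisy versions of the same sentence share the underlying waveform.
    """
    bank = {}
    for word in cfg.target_words:
        for speaker in cfg.test_speakers:
            manifest = generate_test_corpus(word, speaker, seed)
            signals = [
                synthesize_row(row, res.roster, res.lexicon, cfg.sample_rate)
                for row in manifest.itertuples()
            ]
            contained = tuple(manifest["keyword"])
            for snr in cfg.snr_levels:
                vectors = []
                for i, sig in enumerate(signals):
                    noisy = mix_at_snr(
                        sig,
                        res.babble,
                        snr,
                        offset_seed=_seed_of(seed, _TAG_MIX, i, int(10 * snr) if math.isfinite(snr) else 0),
                    )
                    v = _encode_signal(noisy, res, cfg)
                    vectors.append(
                        res.encoder.attach_meaning(
                            v, None, cfg.meaning_mass, cfg.acoustic_mass
                        )
                    )
                bank[(word, speaker, snr_label(snr))] = (contained, vectors)
    return bank


def _probe(W, condition, eval_words, point, seed, bank, cfg):
    """Decode every relevant test cell against the frozen memory."""
    rows = []
    for word in eval_words:
        for speaker in cfg.test_speakers:
            for snr in cfg.snr_levels:
                contained, vectors = bank[(word, speaker, snr_label(snr))]
                activations = [
                    decode(W, v, iters=cfg.inner_iters_decode)[1] for v in vectors
                ]
                is_target = np.array([c == word for c in contained])
                for measure in MEASURES:
                    if measure == "matching":
                        scores = np.array([matching_score(a) for a in activations])
                    else:
                        scores = np.array(
                            [recognition_score(a, word) for a in activations]
                        )
                    pref = listening_preference(
                        scores[is_target], scores[~is_target]
                    )
                    rows.append(
                        dict(
                            seed=seed,
                            word=word,
                            condition=condition,
                            speaker=speaker,
                            snr=snr_label(snr),
                            measure=measure,
                            sampling_point=point,
                            preference=pref.preference,
                        )
                    )
    return rows


def _learn_and_probe(manifest, condition, eval_words, seed, res, cfg, bank):
    W = init_memory(
        cfg.r_primitives,
        seed=_seed_of(seed, _TAG_MEMORY),
        acoustic_dim=res.encoder.dimension,
        meaning_dim=res.encoder.meaning_dim,
    )
    rows = []
    blocks = sorted(manifest["block_index"].unique())
    n_blocks = len(blocks)
    for b in blocks:
        for row in manifest[manifest["block_index"] == b].itertuples():
            sig = synthesize_row(row, res.roster, res.lexicon, cfg.sample_rate)
            v = _encode_signal(sig, res, cfg)
            x = res.encoder.attach_meaning(
                v, row.keyword, cfg.meaning_mass, cfg.acoustic_mass
            )
            learn_utterance(W, x, eta=cfg.eta, inner_iters=cfg.inner_iters_learn)
        if b % cfg.sampling_interval == 0 or b == n_blocks:
            point = b // cfg.sampling_interval
            rows.extend(_probe(W, condition, eval_words, point, seed, bank, cfg))
    return rows, W


def run_condition(
    condition: str,
    target_word: str,
    seed: int,
    cfg: ExperimentConfig,
    res: PipelineResources | None = None,
    bank=None,
):
    """Run one learning condition end-to-end for one target word and seed.

    Returns the tidy per-sampling-point rows (both measures, all test
    speakers and SNRs) and the final memory.
    """
    if res is None:
        res = build_resources(seed, cfg)
    if bank is None:
        bank = prepare_test_bank(seed, res, cfg)
    manifest = generate_learning_corpus(condition, target_word, seed)
    return _learn_and_probe(
        manifest, condition, (target_word,), seed, res, cfg, bank
    )


def run_full_design(
    cfg: ExperimentConfig = ExperimentConfig(),
    out_dir: str | Path | None = None,
    log=None,
):
    """All cells x words x seeds; returns (results, summary) tables.

    The baseline memory is word-independent (its corpus contains one token
    of every keyword per block), so per seed it is learned once and probed
    for all three target words; the frequency and multispeaker memories are
    target-specific. Failures in individual cells are reported and skipped.
    """
    all_rows = []
    failures = []
    for seed in cfg.seeds:
        if log:
            log(f"seed {seed}: building resources")
        res = build_resources(seed, cfg)
        bank = prepare_test_bank(seed, res, cfg)
        if "baseline" in cfg.learning_conditions:
            if log:
                log(f"seed {seed}: baseline")
            manifest = generate_learning_corpus(
                "baseline", cfg.target_words[0], seed
            )
            rows, _ = _learn_and_probe(
                manifest, "baseline", cfg.target_words, seed, res, cfg, bank
            )
            all_rows.extend(rows)
        for condition in cfg.learning_conditions:
            if condition == "baseline":
                continue
            for word in cfg.target_words:
                if log:
                    log(f"seed {seed}: {condition}/{word}")
                try:
                    rows, _ = run_condition(condition, word, seed, cfg, res, bank)
                    all_rows.extend(rows)
                except Exception as exc:  # keep going; report at the end
                    failures.append((seed, condition, word, repr(exc)))
    results = pd.DataFrame(all_rows)
    summary = summarise(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    if failures and log:
        for f in failures:
            log(f"FAILED cell: {f}")
    return results, summary


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate over sampling points, words and seeds per design cell."""
    if results.empty:
        return pd.DataFrame()
    g = results.groupby(["condition", "speaker", "snr", "measure"], sort=False)
    out = g["preference"].agg(["mean", "std", "count"]).reset_index()
    return out.rename(
        columns={"mean": "preference_mean", "std": "preference_sd", "count": "n"}
    )


def directional_patterns(results: pd.DataFrame) -> dict[str, dict]:
    """The qualitative replication suite, evaluated on cell means.

    Each entry reports the means entering the comparison and whether the
    expected direction holds:

    * clean/known preferences positive for both measures;
    * recognition preferences exceed matching preferences (known speaker);
    * recognition/known preferences decrease monotonically with noise and
      stay positive;
    * known-speaker preferences exceed unknown-speaker preferences overall;
    * increased word frequency beats the baseline (known speaker);
    * extra speakers in learning do not beat the baseline (known speaker).
    """
    df = results

    def m(**sel) -> float:
        q = df
        for k, v in sel.items():
            q = q[q[k] == v]
        return float(q["preference"].mean())

    out = {}
    vals = {meas: m(speaker="known", snr="clean", measure=meas) for meas in MEASURES}
    out["clean_known_positive"] = {
        "means": vals,
        "passed": all(v > 0 for v in vals.values()),
    }
    rec, mat = m(speaker="known", measure="recognition"), m(
        speaker="known", measure="matching"
    )
    out["recognition_exceeds_matching"] = {
        "means": {"recognition": rec, "matching": mat},
        "passed": rec > mat,
    }
    lvl = {
        s: m(speaker="known", measure="recognition", snr=s)
        for s in ("clean", "10dB", "5dB")
    }
    out["noise_monotone_recognition_known"] = {
        "means": lvl,
        "passed": lvl["clean"] >= lvl["10dB"] >= lvl["5dB"] and lvl["5dB"] > 0,
    }
    known, unknown = m(speaker="known"), m(speaker="unknown")
    out["known_exceeds_unknown"] = {
        "means": {"known": known, "unknown": unknown},
        "passed": known > unknown,
    }
    freq, base = m(speaker="known", condition="frequency"), m(
        speaker="known", condition="baseline"
    )
    out["frequency_exceeds_baseline_known"] = {
        "means": {"frequency": freq, "baseline": base},
        "passed": freq > base,
    }
    multi = m(speaker="known", condition="multispeaker")
    out["multispeaker_not_above_baseline_known"] = {
        "means": {"multispeaker": multi, "baseline": base},
        "passed": multi <= base,
    }
    return out
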