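"""Experiment orchestration: config, aggregation, patterns, CLI."""

import itertools
import math

import pandas as pd
import pytest
from click.testing import CliRunner

from hacnmf.cli import main
from hacnmf.experiment import (
    ExperimentConfig,
    directional_patterns,
    snr_label,
    summarise,
)


class TestConfig:
    def test_defaults_match_the_study_design(self):
        cfg = ExperimentConfig()
        assert cfg.r_primitives == 70
        assert cfg.codebook_sizes == (150, 150, 100)
        assert cfg.lags == (2, 5)
        assert math.isinf(cfg.snr_levels[0]) and cfg.snr_levels[1:] == (10.0, 5.0)
        assert 30 // cfg.sampling_interval == 10  # ten probes over 30 blocks

    def test_factorial_has_54_cells_per_measure(self):
        cfg = ExperimentConfig()
        cells = list(
            itertools.product(
                cfg.learning_conditions,
                cfg.target_words,
                cfg.test_speakers,
                cfg.snr_levels,
            )
        )
        assert len(cells) == 54

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "sample_rate: 8000\nsnr_levels: [clean, 10, 5]\nseeds: [3, 4]\n"
        )
        cfg = ExperimentConfig.from_yaml(p)
        assert cfg.sample_rate == 8000
        assert math.isinf(cfg.snr_levels[0])
        assert cfg.seeds == (3, 4)

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("learning_rate: 1\n")
        with pytest.raises(ValueError):
            ExperimentConfig.from_yaml(p)

    def test_snr_labels(self):
        assert snr_label(math.inf) == "clean"
        assert snr_label(10.0) == "10dB"
        assert snr_label(5.0) == "5dB"


def synthetic_results(prefs):
    """Tidy results frame from {(condition, speaker, snr, measure): pref}."""
    rows = []
    for (cond, spk, snr, meas), p in prefs.items():
        for word in ("cat", "mummy", "banana"):
            for sp in range(1, 11):
                rows.append(
                    dict(
                        seed=1, word=word, condition=cond, speaker=spk,
                        snr=snr, measure=meas, sampling_point=sp, preference=p,
                    )
                )
    return pd.DataFrame(rows)


class TestAggregation:
    @pytest.fixture()
    def results(self):
        prefs = {}
        for cond, base in (("baseline", 0.2), ("frequency", 0.3), ("multispeaker", 0.15)):
            for spk, spk_f in (("known", 1.0), ("unknown", 0.5)):
                for snr, snr_f in (("clean", 1.0), ("10dB", 0.6), ("5dB", 0.3)):
                    for meas, m_f in (("matching", 1.0), ("recognition", 2.0)):
                        prefs[(cond, spk, snr, meas)] = base * spk_f * snr_f * m_f
        return synthetic_results(prefs)

    def test_summary_has_one_row_per_cell_and_measure(self, results):
        s = summarise(results)
        assert len(s) == 3 * 2 * 3 * 2
        assert {"preference_mean", "preference_sd", "n"} <= set(s.columns)

    def test_patterns_pass_on_well_ordered_results(self, results):
        pats = directional_patterns(results)
        assert len(pats) == 6
        assert all(info["passed"] for info in pats.values())

    def test_patterns_detect_violations(self, results):
        # make noise help rather than hurt: monotonicity must fail
        broken = results.copy()
        sel = (broken.measure == "recognition") & (broken.snr == "5dB") & (
            broken.speaker == "known"
        )
        broken.loc[sel, "preference"] = 10.0
        pats = directional_patterns(broken)
        assert not pats["noise_monotone_recognition_known"]["passed"]


class TestPipelineDeterminism:
    def test_same_seed_reproduces_identical_preferences(self):
        """Three learning blocks probed against one test cell, run twice:
        every preference row must be bit-identical."""
        from hacnmf.corpus import generate_learning_corpus
        from hacnmf.experiment import (
            _learn_and_probe,
            build_resources,
            prepare_test_bank,
        )

        cfg = ExperimentConfig.reduced(
            target_words=("cat",),
            snr_levels=(math.inf,),
            test_speakers=("known",),
            n_codebook_sentences=150,
            babble_duration=3.0,
            seeds=(1,),
        )
        res = build_resources(1, cfg)
        bank = prepare_test_bank(1, res, cfg)
        manifest = generate_learning_corpus("baseline", "cat", 1)
        manifest = manifest[manifest["block_index"] <= 3]
        runs = [
            pd.DataFrame(
                _learn_and_probe(manifest, "baseline", ("cat",), 1, res, cfg, bank)[0]
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0], runs[1])
        assert set(runs[0]["sampling_point"]) == {1}


class TestCli:
    def test_generate_manifest_only_baseline(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "generate", "--condition", "baseline", "--target-word", "cat",
                "--seed", "2", "--out-dir", str(tmp_path), "--manifest-only",
            ],
        )
        assert result.exit_code == 0
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 450
        assert list(manifest.columns) == [
            "utterance_id", "wav_path", "speaker_id", "keyword",
            "condition_tag", "block_index",
        ]

    def test_report_prints_patterns(self, tmp_path):
        df = synthetic_results(
            {
                (c, s, n, m): 0.1
                for c in ("baseline", "frequency", "multispeaker")
                for s in ("known", "unknown")
                for n in ("clean", "10dB", "5dB")
                for m in ("matching", "recognition")
            }
        )
        p = tmp_path / "results.csv"
        df.to_csv(p, index=False)
        result = CliRunner().invoke(main, ["report", "--results", str(p)])
        assert result.exit_code == 0
        assert "recognition_exceeds_matching" in result.output

    def test_missing_config_is_an_error(self, tmp_path):
        result = CliRunner().invoke(
            main,
            ["learn", "--manifest", "nope.csv", "--codebook", "nope.json",
             "--out", str(tmp_path / "w.npz")],
        )
        assert result.exit_code != 0

    def test_unknown_flag_is_usage_error(self):
        result = CliRunner().invoke(main, ["generate", "--frobnicate"])
        assert result.exit_code != 0
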