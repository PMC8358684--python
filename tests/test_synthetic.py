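"""The synthetic corpus generator: sampling, linkage, calibration, I/O."""

import math

import numpy as np
import pandas as pd
import pytest

import pausemix as pm
from pausemix.synthetic import (
    _pi_from_ability,
    read_corpus_jsonl,
    read_truth_csv,
    write_corpus_jsonl,
    write_truth_csv,
)


class TestSampleMixturePauses:
    def test_degenerate_zero_variance_component(self):
        spec = pm.MixtureSpec([5.0], [0.0], [1.0])
        d = pm.sample_mixture_pauses(spec, 3, seed=0)
        np.testing.assert_allclose(d, math.exp(5.0), rtol=1e-15)

    def test_log_mean_matches_closed_form(self):
        # mixture mean on the log scale is sum pi_k mu_k = 5.0; the
        # log-scale variance is sum pi_k (sigma_k^2 + mu_k^2) - 5^2 = 1.25
        spec = pm.MixtureSpec([4.0, 6.0], [0.5, 0.5], [0.5, 0.5])
        d = pm.sample_mixture_pauses(spec, 50_000, seed=42)
        se = math.sqrt(1.25 / 50_000)
        assert abs(np.log(d).mean() - 5.0) < 3 * se

    def test_deterministic_under_fixed_seed(self, default_spec):
        a = pm.sample_mixture_pauses(default_spec, 1000, seed=7)
        b = pm.sample_mixture_pauses(default_spec, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_all_durations_positive_with_finite_logs(self, default_spec):
        d = pm.sample_mixture_pauses(default_spec, 5000, seed=1)
        assert np.all(d > 0) and np.all(np.isfinite(np.log(d)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(pm.ValidationError, match="sum to 1"):
            pm.MixtureSpec([1.0, 2.0], [1.0, 1.0], [0.6, 0.6])
        with pytest.raises(pm.ValidationError):
            pm.sample_mixture_pauses(pm.MixtureSpec([1.0], [1.0], [1.0]), 0, seed=0)


class TestAbilityLink:
    def test_zero_link_leaves_base_proportions(self):
        cfg = pm.CorpusConfig(score_link=0.0, target_corr=0.0)
        np.testing.assert_allclose(_pi_from_ability(cfg, 1.7), cfg.pi_base, rtol=1e-12)

    def test_monotone_link(self):
        cfg = pm.CorpusConfig()
        assert _pi_from_ability(cfg, -1.0)[0] >= _pi_from_ability(cfg, 1.0)[0]

    def test_pi_stays_on_simplex(self):
        cfg = pm.CorpusConfig(score_link=2.0, target_corr=-0.5)
        for a in (-4.0, -1.0, 0.0, 2.5, 4.0):
            pi = _pi_from_ability(cfg, a)
            assert abs(pi.sum() - 1.0) < 1e-12 and np.all(pi >= 0)


class TestGenerateEssay:
    def test_fixed_seed_reproducible(self):
        cfg = pm.CorpusConfig(seed=1).resolved()
        e1, t1 = pm.generate_essay(cfg, 0.5, seed=9, essay_id="x")
        e2, t2 = pm.generate_essay(cfg, 0.5, seed=9, essay_id="x")
        assert e1 == e2 and t1 == t2

    def test_low_effort_construction(self):
        cfg = pm.CorpusConfig(seed=1).resolved()
        essay, truth = pm.generate_essay(cfg, 0.0, seed=3, low_effort=True)
        assert essay.n_pauses < 30 and essay.strand1 == 0 and essay.strand3 == 0
        assert truth["low_effort"]

    def test_ability_outside_support_rejected(self):
        cfg = pm.CorpusConfig(seed=1).resolved()
        with pytest.raises(pm.ValidationError):
            pm.generate_essay(cfg, 9.0, seed=0)


class TestGenerateCorpus:
    def test_low_effort_count_exact(self, small_corpus_config):
        corpus, ledger = pm.generate_corpus(small_corpus_config)
        n_low = sum(1 for e in corpus if e.n_pauses < 30 and e.strand1 == 0 and e.strand3 == 0)
        assert n_low == int(0.09 * small_corpus_config.n_essays)
        assert len(corpus) == len(ledger) == small_corpus_config.n_essays

    def test_empty_corpus(self):
        corpus, ledger = pm.generate_corpus(pm.CorpusConfig(n_essays=0))
        assert corpus == [] and ledger.empty

    def test_ledger_pi_rows_on_simplex(self, small_corpus_config):
        _, ledger = pm.generate_corpus(small_corpus_config)
        pi = ledger[["pi_1", "pi_2", "pi_3"]].to_numpy()
        np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_end_to_end(self, small_corpus_config):
        c1, l1 = pm.generate_corpus(small_corpus_config)
        c2, l2 = pm.generate_corpus(small_corpus_config)
        assert c1 == c2
        pd.testing.assert_frame_equal(l1, l2)

    def test_calibrated_correlation_hits_target(self):
        # generator calibration: with the score-noise SD chosen from
        # target_corr, the realized corr(true pi_1, strand score) on one
        # 900-essay corpus lands within Monte-Carlo error of the target
        cfg = pm.CorpusConfig(n_essays=900, target_corr=-0.23, seed=17)
        corpus, ledger = pm.generate_corpus(cfg)
        engaged = ledger[~ledger.low_effort]
        r = float(np.corrcoef(engaged.pi_1, engaged.strand1)[0, 1])
        assert abs(r - (-0.23)) < 0.08

    def test_null_link_gives_null_correlation(self):
        # score_link=0 with heteroscedastic pi noise: pi_1 varies but is
        # independent of the scores; |r| stays inside the null band 2/sqrt(n)
        for seed in (1, 2, 3):
            cfg = pm.CorpusConfig(
                n_essays=900, score_link=0.0, target_corr=0.0, pi_noise_scale=0.5, seed=seed
            )
            corpus, ledger = pm.generate_corpus(cfg)
            engaged = ledger[~ledger.low_effort]
            r = float(np.corrcoef(engaged.pi_1, engaged.strand1)[0, 1])
            assert abs(r) < 0.11


class TestCalibration:
    def test_sign_mismatch_rejected(self):
        with pytest.raises(pm.ValidationError):
            pm.calibrate_score_noise(pm.CorpusConfig(score_link=0.35, target_corr=0.4))

    def test_unattainable_target_rejected(self):
        with pytest.raises(pm.ValidationError, match="unattainable"):
            pm.calibrate_score_noise(pm.CorpusConfig(score_link=0.1, target_corr=-0.99))


class TestCorpusIO:
    def test_jsonl_round_trip(self, tmp_path, small_corpus_config):
        corpus, ledger = pm.generate_corpus(small_corpus_config)
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(path, corpus)
        assert read_corpus_jsonl(path) == corpus

    def test_truth_csv_round_trip(self, tmp_path, small_corpus_config):
        _, ledger = pm.generate_corpus(small_corpus_config)
        path = tmp_path / "truth.csv"
        write_truth_csv(path, ledger)
        back = read_truth_csv(path)
        assert list(back.columns) == list(ledger.columns)
        np.testing.assert_allclose(back.pi_1.to_numpy(), ledger.pi_1.to_numpy(), rtol=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pi_base": (0.5, 0.4)},  # not a simplex with mu/sigma of len 3
            {"sigma": (0.45, -0.1, 0.45)},
            {"mu": (5.8, 4.6, 7.0)},  # not increasing
            {"low_effort_frac": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(pm.ValidationError):
            pm.CorpusConfig(**kwargs)
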