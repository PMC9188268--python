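import numpy as np
import pytest

from bimodalsim.fade import (FeatureNormalizer, HmmConfig, RecognitionMatrix,
                             SnrGrid, SrtOutsideGridError, concat_features,
                             extract_srt, recognize, run_grid,
                             sentence_segments, train_models)
from bimodalsim.scene import default_vocabulary


class TestConcat:
    def test_dimensions_add_up(self):
        out = concat_features(np.zeros((50, 31)), np.zeros((50, 46)))
        assert out.shape == (50, 77)

    def test_zero_electric_leaves_acoustic(self):
        rng = np.random.default_rng(0)
        acoustic = rng.standard_normal((30, 31))
        out = concat_features(acoustic, np.zeros((30, 46)))
        assert np.array_equal(out[:, :31], acoustic)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frame count"):
            concat_features(np.zeros((100, 31)), np.zeros((99, 46)))


class TestNormalizer:
    def test_moments_on_fit_corpus(self):
        rng = np.random.default_rng(1)
        mats = [rng.standard_normal((40, 8)) * 3 + 5 for _ in range(4)]
        norm = FeatureNormalizer.fit(mats)
        stacked = np.vstack([norm(m) for m in mats])
        assert np.max(np.abs(stacked.mean(axis=0))) < 1e-9
        assert np.max(np.abs(stacked.var(axis=0) - 1.0)) < 1e-9


class TestTraining:
    def test_clean_corpus_self_consistency(self, desk_corpus,
                                           clean_model_set):
        """Recognizing the noise-free training set scores 100 % correct."""
        models, train = clean_model_set
        test = [(feats, sent.slot_words)
                for (feats, _), sent in zip(train, desk_corpus.sentences)]
        assert recognize(test, models) == 100.0

    def test_training_deterministic(self, desk_corpus, clean_model_set):
        models, train = clean_model_set
        again = train_models(train, desk_corpus.vocabulary,
                             models.cfg, seed=0)
        for label, hmm in models.models.items():
            assert np.array_equal(hmm.means, again.models[label].means)
            assert np.array_equal(hmm.transmat, again.models[label].transmat)

    def test_missing_word_coverage_reported(self, clean_model_set):
        _, train = clean_model_set
        vocab = default_vocabulary(5)  # word ids beyond the training set
        with pytest.raises(ValueError, match="name04"):
            train_models(train, vocab, HmmConfig(states_word=2), seed=0)

    def test_constant_features_hit_variance_floor(self):
        """Degenerate (zero-variance) input trains without blowing up."""
        cfg = HmmConfig(states_word=2, states_edge=2)
        feats = np.ones((30, 4))
        segs = sentence_segments([(1600 * i, 1600 * (i + 1))
                                  for i in range(1, 6)],
                                 ("name00", "verb00", "number00",
                                  "adjective00", "object00"), 30)
        vocab = {s: [f"{s}00"] for s in
                 ("name", "verb", "number", "adjective", "object")}
        models = train_models([(feats, segs)] * 3, vocab, cfg, seed=0)
        for hmm in models.models.values():
            assert np.all(hmm.covars >= cfg.var_floor - 1e-12)
            assert np.all(np.isfinite(hmm.means))

    def test_scoring_arithmetic(self, desk_corpus, clean_model_set):
        """3 of 5 words correct on a single sentence scores 60 %."""
        models, train = clean_model_set
        feats, _ = train[0]
        truth = list(desk_corpus.sentences[0].slot_words)
        truth[1] = "verb_wrong"
        truth[3] = "adj_wrong"
        assert recognize([(feats, tuple(truth))], models) == 60.0


class TestChanceLevel:
    def test_noise_decodes_at_slot_chance(self):
        """Random-feature decoding against random truths: ~1/alternatives."""
        from bimodalsim.acoustic import AcousticFeatureConfig, logmel
        from bimodalsim.scene import generate_corpus
        corpus = generate_corpus(10, 20, seed=2, token_dur=0.12)
        cfg = AcousticFeatureConfig()
        hmm_cfg = HmmConfig(states_word=2, states_edge=2, states_silence=2)
        train = []
        for sent in corpus.sentences:
            feats = logmel(sent.waveform, cfg)
            segs = sentence_segments(sent.word_boundaries, sent.slot_words,
                                     feats.shape[0])
            train.append((feats, segs))
        models = train_models(train, corpus.vocabulary, hmm_cfg, seed=0)
        rng = np.random.default_rng(3)
        n_sent, n_frames = 40, 110
        test = []
        for _ in range(n_sent):
            noise_feats = rng.standard_normal((n_frames, 31)) * 20 + 40
            truth = tuple(rng.choice(corpus.vocabulary[s])
                          for s in ("name", "verb", "number",
                                    "adjective", "object"))
            test.append((noise_feats, truth))
        rate = recognize(test, models)
        # binomial: p=0.1, n=200 slots -> sd 2.1 points; allow 4 sd
        assert abs(rate - 10.0) <= 4 * 100 * np.sqrt(0.1 * 0.9 / (5 * n_sent))


def _logistic_matrix(midpoints, test_snrs, slope=2.0, chance=10.0):
    rates = np.empty((len(midpoints), len(test_snrs)))
    for i, mid in enumerate(midpoints):
        p = 1.0 / (1.0 + np.exp(-slope * (test_snrs - mid)))
        rates[i] = chance + (100.0 - chance) * p
    return RecognitionMatrix(rates, np.array(midpoints, float),
                             np.asarray(test_snrs, float))


class TestSrtExtraction:
    def test_linear_interpolation(self):
        m = RecognitionMatrix(np.array([[40.0, 60.0]]), np.array([0.0]),
                              np.array([-9.0, -6.0]))
        assert extract_srt(m) == pytest.approx(-7.5)

    def test_minimum_over_rows(self):
        m = RecognitionMatrix(np.array([[40.0, 60.0], [40.0, 40.0],
                                        [60.0, 80.0]]),
                              np.array([0.0, 1.0, 2.0]),
                              np.array([-9.0, -6.0]))
        # rows cross at -7.5 / never / -9 (already above at grid start)
        assert extract_srt(m) == pytest.approx(-9.0)

    def test_logistic_crossing_recovery(self):
        """Synthetic psychometric matrices: SRT within 0.3 dB of truth.

        The oracle is the analytic 50 % crossing of the chance-floored
        logistic: chance + (100 - chance) * p = 50 at p = 4/9.
        """
        slope = 2.0
        test_snrs = np.arange(-15.0, 10.0, 1.5)
        for mids in ([-7.5, -4.5], [-6.2, -1.0, 3.3], [0.4], [-3.14]):
            m = _logistic_matrix(mids, test_snrs, slope=slope)
            true_50 = min(mids) + np.log((4 / 9) / (5 / 9)) / slope
            assert extract_srt(m) == pytest.approx(true_50, abs=0.3)

    def test_no_crossing_raises_descriptive_error(self):
        m = RecognitionMatrix(np.full((2, 3), 20.0), np.zeros(2),
                              np.array([-6.0, -3.0, 0.0]))
        with pytest.raises(SrtOutsideGridError, match="extend"):
            extract_srt(m)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            RecognitionMatrix(np.array([[120.0]]), np.zeros(1), np.zeros(1))


class TestRunGrid:
    @staticmethod
    def _stub_featurizer(vocab, seed=0):
        """Synthetic featurizer: word-coded patterns + SNR-scaled noise."""
        slots = ("name", "verb", "number", "adjective", "object")
        rng_proto = np.random.default_rng(seed)
        protos = {w: rng_proto.standard_normal(6) * 4
                  for words in vocab.values() for w in words}

        def featurizer(snr_db, mixture):
            rng = np.random.default_rng([seed, int(snr_db * 100) & 0xffff,
                                         mixture])
            out = []
            for si in range(6):
                words = tuple(rng.choice(vocab[s]) for s in slots)
                frames, segs, pos = [], [], 0
                segs.append(("<start>", 0, 3))
                frames.extend([np.zeros(6)] * 3)
                pos = 3
                for w in words:
                    seg_len = 5
                    block = np.tile(protos[w], (seg_len, 1))
                    frames.extend(block)
                    segs.append((w, pos, pos + seg_len))
                    pos += seg_len
                segs.append(("<end>", pos, pos + 3))
                frames.extend([np.zeros(6)] * 3)
                feats = np.array(frames)
                noise_sd = 10 ** (-snr_db / 20.0)
                feats = feats + rng.standard_normal(feats.shape) * noise_sd
                out.append((feats, None, segs, words))
            return out

        return featurizer

    def test_shape_contract_and_monotone_trend(self):
        vocab = {s: [f"{s}0{i}" for i in range(2)]
                 for s in ("name", "verb", "number", "adjective", "object")}
        grid = SnrGrid(np.array([0.0, 20.0]), np.array([-20.0, 20.0]),
                       n_train_mixtures=2)
        cfg = HmmConfig(states_word=2, states_edge=2)
        matrix = run_grid(self._stub_featurizer(vocab), vocab, grid, cfg,
                          seed=0)
        assert matrix.rates.shape == (2, 2)
        # at +20 dB the patterns are clean; at -20 dB they are buried
        assert matrix.rates[1, 1] >= matrix.rates[1, 0]
        assert matrix.rates[1, 1] > 90.0
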