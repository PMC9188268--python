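import numpy as np
import pytest

from bimodalsim.acoustic import AcousticFeatureConfig, logmel
from bimodalsim.fade import HmmConfig, sentence_segments, train_models
from bimodalsim.scene import HeadModel, generate_corpus


@pytest.fixture(scope="session")
def desk_corpus():
    """Small balanced corpus: 4 alternatives per slot, 8 sentences."""
    return generate_corpus(4, 8, seed=1, token_dur=0.15)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def clean_model_set(desk_corpus):
    """Word HMMs trained on the clean desk corpus, with features."""
    cfg = AcousticFeatureConfig()
    hmm_cfg = HmmConfig(states_word=2, states_edge=2, states_silence=2)
    train = []
    for sent in desk_corpus.sentences:
        feats = logmel(sent.waveform, cfg)
        segs = sentence_segments(sent.word_boundaries, sent.slot_words,
                                 feats.shape[0])
        train.append((feats, segs))
    models = train_models(train, desk_corpus.vocabulary, hmm_cfg, seed=0)
    return models, train
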