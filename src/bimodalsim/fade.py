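"""Machine-learning back-end: HMM recognizer over a train x test SNR grid.

The simulation framework replaces the listener by an automatic speech
recognizer.  For every training SNR a set of whole-word left-to-right
HMMs (single-Gaussian emissions) is estimated from noisy matrix
sentences; each model set is then tested over the whole SNR range under a
slot-constrained grammar (start model, five slots of parallel word
models, end model), yielding a matrix of word-correct percentages with
training and testing SNR as its two dimensions.  The predicted speech
reception threshold (SRT) is the lowest testing SNR at which any model
set reaches the 50 % criterion, linearly interpolated between grid
points.

Per-word training uses :class:`hmmlearn.hmm.GaussianHMM` (Baum-Welch with
a zero-preserving left-to-right transition structure); the composite
grammar decoding is a dense Viterbi over the concatenated state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .scene import SLOT_NAMES

START, END, SIL = "<start>", "<end>", "<sil>"


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def concat_features(acoustic: np.ndarray, electric: np.ndarray) -> np.ndarray:
    """Column-wise concatenation, acoustic first; frame counts must match."""
    acoustic = np.asarray(acoustic, float)
    electric = np.asarray(electric, float)
    if acoustic.shape[0] != electric.shape[0]:
        raise ValueError(
            f"frame count mismatch: acoustic {acoustic.shape[0]} vs "
            f"electric {electric.shape[0]}; resample the electric features "
            "to the acoustic frame grid")
    return np.hstack([acoustic, electric])


@dataclass
class FeatureNormalizer:
    """Per-feature zero-mean/unit-variance scaling fitted on a corpus."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, matrices: list[np.ndarray]) -> "FeatureNormalizer":
        stacked = np.vstack(matrices)
        return cls(stacked.mean(axis=0),
                   np.maximum(stacked.std(axis=0), 1e-12))

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class HmmConfig:
    states_word: int = 8
    states_silence: int = 6
    states_edge: int = 3             # start and end models
    max_iter: int = 20
    tol: float = 1e-4
    var_floor: float = 1e-3
    self_loop: float = 0.5           # initial stay probability
    exit_prob: float = 0.5           # word-exit probability in the grammar

    def n_states(self, label: str) -> int:
        if label in (START, END):
            return self.states_edge
        if label == SIL:
            return self.states_silence
        return self.states_word


@dataclass
class WordHmm:
    label: str
    transmat: np.ndarray
    means: np.ndarray
    covars: np.ndarray               # diagonal variances, (states, dim)

    @property
    def n_states(self) -> int:
        return len(self.means)


@dataclass
class ModelSet:
    models: dict[str, WordHmm]
    vocabulary: dict[str, list[str]]
    cfg: HmmConfig
    normalizer: FeatureNormalizer | None = None
    meta: dict = field(default_factory=dict)


Segment = tuple[str, int, int]      # (label, first frame, past-the-end frame)


def sentence_segments(boundaries: list[tuple[int, int]],
                      slot_words: tuple[str, ...], n_frames: int,
                      frame_shift: int = 160) -> list[Segment]:
    """Word-level frame segmentation of one sentence's feature matrix."""
    segs: list[Segment] = []
    first_word = boundaries[0][0] // frame_shift
    segs.append((START, 0, max(first_word, 1)))
    prev_end = None
    for word, (s0, s1) in zip(slot_words, boundaries):
        f0, f1 = s0 // frame_shift, max(s1 // frame_shift, s0 // frame_shift + 1)
        if prev_end is not None and f0 > prev_end:
            segs.append((SIL, prev_end, f0))   # inter-word pause
        segs.append((word, min(f0, n_frames - 1), min(f1, n_frames)))
        prev_end = f1
    last = min(boundaries[-1][1] // frame_shift, n_frames - 1)
    segs.append((END, last, n_frames))
    return segs


def _left_to_right_transmat(n: int, stay: float) -> np.ndarray:
    a = np.zeros((n, n))
    for s in range(n - 1):
        a[s, s], a[s, s + 1] = stay, 1.0 - stay
    a[n - 1, n - 1] = 1.0
    return a


def _fit_word(label: str, segments: list[np.ndarray],
              cfg: HmmConfig, seed: int) -> WordHmm:
    dim = segments[0].shape[1]
    n_states = min(cfg.n_states(label), min(len(s) for s in segments))
    x = np.vstack(segments)
    lengths = [len(s) for s in segments]
    # flat start: uniform-segmentation means, global diagonal covariance
    means = np.zeros((n_states, dim))
    counts = np.zeros(n_states)
    for seg in segments:
        bounds = np.linspace(0, len(seg), n_states + 1).astype(int)
        for s in range(n_states):
            chunk = seg[bounds[s]:max(bounds[s + 1], bounds[s] + 1)]
            means[s] += chunk.sum(axis=0)
            counts[s] += len(chunk)
    means /= counts[:, None]
    gvar = np.maximum(x.var(axis=0), cfg.var_floor)

    hmm = GaussianHMM(n_components=n_states, covariance_type="diag",
                      min_covar=cfg.var_floor, n_iter=cfg.max_iter,
                      tol=cfg.tol, init_params="", params="tmc",
                      random_state=seed)
    hmm.startprob_ = np.eye(n_states)[0]
    hmm.transmat_ = _left_to_right_transmat(n_states, cfg.self_loop)
    hmm.means_ = means
    hmm.covars_ = np.tile(gvar, (n_states, 1))
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        hmm.fit(x, lengths)
    # hmmlearn's diag covars_ property returns (n, dim, dim); keep diagonals
    cv = np.asarray(hmm.covars_)
    if cv.ndim == 3:
        cv = np.einsum("sii->si", cv)
    return WordHmm(label, hmm.transmat_, hmm.means_,
                   np.maximum(cv, cfg.var_floor))


def train_models(train_data: list[tuple[np.ndarray, list[Segment]]],
                 vocabulary: dict[str, list[str]],
                 cfg: HmmConfig | None = None, seed: int = 0,
                 normalizer: FeatureNormalizer | None = None) -> ModelSet:
    """Estimate per-word, start and end HMMs from labelled utterances.

    ``train_data`` is a list of (feature matrix, segment list) pairs.
    Every vocabulary word must be covered by at least one segment.
    """
    cfg = cfg if cfg is not None else HmmConfig()
    by_label: dict[str, list[np.ndarray]] = {}
    for features, segments in train_data:
        for label, f0, f1 in segments:
            by_label.setdefault(label, []).append(features[f0:f1])
    required = [w for words in vocabulary.values() for w in words]
    for word in required:
        if word not in by_label:
            raise ValueError(f"no training material for word '{word}'")
    models = {label: _fit_word(label, segs, cfg, seed)
              for label, segs in sorted(by_label.items())}
    return ModelSet(models, vocabulary, cfg, normalizer)


# ---------------------------------------------------------------------------
# grammar-constrained recognition
# ---------------------------------------------------------------------------

class _Grammar:
    """Composite state space: start -> slot 1..5 (parallel words) -> end."""

    def __init__(self, model_set: ModelSet):
        cfg = model_set.cfg
        self.means, self.covars = [], []
        self.state_slot: list[int] = []      # -1 start, 0..4 slots, 5 end
        self.state_word: list[str] = []
        offsets: dict[tuple[int, str], int] = {}
        log_trans: list[tuple[int, int, float]] = []

        def add_model(hmm: WordHmm, slot: int) -> tuple[int, int]:
            base = len(self.means)
            for s in range(hmm.n_states):
                self.means.append(hmm.means[s])
                self.covars.append(hmm.covars[s])
                self.state_slot.append(slot)
                self.state_word.append(hmm.label)
            with np.errstate(divide="ignore"):
                la = np.log(hmm.transmat)
            for i in range(hmm.n_states):
                for j in range(hmm.n_states):
                    if np.isfinite(la[i, j]) and not (
                            i == j == hmm.n_states - 1):
                        log_trans.append((base + i, base + j, la[i, j]))
            last = base + hmm.n_states - 1
            log_trans.append((last, last, np.log(1.0 - cfg.exit_prob)))
            return base, last

        start0, start_exit = add_model(model_set.models[START], -1)
        prev_exits = [start_exit]
        log_exit = np.log(cfg.exit_prob)
        has_sil = SIL in model_set.models
        for slot_idx, slot in enumerate(SLOT_NAMES):
            words = model_set.vocabulary[slot]
            entries = []
            exits = []
            for word in words:
                b, e = add_model(model_set.models[word], slot_idx)
                entries.append(b)
                exits.append(e)
            branch = log_exit - np.log(len(words))
            if has_sil and slot_idx > 0:
                # optional inter-word pause: its own copy per junction so
                # the grammar cannot skip a slot through a shared model
                sil0, sil_exit = add_model(model_set.models[SIL], -1)
                for pe in prev_exits:
                    log_trans.append((pe, sil0, log_exit + np.log(0.5)))
                    for b in entries:
                        log_trans.append((pe, b,
                                          branch + np.log(0.5)))
                for b in entries:
                    log_trans.append((sil_exit, b,
                                      log_exit - np.log(len(words))))
            else:
                for pe in prev_exits:
                    for b in entries:
                        log_trans.append((pe, b, branch))
            prev_exits = exits
        end0, end_exit = add_model(model_set.models[END], 5)
        for pe in prev_exits:
            log_trans.append((pe, end0, log_exit))

        n = len(self.means)
        self.n_states = n
        self.log_a = np.full((n, n), -np.inf)
        for i, j, lp in log_trans:
            self.log_a[i, j] = max(self.log_a[i, j], lp)
        self.entry_state = start0
        self.final_state = end_exit
        self.means = np.array(self.means)
        self.covars = np.array(self.covars)

    def log_likelihoods(self, x: np.ndarray) -> np.ndarray:
        inv = 1.0 / self.covars
        const = -0.5 * (np.log(2 * np.pi * self.covars).sum(axis=1))
        quad = (x ** 2) @ inv.T - 2 * x @ (self.means * inv).T \
            + ((self.means ** 2) * inv).sum(axis=1)[None, :]
        return const[None, :] - 0.5 * quad

    def decode(self, x: np.ndarray) -> list[str]:
        """Viterbi path under the grammar; returns the five decoded words."""
        log_b = self.log_likelihoods(np.asarray(x, float))
        t_total, n = log_b.shape
        delta = np.full(n, -np.inf)
        delta[self.entry_state] = log_b[0, self.entry_state]
        back = np.zeros((t_total, n), np.int32)
        for t in range(1, t_total):
            cand = delta[:, None] + self.log_a
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(n)] + log_b[t]
        state = self.final_state if np.isfinite(delta[self.final_state]) \
            else int(np.argmax(delta))
        path = np.empty(t_total, np.int32)
        path[-1] = state
        for t in range(t_total - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        words = [None] * 5
        for s in path:
            slot = self.state_slot[s]
            if 0 <= slot < 5:
                words[slot] = self.state_word[s]
        return words


def recognize(test_data: list[tuple[np.ndarray, tuple[str, ...]]],
              model_set: ModelSet) -> float:
    """Word-correct percentage of slot-constrained Viterbi decoding.

    ``test_data`` is a list of (feature matrix, true five-word tuple).
    """
    grammar = _Grammar(model_set)
    n_correct = n_total = 0
    for features, truth in test_data:
        decoded = grammar.decode(features)
        n_correct += sum(d == t for d, t in zip(decoded, truth))
        n_total += 5
    return 100.0 * n_correct / n_total


# ---------------------------------------------------------------------------
# SNR grid and SRT
# ---------------------------------------------------------------------------

@dataclass
class SnrGrid:
    train_snrs: np.ndarray
    test_snrs: np.ndarray
    n_train_mixtures: int = 8
    n_test_mixtures: int = 1

    def __post_init__(self) -> None:
        self.train_snrs = np.sort(np.asarray(self.train_snrs, float))
        self.test_snrs = np.sort(np.asarray(self.test_snrs, float))

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float = 3.0,
                   **kw) -> "SnrGrid":
        snrs = np.arange(lo, hi + step / 2, step)
        return cls(snrs, snrs.copy(), **kw)


@dataclass
class RecognitionMatrix:
    rates: np.ndarray                # (train, test) word-correct percentages
    train_snrs: np.ndarray
    test_snrs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.rates < 0) | (self.rates > 100)):
            raise ValueError("recognition rates must lie in [0, 100]")


def run_grid(featurizer, vocabulary: dict[str, list[str]],
             grid: SnrGrid, hmm_cfg: HmmConfig | None = None,
             seed: int = 0, meta: dict | None = None) -> RecognitionMatrix:
    """Train at every training SNR and test over the whole SNR range.

    ``featurizer(snr_db, mixture_index)`` must return a list over
    sentences of ``(acoustic, electric_or_None, segments, slot_words)``
    where segments index the frame axis.  Mixture indices
    ``0..n_train_mixtures-1`` are training noise instances; index
    ``n_train_mixtures`` is the held-out test instance.  The electric
    features are normalized with statistics of each training set
    (mean 0 / variance 1 per feature) before concatenation.
    """
    hmm_cfg = hmm_cfg if hmm_cfg is not None else HmmConfig()
    test_cache: dict[float, list] = {}
    rates = np.zeros((len(grid.train_snrs), len(grid.test_snrs)))
    for ti, train_snr in enumerate(grid.train_snrs):
        raw = []
        for mix in range(grid.n_train_mixtures):
            raw.extend(featurizer(float(train_snr), mix))
        has_electric = raw[0][1] is not None
        norm = FeatureNormalizer.fit([r[1] for r in raw]) if has_electric \
            else None
        train_data = []
        for acoustic, electric, segments, _words in raw:
            feats = concat_features(acoustic, norm(electric)) \
                if has_electric else acoustic
            train_data.append((feats, segments))
        model_set = train_models(train_data, vocabulary, hmm_cfg, seed)
        model_set.normalizer = norm
        grammar = _Grammar(model_set)
        for si, test_snr in enumerate(grid.test_snrs):
            if test_snr not in test_cache:
                test_cache[test_snr] = featurizer(float(test_snr),
                                                  grid.n_train_mixtures)
            n_correct = n_total = 0
            for acoustic, electric, _segs, words in test_cache[test_snr]:
                feats = concat_features(acoustic, norm(electric)) \
                    if has_electric else acoustic
                decoded = grammar.decode(feats)
                n_correct += sum(d == t for d, t in zip(decoded, words))
                n_total += 5
            rates[ti, si] = 100.0 * n_correct / n_total
    return RecognitionMatrix(rates, grid.train_snrs, grid.test_snrs,
                             meta or {})


class SrtOutsideGridError(ValueError):
    """No train row crosses the criterion; widen the SNR grid."""


def extract_srt(matrix: RecognitionMatrix, criterion: float = 50.0) -> float:
    """Lowest testing SNR reaching the criterion, over all train rows.

    Per train row the rate-vs-test-SNR curve is linearly interpolated at
    its first upward crossing of the criterion; the SRT is the minimum
    crossing over rows.  Rows that never cross are skipped.
    """
    crossings = []
    snrs = matrix.test_snrs
    for row in matrix.rates:
        for j in range(len(snrs)):
            if row[j] >= criterion:
                if j == 0:
                    crossings.append(snrs[0])
                else:
                    frac = (criterion - row[j - 1]) / (row[j] - row[j - 1])
                    crossings.append(snrs[j - 1] + frac * (snrs[j] - snrs[j - 1]))
                break
    if not crossings:
        raise SrtOutsideGridError(
            f"no train row reaches {criterion:.0f} % within the test grid "
            f"[{snrs[0]:g}, {snrs[-1]:g}] dB; extend the SNR range upwards")
    return float(min(crossings))
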