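"""Synthetic acoustic scenes for bimodal-listening simulations.

This module generates the raw material every model chain in the package
consumes: a closed-set matrix-style sentence corpus (5 slots x 10
alternatives, the structure of the German OLSA test), speech-shaped
stationary noise and multi-talker babble, and a parametric four-microphone
head model that spatializes sources with direction-dependent interaural
time and level differences.  Measured 4-channel head-related impulse
responses can be substituted when available; the parametric model stands in
for them and preserves the cues the beamformers exploit.

All audio is mono float64 at 16 kHz unless stated otherwise.  Channel
order for 4-channel signals is (left-front, left-rear, right-front,
right-rear).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

FS = 16000
SLOT_NAMES = ("name", "verb", "number", "adjective", "object")
CHANNELS = ("left_front", "left_rear", "right_front", "right_rear")
SPEED_OF_SOUND = 343.0

#: azimuths (degrees, positive to the listener's right) of the five babble
#: loudspeakers surrounding the listener in the diffuse scenario
BABBLE_AZIMUTHS = (-90.0, -45.0, 45.0, 90.0, -180.0)

SCENARIOS = ("S0N-90", "S0N0", "S0N+90", "S0N20TB")


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

@dataclass
class MatrixSentence:
    """One five-word sentence: word ids, waveform and word boundaries."""

    slot_words: tuple[str, ...]
    waveform: np.ndarray
    word_boundaries: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.slot_words) != 5:
            raise ValueError("a matrix sentence has exactly 5 words")
        prev_end = 0
        for start, end in self.word_boundaries:
            if not (prev_end <= start < end <= len(self.waveform)):
                raise ValueError("word boundaries must be ordered, "
                                 "non-overlapping and inside the waveform")
            prev_end = end


@dataclass
class Corpus:
    sentences: list[MatrixSentence]
    vocabulary: dict[str, list[str]]
    seed: int
    fs: int = FS

    def __len__(self) -> int:
        return len(self.sentences)

    def word_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sent in self.sentences:
            for w in sent.slot_words:
                counts[w] = counts.get(w, 0) + 1
        return counts


def default_vocabulary(n_alternatives: int = 10) -> dict[str, list[str]]:
    """Word identifiers per slot, e.g. ``name03`` or ``verb07``."""
    return {slot: [f"{slot}{i:02d}" for i in range(n_alternatives)]
            for slot in SLOT_NAMES}


def _token_params(slot_index: int, word_index: int, token_dur: float):
    """Deterministic spectro-temporal recipe for one vocabulary word.

    Tokens are harmonic complexes with two formant-like resonances whose
    frequencies depend on the word identity only, so every utterance of a
    word is acoustically identical up to sentence context.  The RNG is
    keyed on the identity, never on the corpus seed.
    """
    rng = np.random.default_rng(900_001 + 101 * slot_index + word_index)
    f0 = 95.0 + 12.0 * slot_index + 7.0 * word_index + rng.uniform(0, 4)
    # formants drawn from slot-specific regions so slots differ grossly and
    # words within a slot differ finely
    f1 = 300.0 + 90.0 * word_index + rng.uniform(0, 40)
    f2 = 1200.0 + 55.0 * slot_index * 10 + 220.0 * word_index + rng.uniform(0, 80)
    f2 = min(f2, 6800.0)
    dur = token_dur * (0.8 + 0.4 * ((word_index * 7 + slot_index * 3) % 10) / 9.0)
    return f0, f1, f2, dur


def synth_word_token(slot: str, word_id: str, fs: int = FS,
                     token_dur: float = 0.4) -> np.ndarray:
    """Synthesize the deterministic waveform for one vocabulary word."""
    slot_index = SLOT_NAMES.index(slot)
    word_index = int(word_id[-2:])
    f0, f1, f2, dur = _token_params(slot_index, word_index, token_dur)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    tone = np.zeros(n)
    for k in range(1, int(7000 // f0) + 1):
        fk = k * f0
        # formant-like spectral envelope: two resonant humps + tilt
        amp = (1.0 / (1.0 + ((fk - f1) / 150.0) ** 2)
               + 0.5 / (1.0 + ((fk - f2) / 250.0) ** 2)) / k ** 0.3
        tone += amp * np.sin(2 * np.pi * fk * t)
    # attack / decay envelope with a word-specific modulation
    env = np.minimum(t / 0.02, 1.0) * np.minimum((dur - t) / 0.05, 1.0)
    env = np.clip(env, 0.0, 1.0)
    env *= 1.0 + 0.3 * np.sin(2 * np.pi * (3.0 + word_index) * t)
    out = tone * env
    rms = np.sqrt(np.mean(out ** 2))
    return out / rms * 0.05


def generate_corpus(vocabulary_spec: int | dict[str, list[str]] = 10,
                    n_sentences: int = 120, seed: int = 0, fs: int = FS,
                    token_dur: float = 0.4, gap_dur: float = 0.04,
                    pad_dur: float = 0.1) -> Corpus:
    """Generate a balanced matrix-sentence corpus.

    Each of the five slots draws every alternative exactly
    ``n_sentences / n_alternatives`` times (the closed-set balance of the
    matrix test).  ``n_sentences`` must therefore be divisible by the
    number of alternatives per slot.

    Parameters
    ----------
    vocabulary_spec : int or dict
        Number of alternatives per slot, or an explicit slot -> word-id map.
    token_dur : float
        Nominal word-token duration in seconds (words vary +-20 %).
    gap_dur, pad_dur : float
        Inter-word gap and leading/trailing silence, in seconds.
    """
    if isinstance(vocabulary_spec, int):
        vocab = default_vocabulary(vocabulary_spec)
    else:
        vocab = {slot: list(words) for slot, words in vocabulary_spec.items()}
    n_alt = {slot: len(words) for slot, words in vocab.items()}
    for slot, n in n_alt.items():
        if n_sentences % n != 0:
            raise ValueError(
                f"n_sentences={n_sentences} not divisible by the "
                f"{n} alternatives in slot '{slot}'; corpus would be unbalanced")

    rng = np.random.default_rng(seed)
    # balanced word schedule per slot, shuffled independently
    schedule = {}
    for slot in SLOT_NAMES:
        reps = n_sentences // n_alt[slot]
        ids = np.repeat(np.arange(n_alt[slot]), reps)
        rng.shuffle(ids)
        schedule[slot] = ids

    tokens = {slot: [synth_word_token(slot, w, fs, token_dur)
                     for w in vocab[slot]] for slot in SLOT_NAMES}
    pad = int(round(pad_dur * fs))
    gap = int(round(gap_dur * fs))

    sentences = []
    for i in range(n_sentences):
        words = tuple(vocab[slot][schedule[slot][i]] for slot in SLOT_NAMES)
        pieces = [np.zeros(pad)]
        boundaries = []
        pos = pad
        for j, slot in enumerate(SLOT_NAMES):
            tok = tokens[slot][schedule[slot][i]]
            pieces.append(tok)
            boundaries.append((pos, pos + len(tok)))
            pos += len(tok)
            if j < 4:
                pieces.append(np.zeros(gap))
                pos += gap
        pieces.append(np.zeros(pad))
        wave = np.concatenate(pieces)
        sentences.append(MatrixSentence(words, wave, boundaries))
    return Corpus(sentences, vocab, seed, fs)


def corpus_long_term_spectrum(corpus: Corpus, nperseg: int = 256):
    """Welch PSD of the concatenated corpus (the speech long-term spectrum)."""
    cat = np.concatenate([s.waveform for s in corpus.sentences])
    freqs, psd = sps.welch(cat, fs=corpus.fs, nperseg=nperseg)
    return freqs, psd


def make_speech_shaped_noise(corpus: Corpus, duration: float,
                             seed: int = 0) -> np.ndarray:
    """Stationary Gaussian noise with the corpus long-term spectrum.

    The analogue of the matrix test's own test-specific noise: white
    Gaussian noise is shaped in the frequency domain by the square root of
    the corpus Welch PSD and RMS-matched to the corpus speech.
    """
    if not len(corpus):
        raise ValueError("corpus is empty")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * corpus.fs))
    rng = np.random.default_rng(seed)
    cat = np.concatenate([s.waveform for s in corpus.sentences])
    mag = np.abs(np.fft.rfft(cat))
    # phase randomization of the concatenated corpus: the noise inherits
    # the exact long-term magnitude spectrum; fresh phase draws per block
    blocks = []
    remaining = n
    while remaining > 0:
        phase = rng.uniform(0, 2 * np.pi, len(mag))
        phase[0] = 0.0
        if len(cat) % 2 == 0:
            phase[-1] = 0.0
        block = np.fft.irfft(mag * np.exp(1j * phase), len(cat))
        blocks.append(block[:remaining])
        remaining -= len(block)
    out = np.concatenate(blocks)
    cat_rms = np.sqrt(np.mean(cat ** 2))
    return out / np.sqrt(np.mean(out ** 2)) * cat_rms


def make_babble(corpus: Corpus, n_talkers_per_stream: int = 4,
                n_streams: int = 5, seed: int = 0,
                duration: float | None = None) -> list[np.ndarray]:
    """Multi-talker babble: each stream sums independent talkers.

    A talker is an independent random permutation of the corpus sentences,
    concatenated; summing ``n_talkers_per_stream`` of them gives one
    stream.  Streams are RMS-equalized and mutually uncorrelated because
    no two talkers share a permutation phase.
    """
    if len(corpus) < 2:
        raise ValueError("corpus too small to draw uncorrelated streams")
    rng = np.random.default_rng(seed)
    total_len = sum(len(s.waveform) for s in corpus.sentences)
    out_len = total_len if duration is None else int(round(duration * corpus.fs))
    if out_len > total_len:
        raise ValueError("requested duration exceeds corpus material")
    streams = []
    for _ in range(n_streams):
        acc = np.zeros(out_len)
        for _ in range(n_talkers_per_stream):
            order = rng.permutation(len(corpus))
            pieces, have = [], 0
            for i in order:
                pieces.append(corpus.sentences[i].waveform)
                have += len(pieces[-1])
                if have >= out_len + 1600:
                    break
            cat = np.concatenate(pieces)
            # per-talker rate/pitch jitter (+-3 %): a crude voice difference
            # that decorrelates talkers sharing the token inventory
            rate = rng.uniform(0.97, 1.03)
            cat = np.interp(np.arange(out_len) * rate,
                            np.arange(len(cat)), cat)
            acc += cat
        acc /= np.sqrt(np.mean(acc ** 2))
        streams.append(acc)
    return streams


# ---------------------------------------------------------------------------
# head model and spatialization
# ---------------------------------------------------------------------------

@dataclass
class HeadModel:
    """Parametric 4-microphone head: Woodworth-type ITD + head shadow.

    Each side carries a front and a rear microphone separated by
    ``mic_spacing``.  The ear contralateral to a lateral source is
    attenuated by ``shadow_db * |sin(azimuth)|`` broadband plus a
    first-order low-pass whose strength scales with laterality.  Measured
    HRIRs (4-channel, one set per azimuth) can be supplied via ``hrirs``;
    they then replace the parametric transfer functions.
    """

    itd_max: float = 700e-6          # max interaural time difference [s]
    mic_spacing: float = 0.01        # front/rear spacing per side [m]
    shadow_db: float = 8.0           # broadband far-ear shadow at 90 deg
    shadow_cutoff: float = 2000.0    # low-pass corner of the shadow [Hz]
    fs: int = FS
    filter_tail: int = 256           # extra output samples for filter decay
    reverb_rt: float = 0.0           # exponential tail RT60 [s]; 0 = off
    reverb_level_db: float = -20.0   # tail level re direct sound
    hrirs: dict[float, np.ndarray] | None = None

    mic_positions = CHANNELS

    def _base_delay(self) -> float:
        return self.itd_max / 2 + self.mic_spacing / SPEED_OF_SOUND

    def transfer(self, azimuth: float, freqs: np.ndarray) -> np.ndarray:
        """Complex 4 x len(freqs) transfer functions for a plane wave.

        Azimuth in degrees, positive to the listener's right.  Symmetric by
        construction: the left channels at ``az`` equal the right channels
        at ``-az``.
        """
        az = np.deg2rad(azimuth)
        sin_az, cos_az = np.sin(az), np.cos(az)
        h = np.empty((4, len(freqs)), complex)
        base = self._base_delay()
        for ci, (side, fr) in enumerate(
                [(-1, +1), (-1, -1), (+1, +1), (+1, -1)]):
            # side -1 = left ear, +1 = right ear; fr +1 front mic, -1 rear
            ear_delay = side * sin_az * self.itd_max / 2
            mic_delay = (1 - fr) / 2 * (self.mic_spacing / SPEED_OF_SOUND) * cos_az
            tau = base + ear_delay + mic_delay
            # shadow on the ear opposite the source
            lat = max(0.0, -side * sin_az) if side * sin_az < 0 else 0.0
            gain = 10.0 ** (-self.shadow_db * lat / 20.0)
            lp = (1.0 + (freqs / self.shadow_cutoff) ** 2) ** (-lat / 2.0)
            h[ci] = gain * lp * np.exp(-2j * np.pi * freqs * tau)
        return h

    def head_shadow_db(self, azimuth: float, frequency: float) -> float:
        """Far-ear attenuation in dB at one azimuth and frequency (left ear)."""
        hz = np.atleast_1d(float(frequency))
        h = self.transfer(azimuth, hz)
        return -20 * np.log10(np.abs(h[0, 0]) + 1e-300)


def load_hrirs(paths_by_azimuth: dict[float, str]) -> dict[float, np.ndarray]:
    """Load measured 4-channel HRIRs from WAV files keyed by azimuth."""
    from .audio_io import read_wav
    out = {}
    for az, path in paths_by_azimuth.items():
        fs, data = read_wav(path)
        if data.ndim != 2 or data.shape[0] != 4:
            raise ValueError(f"HRIR {path} must have 4 channels")
        out[float(az)] = data
    return out


def spatialize(source: np.ndarray, azimuth: float,
               head: HeadModel) -> np.ndarray:
    """Render a mono source at an azimuth into the 4 microphone channels."""
    if not -180.0 <= azimuth < 180.0:
        raise ValueError("azimuth must lie in [-180, 180)")
    source = np.asarray(source, float)
    if head.hrirs is not None:
        key = min(head.hrirs, key=lambda a: abs(a - azimuth))
        irs = head.hrirs[key]
        n_out = len(source) + irs.shape[1] - 1
        return np.stack([sps.fftconvolve(source, irs[c]) for c in range(4)])

    n_out = len(source) + head.filter_tail
    freqs = np.fft.rfftfreq(n_out, 1.0 / head.fs)
    h = head.transfer(azimuth, freqs)
    if head.reverb_rt > 0:
        h = h * _reverb_transfer(head, freqs)
    spec = np.fft.rfft(source, n_out)
    return np.fft.irfft(spec * h, n_out)


def _reverb_transfer(head: HeadModel, freqs: np.ndarray) -> np.ndarray:
    """Diffuse exponential-decay tail, identical on all channels."""
    n = 2 * (len(freqs) - 1)
    rng = np.random.default_rng(4242)  # fixed: the room, not an experiment seed
    t = np.arange(n) / head.fs
    tail = rng.standard_normal(n) * np.exp(-6.91 * t / head.reverb_rt)
    tail[0] = 0.0
    tail *= 10 ** (head.reverb_level_db / 20) / (np.sqrt(np.mean(tail ** 2)) + 1e-30)
    ir = np.zeros(n)
    ir[0] = 1.0
    ir += tail
    return np.fft.rfft(ir)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A spatial scenario: frontal target plus configured noise sources."""

    scenario_id: str
    snr_db: float
    target_azimuth: float = 0.0
    noise_sources: list[tuple[float, str]] = field(default_factory=list)

    @classmethod
    def standard(cls, scenario_id: str, snr_db: float) -> "Scene":
        if scenario_id == "S0N-90":
            sources = [(-90.0, "ssn")]
        elif scenario_id == "S0N0":
            sources = [(0.0, "ssn")]
        elif scenario_id == "S0N+90":
            sources = [(90.0, "ssn")]
        elif scenario_id == "S0N20TB":
            sources = [(az, "babble") for az in BABBLE_AZIMUTHS]
        else:
            raise ValueError(f"unknown scenario {scenario_id!r}; "
                             f"expected one of {SCENARIOS}")
        return cls(scenario_id, snr_db, 0.0, sources)

    def validate(self) -> None:
        if self.scenario_id == "S0N20TB":
            azs = {az for az, _ in self.noise_sources}
            if len(self.noise_sources) < 5 or len(azs) != len(self.noise_sources):
                raise ValueError("diffuse babble scene needs >=5 noise "
                                 "sources at distinct azimuths")
        elif len(self.noise_sources) != 1:
            raise ValueError("single-noise scenario needs exactly one source")


def speech_activity_gate(speech: np.ndarray, fs: int = FS,
                         threshold_db: float = -40.0) -> np.ndarray:
    """Boolean gate marking speech-active samples (envelope re max)."""
    mono = np.max(np.abs(np.atleast_2d(speech)), axis=0)
    win = int(0.01 * fs)
    env = sps.fftconvolve(mono, np.ones(win) / win, mode="same")
    return env > env.max() * 10 ** (threshold_db / 20)


def measured_snr_db(speech_4ch: np.ndarray, noise_4ch: np.ndarray,
                    fs: int = FS) -> float:
    """Broadband SNR over speech-active samples, mean of the front mics."""
    gate = speech_activity_gate(speech_4ch, fs)
    fronts = [0, 2]
    ps = np.mean(speech_4ch[fronts][:, gate] ** 2)
    pn = np.mean(noise_4ch[fronts][:, gate] ** 2)
    return 10 * np.log10(ps / pn)


def mix_scene(scene: Scene, speech: np.ndarray, head: HeadModel,
              seed: int = 0, corpus: Corpus | None = None,
              noise_bank: dict[str, list[np.ndarray]] | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatialize target and noise and mix at the scene SNR.

    Returns ``(mixture, speech_only, noise_only)`` as 4-channel arrays with
    ``mixture = speech_only + noise_only`` sample-exactly.  The broadband
    SNR of the two separated parts, measured over speech-active samples on
    the two front microphones, equals ``scene.snr_db`` by construction.

    Noise material comes from ``noise_bank`` (keys ``"ssn"`` / ``"babble"``,
    each a list of mono signals to draw from) or is generated from
    ``corpus`` on the fly; a fresh draw/segment per call via ``seed``.
    """
    scene.validate()
    speech = np.asarray(speech, float)
    if not np.any(speech):
        raise ValueError("speech input is silent")
    rng = np.random.default_rng(seed)
    speech_4 = spatialize(speech, scene.target_azimuth, head)
    n_out = speech_4.shape[1]

    dur = len(speech) / head.fs + 0.2
    noise_4 = np.zeros_like(speech_4)
    for k, (az, kind) in enumerate(scene.noise_sources):
        if noise_bank is not None and kind in noise_bank:
            bank = noise_bank[kind]
            src = bank[int(rng.integers(len(bank)))]
            if len(src) < int(dur * head.fs):
                raise ValueError("noise bank entry shorter than the speech")
            off = int(rng.integers(0, len(src) - int(dur * head.fs) + 1))
            mono = src[off:off + int(dur * head.fs)]
        elif corpus is not None:
            sub_seed = int(rng.integers(2 ** 31))
            if kind == "ssn":
                mono = make_speech_shaped_noise(corpus, dur, sub_seed)
            else:
                mono = make_babble(corpus, 4, 1, sub_seed, duration=dur)[0]
        else:
            raise ValueError("need corpus or noise_bank to synthesize noise")
        if not np.any(mono):
            raise ValueError("silent noise source")
        rendered = spatialize(mono, az, head)[:, :n_out]
        if rendered.shape[1] < n_out:
            rendered = np.pad(rendered, ((0, 0), (0, n_out - rendered.shape[1])))
        noise_4 += rendered

    # calibrate the noise gain so the gated front-mic SNR is exact
    gate = speech_activity_gate(speech_4, head.fs)
    fronts = [0, 2]
    ps = np.mean(speech_4[fronts][:, gate] ** 2)
    pn = np.mean(noise_4[fronts][:, gate] ** 2)
    noise_4 *= np.sqrt(ps / pn) * 10 ** (-scene.snr_db / 20)
    return speech_4 + noise_4, speech_4, noise_4
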