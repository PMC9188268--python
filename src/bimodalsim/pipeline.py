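"""End-to-end processing chains tying scene, devices and models together.

The listener is always fitted as in the reference population this package
emulates: hearing aid (acoustic hearing) on the left, cochlear implant on
the right.  A :class:`DeviceChain` turns the 4-microphone scene signals
into the two device output channels for a chosen beamformer; on top of it
sit the two prediction paths (ASR back-end in :mod:`.fade`, SII back-end
in :mod:`.bsim`) and the instrumental-SNR benefit metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bsim as bsim_mod
from .acoustic import (AcousticFeatureConfig, Audiogram, apply_audibility,
                       logmel, n_frames, threshold_spl)
from .electric import AceConfig, IrConfig, NervePopulation, electric_features
from .evaluation import instrumental_snr
from .fade import (HmmConfig, RecognitionMatrix, SnrGrid, extract_srt,
                   run_grid, sentence_segments)
from .frontend import (AdmState, CompressorConfig, MvdrFilter, adm_process,
                       compress_ha, hagerman_separate, headphone_filter,
                       mvdr_design, mvdr_process)
from .bsim import BandSnrProfile, BsimConfig, EaWeighting, SrtResult, ci_auralize, find_srt
from .scene import (Corpus, HeadModel, Scene, make_babble,
                    make_speech_shaped_noise, mix_scene)


def _subseed(*keys: int) -> list[int]:
    """Stable non-negative RNG key from a tuple of integers."""
    return [int(k) & 0x7FFFFFFF for k in keys]


# ---------------------------------------------------------------------------
# device chain
# ---------------------------------------------------------------------------

@dataclass
class DeviceChain:
    """Beamformer + hearing-aid processing: 4 mics in, (left, right) out."""

    beamformer: str = "NoBF"
    head: HeadModel = field(default_factory=HeadModel)
    audiogram: Audiogram = field(default_factory=Audiogram.moderate_sloping)
    compressor: CompressorConfig = field(default_factory=CompressorConfig)
    adm_step: float = 0.1
    headphone_fir: np.ndarray | None = None
    compress_left: bool = True
    _mvdr: MvdrFilter | None = field(default=None, repr=False)

    def mvdr_filter(self) -> MvdrFilter:
        if self._mvdr is None:
            self._mvdr = mvdr_design(self.head)
        return self._mvdr

    def beamform(self, x4: np.ndarray) -> np.ndarray:
        if self.beamformer == "NoBF":
            return np.stack([x4[0], x4[2]])
        if self.beamformer == "ADM":
            left = adm_process(x4[0], x4[1],
                               AdmState(step_size=self.adm_step,
                                        fs=self.head.fs,
                                        mic_spacing=self.head.mic_spacing))
            right = adm_process(x4[2], x4[3],
                                AdmState(step_size=self.adm_step,
                                         fs=self.head.fs,
                                         mic_spacing=self.head.mic_spacing))
            return np.stack([left, right])
        if self.beamformer == "MVDR":
            return mvdr_process(x4, self.mvdr_filter())
        raise ValueError(f"unknown beamformer {self.beamformer!r}")

    def process(self, x4: np.ndarray) -> np.ndarray:
        """Full deterministic chain; left channel gets HA compression."""
        y = self.beamform(np.atleast_2d(np.asarray(x4, float)))
        left = y[0]
        if self.compress_left:
            left = compress_ha(left, self.audiogram, self.compressor)
        left = headphone_filter(left, self.headphone_fir)
        return np.stack([left, y[1]])


# ---------------------------------------------------------------------------
# bimodal feature extraction (ASR path)
# ---------------------------------------------------------------------------

@dataclass
class FeatureChain:
    """Acoustic + electric feature extraction behind the device chain."""

    devices: DeviceChain = field(default_factory=DeviceChain)
    acoustic_cfg: AcousticFeatureConfig = field(
        default_factory=AcousticFeatureConfig)
    ace_cfg: AceConfig = field(default_factory=AceConfig)
    pop: NervePopulation = field(default_factory=NervePopulation)
    ir_cfg: IrConfig = field(default_factory=IrConfig)
    side_mode: str = "bimodal"       # bimodal | acoustic | ci
    ci_agc_rms: float = 0.05         # CI front-end AGC target (re full scale)

    def featurize(self, mixture_4ch: np.ndarray, seed: int,
                  ) -> tuple[np.ndarray, np.ndarray | None]:
        """(acoustic features, electric features) for one noisy sentence.

        The electric features are raw (unnormalized); normalization
        happens per training corpus in the recognizer back-end.
        """
        left, right = self.devices.process(mixture_4ch)
        acoustic = electric = None
        if self.side_mode in ("bimodal", "acoustic"):
            feats = logmel(left, self.acoustic_cfg)
            thresholds = threshold_spl(self.devices.audiogram,
                                       self.acoustic_cfg)
            acoustic = apply_audibility(feats, thresholds, seed)
        if self.side_mode in ("bimodal", "ci"):
            nf = n_frames(len(right), self.acoustic_cfg)
            # CI front-end AGC: map the working level onto the processor's
            # electric dynamic range regardless of beamformer gain
            rms = np.sqrt(np.mean(right ** 2))
            if rms > 0:
                right = right * (self.ci_agc_rms / rms)
            electric = electric_features(right, self.ace_cfg, self.pop,
                                         self.ir_cfg, seed + 1, nf)
        if acoustic is None:          # CI only: electric carries everything
            acoustic = np.zeros((electric.shape[0], 0))
        return acoustic, electric


# ---------------------------------------------------------------------------
# FADE-style grid simulation
# ---------------------------------------------------------------------------

def make_featurizer(corpus: Corpus, scenario: str, chain: FeatureChain,
                    seed: int = 0):
    """Build the ``featurizer(snr, mixture)`` callable for the SNR grid.

    Each (SNR, mixture) pair mixes every corpus sentence with a fresh
    noise instance of the scenario at that SNR, runs the device chain and
    returns per-sentence features plus word segmentation.
    """
    head = chain.devices.head
    noise_banks: dict[int, dict[str, list[np.ndarray]]] = {}
    frame_shift = chain.acoustic_cfg.frame_shift
    max_len = max(len(s.waveform) for s in corpus.sentences)
    bank_dur = max_len / corpus.fs + 0.5

    def get_bank(mixture: int) -> dict[str, list[np.ndarray]]:
        if mixture not in noise_banks:
            s = _subseed(seed, 7001, mixture)
            if scenario == "S0N20TB":
                bank = {"babble": make_babble(corpus, 4, 5, s,
                                              duration=bank_dur)}
            else:
                bank = {"ssn": [make_speech_shaped_noise(corpus, bank_dur, s)]}
            noise_banks[mixture] = bank
        return noise_banks[mixture]

    def featurizer(snr_db: float, mixture: int):
        bank = get_bank(mixture)
        out = []
        for si, sent in enumerate(corpus.sentences):
            scene = Scene.standard(scenario, snr_db)
            mix_seed = _subseed(seed, int(round(snr_db * 100)), mixture, si)
            mixture_4, _, _ = mix_scene(scene, sent.waveform, head,
                                        mix_seed, noise_bank=bank)
            feat_seed = int(np.random.default_rng(
                mix_seed + [11]).integers(2 ** 31))
            acoustic, electric = chain.featurize(mixture_4, feat_seed)
            segs = sentence_segments(sent.word_boundaries, sent.slot_words,
                                     acoustic.shape[0], frame_shift)
            out.append((acoustic, electric, segs, sent.slot_words))
        return out

    return featurizer


def fade_srt(corpus: Corpus, scenario: str, chain: FeatureChain,
             grid: SnrGrid, hmm_cfg: HmmConfig | None = None,
             seed: int = 0) -> tuple[float, RecognitionMatrix]:
    """Full ASR-based SRT prediction for one scenario x beamformer cell."""
    featurizer = make_featurizer(corpus, scenario, chain, seed)
    matrix = run_grid(featurizer, corpus.vocabulary, grid, hmm_cfg, seed,
                      meta={"scenario": scenario,
                            "beamformer": chain.devices.beamformer,
                            "side_mode": chain.side_mode, "seed": seed})
    return extract_srt(matrix), matrix


# ---------------------------------------------------------------------------
# BSIM-style prediction
# ---------------------------------------------------------------------------

def _threshold_noise(audiogram: Audiogram, n: int, fs: int,
                     dbfs_spl: float, seed: int) -> np.ndarray:
    """Internal noise whose band levels sit at the hearing threshold.

    Used to make sub-threshold acoustic signal components count as
    inaudible in the SII chain: white Gaussian noise spectrally shaped to
    the ISO 226 + audiogram threshold, per unit ERB bandwidth.
    """
    from .acoustic import ISO226_FREQS, ISO226_THRESH
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    f_safe = np.maximum(freqs, 20.0)
    thresh = np.interp(np.log10(f_safe), np.log10(ISO226_FREQS),
                       ISO226_THRESH) + audiogram.hl_at(f_safe)
    erb = 24.7 + 0.108 * f_safe      # ERB bandwidth at center frequency
    psd = 10 ** ((thresh - dbfs_spl) / 10.0) / erb      # power per Hz
    shape = np.sqrt(psd * fs / 2.0)
    return np.fft.irfft(np.fft.rfft(white) * shape, n)


@dataclass
class BsimPrediction:
    result: SrtResult
    profile: BandSnrProfile
    combined_snr: np.ndarray


def bsim_predict(corpus: Corpus, scenario: str, devices: DeviceChain,
                 cfg: BsimConfig | None = None,
                 ace_cfg: AceConfig | None = None,
                 pop: NervePopulation | None = None,
                 weighting: EaWeighting | None = None,
                 side_mode: str = "bimodal", base_snr_db: float = 0.0,
                 duration: float = 2.0, seed: int = 0,
                 ci_agc_rms: float = 0.05) -> BsimPrediction:
    """SII-based SRT prediction for one scenario x beamformer cell.

    The speech material is speech-shaped noise with the corpus long-term
    spectrum (a macroscopic model only regards the long-term spectrum).
    Speech and noise pass the device chain separately via phase
    inversion; the CI side is auralized; band SNRs (left / right / EC)
    feed the SII, and the broadband speech gain is bisected until the SII
    meets the side's reference.
    """
    cfg = cfg if cfg is not None else BsimConfig()
    ace_cfg = ace_cfg if ace_cfg is not None else AceConfig()
    pop = pop if pop is not None else NervePopulation()
    speech = make_speech_shaped_noise(corpus, duration, _subseed(seed, 1))
    scene = Scene.standard(scenario, base_snr_db)
    _, speech_4, noise_4 = mix_scene(scene, speech, devices.head,
                                     _subseed(seed, 2), corpus=corpus)
    s_hat, n_hat = hagerman_separate(devices.process, speech_4, noise_4)
    s_l, n_l = s_hat[0], n_hat[0]
    # CI front-end AGC: one common gain for the separated pair, set by the
    # level of the full mixture the processor actually receives
    mix_rms = np.sqrt(np.mean((s_hat[1] + n_hat[1]) ** 2))
    agc = ci_agc_rms / mix_rms if mix_rms > 0 else 1.0
    s_r, n_r = ci_auralize(agc * s_hat[1], agc * n_hat[1], ace_cfg, pop)
    thr = _threshold_noise(devices.audiogram, len(n_l), devices.head.fs,
                           devices.compressor.dbfs_spl, _subseed(seed, 3)[0])
    joint = bsim_mod.band_snrs(s_l, n_l + thr, s_r, n_r, cfg)

    if side_mode == "acoustic":
        combined = joint.snr_left
        dominant = "acoustic"
    elif side_mode == "ci":
        combined = joint.snr_right
        dominant = "ci"
    else:
        neg = np.full_like(joint.snr_left, -1e9)
        acoustic = BandSnrProfile(joint.center_freqs, joint.snr_left,
                                  neg, neg, np.array(["left"] * cfg.n_bands))
        electric = BandSnrProfile(joint.center_freqs, neg, joint.snr_right,
                                  neg, np.array(["right"] * cfg.n_bands))
        combined = np.maximum(bsim_mod.ea_weight(acoustic, electric,
                                                 weighting), joint.snr_ec)
        dominant = joint.dominant_side()

    result = find_srt(bsim_mod.shifted_profile(combined, dominant),
                      side_mode, cfg, base_snr_db)
    return BsimPrediction(result, joint, combined)


# ---------------------------------------------------------------------------
# instrumental SNR benefit
# ---------------------------------------------------------------------------

def isnr_improvements(corpus: Corpus, scenario: str, devices: DeviceChain,
                      base_snr_db: float = 0.0, duration: float = 2.0,
                      seed: int = 0) -> dict[str, float]:
    """Per-side instrumental SNR improvement of the device chain [dB]."""
    speech = make_speech_shaped_noise(corpus, duration, _subseed(seed, 1))
    scene = Scene.standard(scenario, base_snr_db)
    _, speech_4, noise_4 = mix_scene(scene, speech, devices.head,
                                     _subseed(seed, 2), corpus=corpus)
    out = {}
    for side in ("left", "right"):
        _, _, imp = instrumental_snr(speech_4, noise_4, devices.process,
                                     side, devices.head.fs)
        out[side] = imp
    return out
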