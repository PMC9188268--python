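"""Acoustic (hearing-aid side) feature pathway.

The acoustic ear is represented by a 31-channel log-Mel spectrogram,
calibrated in dB SPL, followed by an audibility stage that expresses each
time-frequency cell relative to the listener's hearing threshold and
replaces inaudible cells with unit-variance Gaussian noise.  The threshold
is the ISO 226 (2003) threshold-of-hearing curve plus the audiogram's
hearing level, interpolated to the Mel band centers — a purely
audibility-based hearing-loss simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .scene import FS

# ISO 226:2003 threshold of hearing, dB SPL (free-field, frontal incidence)
ISO226_FREQS = np.array([
    20, 25, 31.5, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500,
    630, 800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000,
    10000, 12500], float)
ISO226_THRESH = np.array([
    78.5, 68.7, 59.5, 51.1, 44.0, 37.5, 31.5, 26.5, 22.1, 17.9, 14.4,
    11.4, 8.6, 6.2, 4.4, 3.0, 2.2, 2.4, 3.5, 1.7, -1.3, -4.2, -6.0,
    -5.4, -1.5, 6.0, 12.6, 13.9, 12.3], float)


@dataclass
class Audiogram:
    """Pure-tone thresholds: frequency [Hz] -> hearing level [dB HL]."""

    freqs: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.thresholds = np.asarray(self.thresholds, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("audiogram frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("audiogram thresholds must be finite")

    @classmethod
    def flat(cls, hl_db: float) -> "Audiogram":
        freqs = np.array([125., 250., 500., 1000., 2000., 4000., 8000.])
        return cls(freqs, np.full(len(freqs), float(hl_db)))

    @classmethod
    def moderate_sloping(cls) -> "Audiogram":
        """Moderate-to-severe sloping loss typical of a bimodal HA ear."""
        return cls(np.array([125., 250., 500., 1000., 2000., 4000., 8000.]),
                   np.array([30., 35., 40., 50., 65., 75., 80.]))

    @classmethod
    def from_table(cls, path: str) -> "Audiogram":
        data = np.atleast_2d(np.genfromtxt(path))
        return cls(data[:, 0], data[:, 1])

    def hl_at(self, freqs: np.ndarray) -> np.ndarray:
        """Hearing level interpolated linearly on a log-frequency axis."""
        return np.interp(np.log10(np.asarray(freqs, float)),
                         np.log10(self.freqs), self.thresholds)


@dataclass
class AcousticFeatureConfig:
    sample_rate: int = FS
    frame_len_s: float = 0.025
    frame_shift_s: float = 0.010
    n_mel: int = 31
    f_min: float = 64.0
    f_max: float = 8000.0
    dbfs_spl: float = 100.0          # calibration: 0 dBFS sine == 100 dB SPL

    def __post_init__(self) -> None:
        if self.frame_len_s <= self.frame_shift_s:
            raise ValueError("frame length must exceed frame shift")
        if self.n_mel < 1:
            raise ValueError("need at least one Mel band")

    @property
    def frame_len(self) -> int:
        return int(round(self.frame_len_s * self.sample_rate))

    @property
    def frame_shift(self) -> int:
        return int(round(self.frame_shift_s * self.sample_rate))

    @property
    def n_fft(self) -> int:
        return 1 << int(np.ceil(np.log2(self.frame_len)))


def n_frames(n_samples: int, cfg: AcousticFeatureConfig) -> int:
    if n_samples < cfg.frame_len:
        raise ValueError("signal shorter than one analysis frame")
    return (n_samples - cfg.frame_len) // cfg.frame_shift + 1


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_band_centers(cfg: AcousticFeatureConfig) -> np.ndarray:
    mels = np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max),
                       cfg.n_mel + 2)
    return mel_to_hz(mels)[1:-1]


def mel_filterbank(cfg: AcousticFeatureConfig) -> np.ndarray:
    """Triangular Mel weighting matrix, (n_mel, n_fft//2 + 1)."""
    mels = np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max),
                       cfg.n_mel + 2)
    edges = mel_to_hz(mels)
    fft_freqs = np.fft.rfftfreq(cfg.n_fft, 1.0 / cfg.sample_rate)
    fb = np.zeros((cfg.n_mel, len(fft_freqs)))
    for b in range(cfg.n_mel):
        lo, ctr, hi = edges[b], edges[b + 1], edges[b + 2]
        rising = (fft_freqs - lo) / (ctr - lo)
        falling = (hi - fft_freqs) / (hi - ctr)
        fb[b] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def logmel(signal: np.ndarray, cfg: AcousticFeatureConfig | None = None,
           ) -> np.ndarray:
    """Log-Mel spectrogram in dB SPL, (frames, n_mel).

    Framing -> normalized Hamming window -> FFT power spectrum ->
    triangular Mel weighting -> 10*log10, offset so a full-scale sinusoid
    reads ``cfg.dbfs_spl`` dB SPL in its band.
    """
    cfg = cfg if cfg is not None else AcousticFeatureConfig()
    x = np.asarray(signal, float)
    nf = n_frames(len(x), cfg)
    idx = (np.arange(cfg.frame_len)[None, :]
           + cfg.frame_shift * np.arange(nf)[:, None])
    frames = x[idx]
    win = np.hamming(cfg.frame_len)
    win = win / (win.sum() / 2.0)    # full-scale sine -> unit peak magnitude
    spec = np.fft.rfft(frames * win, cfg.n_fft)
    power = np.abs(spec) ** 2
    melpow = power @ mel_filterbank(cfg).T
    return 10.0 * np.log10(melpow + 1e-30) + cfg.dbfs_spl


def threshold_spl(audiogram: Audiogram,
                  cfg: AcousticFeatureConfig | None = None) -> np.ndarray:
    """Per-Mel-band hearing threshold in dB SPL.

    ISO 226 threshold of hearing (log-frequency interpolation of the
    embedded table) plus the audiogram's hearing level at the band center.
    Band centers outside the tabulated support are clamped to the edge.
    """
    cfg = cfg if cfg is not None else AcousticFeatureConfig()
    centers = mel_band_centers(cfg)
    if centers[0] < ISO226_FREQS[0] or centers[-1] > ISO226_FREQS[-1]:
        warnings.warn("Mel band centers outside the ISO 226 table; "
                      "edge values used", stacklevel=2)
    iso = np.interp(np.log10(centers), np.log10(ISO226_FREQS), ISO226_THRESH)
    return iso + audiogram.hl_at(centers)


def apply_audibility(features: np.ndarray, thresholds: np.ndarray,
                     seed: int = 0, return_mask: bool = False):
    """Express features re threshold; fill inaudible cells with N(0, 1).

    Cells strictly below threshold carry no usable signal for the
    recognizer and are replaced by white Gaussian samples (mean 0, sd 1);
    cells exactly at threshold are kept.
    """
    features = np.asarray(features, float)
    thresholds = np.asarray(thresholds, float)
    if features.shape[1] != len(thresholds):
        raise ValueError("feature band count does not match thresholds")
    rel = features - thresholds[None, :]
    mask = rel < 0.0
    rng = np.random.default_rng(seed)
    out = np.where(mask, rng.standard_normal(rel.shape), rel)
    if return_mask:
        return out, mask
    return out
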