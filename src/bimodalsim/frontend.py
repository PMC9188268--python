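"""Hearing-device front-end: beamformers, compression, signal separation.

Three noise-reduction conditions are supported, mirroring common clinical
fittings:

* ``NoBF`` — the front microphone of each side, unprocessed;
* ``ADM``  — a two-microphone adaptive differential microphone per side,
  y(t) = cF(t) - beta * cB(t), with the blocking coefficient beta adapted
  by normalized gradient descent on the output energy;
* ``MVDR`` — a four-microphone binaural minimum-variance
  distortionless-response beamformer designed for a frontal target in a
  spherically isotropic diffuse noise field.

The module also implements a multiband dynamic-range compressor with a
CAMFIT-style gain prescription (linear gain proportional to hearing loss,
capped at 90 dB HL, no amplification above 5 kHz) and the Hagerman-
Olofsson phase-inversion method that recovers separately processed speech
and noise from any deterministic, possibly nonlinear, processing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as sps

from .scene import FS, SPEED_OF_SOUND, HeadModel

BEAMFORMERS = ("NoBF", "ADM", "MVDR")


# ---------------------------------------------------------------------------
# adaptive differential microphone
# ---------------------------------------------------------------------------

@dataclass
class AdmState:
    """Blocking-beam coefficient and adaptation constants of the ADM."""

    beta: float = 0.5
    step_size: float = 0.1           # normalized LMS step per block
    beta_bounds: tuple[float, float] = (0.0, 1.0)
    block_len: int = 128             # 8 ms at 16 kHz
    mic_spacing: float = 0.01        # [m]
    fs: int = FS
    adapt: bool = True


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """All-pass fractional delay via the FFT phase ramp (offline, linear)."""
    n = len(x)
    spec = np.fft.rfft(x)
    k = np.arange(len(spec))
    return np.fft.irfft(spec * np.exp(-2j * np.pi * k * delay_samples / n), n)


def adm_beams(front: np.ndarray, rear: np.ndarray,
              state: AdmState) -> tuple[np.ndarray, np.ndarray]:
    """Fixed delay-and-subtract cardioids cF (front) and cB (back)."""
    if len(front) != len(rear):
        raise ValueError("front and rear microphone signals differ in length")
    d = state.mic_spacing / SPEED_OF_SOUND * state.fs
    c_front = front - _fractional_delay(rear, d)
    c_back = rear - _fractional_delay(front, d)
    return c_front, c_back


def adm_combine(c_front: np.ndarray, c_back: np.ndarray,
                state: AdmState) -> np.ndarray:
    """y = cF - beta*cB, beta adapted blockwise to minimize output energy."""
    if len(c_front) != len(c_back):
        raise ValueError("beam signals differ in length")
    beta = float(state.beta)
    lo, hi = state.beta_bounds
    out = np.empty_like(c_front)
    blk = state.block_len
    for start in range(0, len(c_front), blk):
        cf = c_front[start:start + blk]
        cb = c_back[start:start + blk]
        y = cf - beta * cb
        out[start:start + blk] = y
        if state.adapt:
            # normalized stochastic gradient on E[y^2]; dE/dbeta = -2 y.cB
            denom = float(np.dot(cb, cb)) + 1e-12
            beta += state.step_size * float(np.dot(y, cb)) / denom
            beta = min(max(beta, lo), hi)
    state.beta = beta
    return out


def adm_process(front_mic: np.ndarray, rear_mic: np.ndarray,
                state: AdmState | None = None) -> np.ndarray:
    """Full ADM: form the fixed beams, then adaptively combine them."""
    state = state if state is not None else AdmState()
    c_front, c_back = adm_beams(np.asarray(front_mic, float),
                                np.asarray(rear_mic, float), state)
    return adm_combine(c_front, c_back, state)


# ---------------------------------------------------------------------------
# MVDR beamformer
# ---------------------------------------------------------------------------

@dataclass
class MvdrFilter:
    """Per-bin MVDR weights; ``w[out, bin, mic]`` with y = w^H x per bin."""

    w: np.ndarray
    d: np.ndarray                    # steering vector, (bin, mic)
    sigma: np.ndarray                # coherence matrix, (bin, mic, mic)
    n_fft: int
    fs: int
    ref_channels: tuple[int, ...] = (0, 2)

    def constraint_error(self) -> float:
        """max over outputs and bins of |w^H d - d_ref|.

        The distortionless constraint: each output passes the frontal
        target exactly as its reference microphone receives it.
        """
        errs = []
        for o, ref in enumerate(self.ref_channels):
            resp = np.einsum("bm,bm->b", np.conj(self.w[o]), self.d)
            errs.append(np.max(np.abs(resp - self.d[:, ref])))
        return float(np.max(errs))


def mic_geometry(head: HeadModel) -> np.ndarray:
    """(4, 2) microphone xy positions [m]: LF, LR, RF, RR."""
    half = head.itd_max * SPEED_OF_SOUND / 2
    s = head.mic_spacing
    return np.array([[-half, 0.0], [-half, -s], [half, 0.0], [half, -s]])


def diffuse_coherence(freqs: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Spherically isotropic coherence sinc(2 f d_ij / c) per frequency."""
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    return np.sinc(2.0 * freqs[:, None, None] * dist[None] / SPEED_OF_SOUND)


def mvdr_design(head: HeadModel, n_fft: int = 2048,
                diffuse_model: str = "sinc",
                ref_channels: tuple[int, ...] = (0, 2),
                diagonal_loading: float = 1e-3) -> MvdrFilter:
    """Design the binaural MVDR filter for a frontal target.

    One output per reference channel, each satisfying the distortionless
    constraint ``w^H d = d_ref`` so the target reaches that output exactly
    as it reaches the reference microphone.  ``diagonal_loading`` is the
    regularization fraction of mean eigenvalue added to the coherence
    matrix (`sinc` diffuse model or identity for ``"white"``).
    """
    freqs = np.fft.rfftfreq(n_fft, 1.0 / head.fs)
    d = head.transfer(0.0, freqs).T            # (bin, mic)
    pos = mic_geometry(head)
    if diffuse_model == "sinc":
        sigma = diffuse_coherence(freqs, pos)
    elif diffuse_model == "white":
        sigma = np.broadcast_to(np.eye(4), (len(freqs), 4, 4)).copy()
    else:
        raise ValueError(f"unknown diffuse model {diffuse_model!r}")
    n_mics = sigma.shape[-1]
    load = diagonal_loading * np.trace(sigma, axis1=1, axis2=2).real / n_mics
    sigma_l = sigma + load[:, None, None] * np.eye(n_mics)
    try:
        sinv_d = np.linalg.solve(sigma_l, d[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "coherence matrix singular; increase diagonal_loading") from exc
    denom = np.einsum("bm,bm->b", np.conj(d), sinv_d)
    w_unit = sinv_d / denom[:, None]           # w^H d = 1 per bin
    outs = [w_unit * np.conj(d[:, ref])[:, None] for ref in ref_channels]
    return MvdrFilter(np.stack(outs), d, sigma_l, n_fft, head.fs,
                      tuple(ref_channels))


def mvdr_weights(sigma: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Closed-form single-bin MVDR weights w = Sigma^-1 d / (d^H Sigma^-1 d)."""
    sinv_d = np.linalg.solve(sigma, d)
    return sinv_d / (np.conj(d) @ sinv_d)


def mvdr_process(x: np.ndarray, filt: MvdrFilter) -> np.ndarray:
    """Filter a 4-channel input into the binaural beamformer output.

    Implemented as overlap-add FIR filtering of the per-bin weights; the
    n_fft/2-sample design latency is compensated so the output is aligned
    with the input.
    """
    x = np.atleast_2d(np.asarray(x, float))
    n_out_ch, _, n_mics = filt.w.shape
    if x.shape[0] != n_mics:
        raise ValueError(f"expected {n_mics} input channels, got {x.shape[0]}")
    n = x.shape[1]
    shift = filt.n_fft // 2
    freqs = np.fft.rfftfreq(filt.n_fft, 1.0 / filt.fs)
    phase = np.exp(-2j * np.pi * freqs * shift / filt.fs)
    y = np.zeros((n_out_ch, n + filt.n_fft - 1))
    for o in range(n_out_ch):
        for m in range(n_mics):
            h = np.fft.irfft(np.conj(filt.w[o, :, m]) * phase, filt.n_fft)
            y[o] += sps.fftconvolve(x[m], h)
    return y[:, shift:shift + n]


# ---------------------------------------------------------------------------
# multiband compression (hearing aid)
# ---------------------------------------------------------------------------

@dataclass
class CompressorConfig:
    """Multiband compressor with a CAMFIT-style prescriptive gain rule."""

    n_bands: int = 9
    f_lo: float = 100.0
    f_hi: float = 8000.0
    attack_ms: float = 20.0
    release_ms: float = 100.0
    ratio: float = 2.0
    knee_spl: float = 50.0
    gain_fraction: float = 0.45      # linear gain = fraction * HL
    camfit_hl_cap: float = 90.0      # HL above this prescribes no extra gain
    camfit_upper_freq: float = 5000.0
    dbfs_spl: float = 100.0          # 0 dBFS sine == this many dB SPL
    gain_table: np.ndarray | None = None   # static per-band gains, overrides
    n_fft: int = 512
    hop: int = 128
    fs: int = FS

    def crossover_freqs(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_bands + 1)

    def band_centers(self) -> np.ndarray:
        edges = self.crossover_freqs()
        return np.sqrt(edges[:-1] * edges[1:])


def camfit_gains(audiogram, cfg: CompressorConfig) -> np.ndarray:
    """Prescribed linear insertion gain per band [dB].

    Gain is proportional to the interpolated hearing loss, with losses
    capped at ``camfit_hl_cap`` (90 dB HL) and no gain above
    ``camfit_upper_freq`` (5 kHz) — the modification that focuses
    amplification on the residual low-frequency hearing of CI candidates.
    """
    centers = cfg.band_centers()
    hl = np.interp(np.log10(centers), np.log10(audiogram.freqs),
                   audiogram.thresholds)
    hl = np.minimum(hl, cfg.camfit_hl_cap)
    gains = cfg.gain_fraction * hl
    gains[centers > cfg.camfit_upper_freq] = 0.0
    return gains


def compress_ha(signal: np.ndarray, audiogram=None,
                cfg: CompressorConfig | None = None) -> np.ndarray:
    """Multiband dynamic-range compression of a mono hearing-aid signal.

    STFT analysis (perfect-reconstruction Hann frames), per-band level
    estimation with attack/release smoothing, gain from the prescription
    (linear below the knee, ``ratio``:1 compressive above), resynthesis.
    """
    cfg = cfg if cfg is not None else CompressorConfig()
    x = np.asarray(signal, float)
    if cfg.gain_table is not None:
        lin_gain = np.asarray(cfg.gain_table, float)
        if len(lin_gain) != cfg.n_bands:
            raise ValueError("gain_table length must equal n_bands")
    elif audiogram is not None:
        lin_gain = camfit_gains(audiogram, cfg)
    else:
        lin_gain = np.zeros(cfg.n_bands)

    nfft, hop = cfg.n_fft, cfg.hop
    win = sps.get_window("hann", nfft)
    stft = sps.ShortTimeFFT(win, hop=hop, fs=cfg.fs, fft_mode="onesided")
    spec = stft.stft(x)                         # (bins, frames)
    fbins = stft.f
    edges = cfg.crossover_freqs()
    band_of_bin = np.clip(np.searchsorted(edges, fbins, side="right") - 1,
                          0, cfg.n_bands - 1)

    # per-band frame levels in dB SPL (0 dBFS sine reference)
    win_gain = win.sum() / 2.0
    power = np.abs(spec) ** 2 / win_gain ** 2
    band_power = np.zeros((cfg.n_bands, spec.shape[1]))
    for b in range(cfg.n_bands):
        band_power[b] = power[band_of_bin == b].sum(axis=0)
    level = 10 * np.log10(band_power + 1e-30) + cfg.dbfs_spl

    a_att = np.exp(-hop / cfg.fs / (cfg.attack_ms / 1000.0))
    a_rel = np.exp(-hop / cfg.fs / (cfg.release_ms / 1000.0))
    smoothed = np.empty_like(level)
    state = level[:, 0]
    for t in range(level.shape[1]):
        coef = np.where(level[:, t] > state, a_att, a_rel)
        state = coef * state + (1 - coef) * level[:, t]
        smoothed[:, t] = state

    over = np.maximum(smoothed - cfg.knee_spl, 0.0)
    gain_db = lin_gain[:, None] - (1.0 - 1.0 / cfg.ratio) * over
    # an insertion-gain compressor never attenuates below unity and never
    # exceeds the prescribed linear gain
    gain_db = np.clip(gain_db, 0.0, lin_gain[:, None])
    spec *= 10 ** (gain_db[band_of_bin] / 20.0)
    y = stft.istft(spec)
    return y[:len(x)]


def headphone_filter(signal: np.ndarray,
                     fir: np.ndarray | None = None) -> np.ndarray:
    """Insert-earphone transfer emulation; identity unless an FIR is given."""
    if fir is None:
        return np.asarray(signal, float)
    return sps.fftconvolve(signal, fir)[:len(signal)]


# ---------------------------------------------------------------------------
# Hagerman-Olofsson phase-inversion separation
# ---------------------------------------------------------------------------

def hagerman_separate(process: Callable[[np.ndarray], np.ndarray],
                      speech: np.ndarray, noise: np.ndarray,
                      check_deterministic: bool = True,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Recover separately processed speech and noise from a mixed chain.

    The chain is run on speech+noise and on speech-noise; half their sum
    and half their difference are the processed speech and noise.  Exact
    for linear chains; for nonlinear chains the re-addition identity
    ``speech_hat + noise_hat == process(speech + noise)`` still holds
    sample-exactly while each part carries a bounded nonlinear error.

    ``process`` must be deterministic (any adaptation state reset per
    call); a short duplicate-call probe enforces this.
    """
    speech = np.asarray(speech, float)
    noise = np.asarray(noise, float)
    if speech.shape != noise.shape:
        raise ValueError("speech and noise must have identical shapes")
    if check_deterministic:
        probe = speech[..., :2048] + noise[..., :2048]
        a, b = process(probe), process(probe)
        if not np.array_equal(a, b):
            raise ValueError("process is not deterministic between calls; "
                             "reset its internal state or randomness")
    plus = process(speech + noise)
    minus = process(speech - noise)
    return (plus + minus) / 2.0, (plus - minus) / 2.0
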