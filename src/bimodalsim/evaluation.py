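"""Benefit metrics and model-vs-reference agreement statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .frontend import hagerman_separate
from .scene import speech_activity_gate

_FRONT = {"left": 0, "right": 1}     # channel index in the 2-ch device output
_FRONT_MIC = {"left": 0, "right": 2}  # front microphone in the 4-ch input


@dataclass
class BenefitRecord:
    scenario: str
    comparison: str                  # e.g. "ADM vs NoBF"
    side_or_model: str
    value_db: float


def _gated_snr(speech: np.ndarray, noise: np.ndarray, gate: np.ndarray,
               ) -> float:
    n = min(len(speech), len(gate))
    g = gate[:n]
    return 10 * np.log10(np.mean(speech[:n][g] ** 2)
                         / np.mean(noise[:n][g] ** 2))


def instrumental_snr(speech_4ch: np.ndarray, noise_4ch: np.ndarray,
                     process, side: str, fs: int = 16000,
                     ) -> tuple[float, float, float]:
    """Instrumental SNR benefit of a processing chain on one side.

    The input SNR is measured at the side's front microphone; the output
    SNR on the corresponding output channel of the chain, with speech and
    noise disentangled by the phase-inversion method.  SNRs are broadband,
    over speech-active samples.  Returns (input, output, improvement) dB.
    """
    gate = speech_activity_gate(speech_4ch, fs)
    mic = _FRONT_MIC[side]
    snr_in = _gated_snr(speech_4ch[mic], noise_4ch[mic], gate)
    s_hat, n_hat = hagerman_separate(process, speech_4ch, noise_4ch)
    ch = _FRONT[side]
    snr_out = _gated_snr(s_hat[ch], n_hat[ch], gate)
    return snr_in, snr_out, snr_out - snr_in


def srt_benefit(srt_nobf: float, srt_alg: float) -> float:
    """SRT benefit of an algorithm re the unprocessed condition [dB].

    Positive values mean the algorithm lowered (improved) the SRT.
    """
    return float(srt_nobf) - float(srt_alg)


def agreement(predicted, reference) -> tuple[float, float, float]:
    """Pearson r (with two-sided p) and RMSE between two SRT vectors."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    if predicted.shape != reference.shape:
        raise ValueError("vectors must have equal length")
    if len(predicted) < 3:
        raise ValueError("need at least 3 points for a correlation")
    r, p = stats.pearsonr(predicted, reference)
    rmse = float(np.sqrt(np.mean((predicted - reference) ** 2)))
    return float(r), float(p), rmse
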