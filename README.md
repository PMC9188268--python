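# bimodalsim

Modelling speech-in-noise performance of **bimodal cochlear-implant
listeners** — a CI on one ear, a hearing aid (HA) on the other — and the
benefit they get from spatial noise-reduction algorithms (beamformers).

The package is for computational audiologists and algorithm developers
who want to compare noise-reduction front-ends on a simulated listener
instead of (or before) patient testing. It implements two established
model families end to end, plus a simple instrumental reference:

* **ASR-based chain** — an automatic speech recognizer replaces the
  listener: spatial scene → beamformer (none / adaptive differential
  microphone / binaural MVDR) → HA compression and CI (ACE) simulation →
  acoustic log-Mel features with audiogram-driven audibility gating, and
  electric features from a stochastic integrate-and-fire auditory-nerve
  population → whole-word HMMs trained and tested over an SNR grid.
  The speech reception threshold (SRT) is the lowest testing SNR with
  50 % words correct:
  `SRT = min over training SNRs of the interpolated 50 % crossing`.
* **SII-based chain** — speech and noise are disentangled through the
  nonlinear device chain by the Hagerman–Olofsson phase-inversion trick
  (process `s+n` and `s−n`; half-sum and half-difference recover the
  parts), the CI side is auralized as a tone-carrier vocoder with
  exponential current spread, and per gammatone band the model listens
  with the left ear, the right ear, or an equalization–cancellation (EC)
  combination — whichever gives the best band SNR. Band SNRs enter the
  speech intelligibility index, SII = Σᵢ wᵢ · clip((SNRᵢ + 15)/30, 0, 1),
  and a broadband speech gain is bisected until the SII meets a
  side-specific reference (0.26 acoustic, 0.42 CI).
* **Instrumental SNR benefit** — output minus input broadband SNR per
  side, via the same phase-inversion separation.

Everything runs on synthetic material generated by the package itself: a
balanced 5-slot × 10-alternative matrix-sentence corpus of deterministic
word tokens, speech-shaped stationary noise, 20-talker babble, and a
parametric 4-microphone head model (Woodworth ITD + head shadow) that
stands in for measured HRIRs. See `docs/methods.md` for the models,
parameters and limitations.

## Worked example

Instrumental benefit of the beamformers with noise at −90° (desk-scale
profile, seconds on one core):

```
$ bimodalsim evaluate -s S0N-90 -b NoBF -b ADM -b MVDR --seed 1
  S0N-90  NoBF iSNR left +0.0 dB, right +0.0 dB
  S0N-90   ADM iSNR left +26.5 dB, right +25.6 dB
  S0N-90  MVDR iSNR left +17.1 dB, right +5.0 dB
```

No beamformer leaves the SNR unchanged; both algorithms suppress the
lateral noise source strongly (the parametric head is anechoic, so
point-source cancellation is far deeper than in a real room — compare
orderings, not absolute dB). The ASR chain turns this into predicted
SRTs (about a minute):

```
$ bimodalsim fade -s S0N-90 -b NoBF -b MVDR --seed 1
  S0N-90  NoBF SRT = -8.5 dB
  S0N-90  MVDR SRT = -24.0 dB
```

The binaural beamformer lowers (improves) the predicted threshold by
15.5 dB in this synthetic scene; `bimodalsim bsim` gives the SII-chain
prediction of the same cells, and `--profile full` switches to the
full-scale corpus, grids and nerve population. From Python:

```python
from bimodalsim.config import ExperimentConfig, run_experiment

cfg = ExperimentConfig(profile="desk", model="fade",
                       scenarios=["S0N-90"], beamformers=["NoBF", "MVDR"],
                       seed=1)
results = run_experiment(cfg, out_dir="runs/demo")   # replayable artifacts
```

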