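# Methods

`bimodalsim` predicts speech reception thresholds (SRTs) — the SNR at
which a listener scores 50 % words correct on a closed-set matrix
sentence test — for *bimodal* listeners: a cochlear implant (CI) on the
right ear and a hearing aid (HA) on the left. Two model chains share the
same spatial scenes and device front-end but differ in their back-end:

1. **ASR chain** (`fade`): scene → beamformer → HA/CI device simulation
   → acoustic (log-Mel) and electric (auditory-nerve) features → HMM
   recognizer trained and tested over an SNR grid → SRT.
2. **SII chain** (`bsim`): scene → phase-inversion separation of speech
   and noise through the (nonlinear) device chain → CI auralization →
   gammatone band SNRs for left ear, right ear and a binaural
   equalization–cancellation (EC) path → speech intelligibility index
   (SII) → bisection on a broadband speech gain to the side-specific
   reference SII → SRT.

A third reference metric, the instrumental SNR benefit (output SNR minus
input SNR per side), is implemented in `evaluation`.

## Synthetic scenes

Real matrix-test recordings and measured cafeteria impulse responses are
licensed/unpublished, so the `scene` module generates stand-ins:

* **Corpus.** 120 five-slot sentences (name–verb–number–adjective–object,
  10 alternatives per slot), balanced so every word occurs exactly
  `n_sentences / alternatives` times. Each vocabulary word is a
  *deterministic* token: a harmonic complex (word-specific f0) with two
  formant-like resonances and an amplitude-modulated envelope, 300–500 ms
  at full scale. Determinism makes the recognition task well-posed
  for small corpora; it removes natural token-to-token variability, so
  absolute SRTs are not comparable to human data — only orderings and
  benefits are meaningful.
* **Stationary noise** is made by phase-randomizing the spectrum of the
  concatenated corpus, so its long-term spectrum equals the speech
  spectrum exactly (the construction behind matrix-test noises).
* **Babble** sums four independent talkers per stream, five streams; each
  talker is a fresh sentence permutation with a ±3 % rate/pitch jitter
  (a crude voice difference). Streams correlate below 0.06 (full corpus).
* **Head model.** Parametric 4-microphone head: Woodworth-type ITD
  (`itd_max` 700 µs), 1 cm front/rear microphone spacing per side,
  far-ear shadow of 8 dB·|sin az| plus a first-order low-pass whose
  strength scales with laterality. Mirror-symmetric by construction;
  measured 4-channel HRIRs can replace it. There is no room acoustic by
  default (an exponential-decay tail is available but off), so spatial
  algorithms perform *better* than they would in a real cafeteria —
  point-source noises are perfectly coherent across microphones. Desk
  runs show ADM/MVDR instrumental benefits of 5–25 dB, far above the
  4–11 dB of measured rooms; again only orderings transfer.
* **SNR convention.** Broadband RMS ratio over speech-active samples
  (envelope above −40 dB re max), averaged over the two *front*
  microphones; mixtures are calibrated to the nominal SNR within 0.1 dB
  by construction. The reference point of the SNR is a documented choice;
  all comparisons use the same convention.

## Device front-end

* **ADM** — per side, fixed delay-and-subtract front/back cardioids from
  the front/rear microphone pair (delay = acoustic travel time over
  1 cm); output `y = cF − β·cB` with β adapted per 8 ms block by
  normalized gradient descent (step 0.1) on output energy, clamped to
  [0, 1] to keep the null in the rear half-plane. Converged β lands
  within 0.002 of a 0.001-step grid search in the test scenes.
* **MVDR** — binaural, four microphones, designed per FFT bin
  (`n_fft` 2048) as `w = Σ⁻¹d / (dᴴΣ⁻¹d)` with the frontal steering
  vector `d` taken from the head model and `Σ` the spherically isotropic
  coherence `sinc(2 f d_ij / c)`, diagonally loaded by 1e−3 of the mean
  eigenvalue. Two outputs preserve the respective reference (front)
  microphone's target response exactly (`wᴴd = d_ref`, error < 1e−6);
  processing is overlap-add FIR with the n_fft/2 design latency removed.
* **HA compression** — STFT-based (512-point Hann, 128 hop,
  perfect reconstruction), 9 log-spaced bands 100–8000 Hz, per-band
  level estimation with 20 ms attack / 100 ms release, gains from a
  CAMFIT-style rule: linear gain = 0.45 × HL capped at 90 dB HL, no gain
  above 5 kHz, 2:1 compression above a 50 dB SPL knee, total gain
  clamped to [0, prescription]. With a 0 dB HL audiogram the stage is an
  identity to < −300 dB.
* **Phase inversion (Hagerman–Olofsson)** — processes `s+n` and `s−n`
  and recombines; exact for linear chains (measured < −280 dB error),
  and for nonlinear chains the re-addition identity
  `ŝ + n̂ = P(s+n)` holds to numerical precision. A duplicate-call probe
  rejects non-deterministic chains.

## Acoustic features and hearing loss

31-band triangular Mel filterbank (HTK mel formula, 64–8000 Hz) on 25 ms
Hamming frames with 10 ms shift; 10·log10 power, calibrated so a
full-scale sinusoid reads 100 dB SPL (configurable). Hearing loss is
audibility-only: the ISO 226 (2003) threshold-of-hearing table
(embedded, log-frequency interpolated to band centers) plus the
audiogram HL gives a per-band threshold; features are expressed relative
to it and strictly sub-threshold cells are replaced by unit-variance
Gaussian draws. The default audiogram is a moderate-to-severe sloping
loss (30→80 dB HL, 125 Hz→8 kHz) typical of a bimodal HA ear.

## Electric pathway

* **ACE**: 128-sample Hann frames (8 ms) advanced at the 900 pps channel
  rate (6.89 ms overlap, sample-rounded with drift compensation); FFT
  bins 188–7938 Hz grouped into 22 quasi-logarithmic channels (geometric
  group sizes, smallest = 1 bin); envelope = magnitude of the complex
  bin sum; the 8 largest envelopes per cycle (ties → lower channel)
  stimulate their electrodes base-to-apex at slots of 1/7200 s; currents
  map log-compressively (steepness 416.2) from [base 4/256, saturation
  150/256] onto [THL 100, MCL 200] clinical units. Envelopes below base
  emit no pulse. A pipeline-level AGC normalizes the processor input to
  a working RMS (0.05 re full scale) — the sensitivity stage a clinical
  processor applies before envelope extraction; without it beamformed
  (quiet) inputs would fall below the base level entirely.
* **Current spread**: cell stimulus = pulse amplitude ×
  exp(−|cell − electrode| / λ), λ = 1 mm (36.8 % at 1 mm); electrodes at
  8.125–23.875 mm from the apex (0.75 mm pitch), 2200 cells equidistant
  over a 35 mm cochlea (desk: 300 cells).
* **Integrate-and-fire population**: between pulses the membrane decays
  with τ = 0.5 ms; each pulse adds its spread current; a spike fires
  when the potential plus Gaussian membrane noise (sd 5 % of threshold)
  exceeds the threshold, elevated by a relative-refractory factor
  exp(−(t−t_abs)/1 ms) after the 0.5 ms absolute period; spike time =
  crossing + 0.5 ms latency + 50 µs Gaussian jitter. All parameters are
  config; detailed published parameter sets for electrically driven
  fibres vary, so these are physiologically-typical defaults.
* **Internal representation**: spikes binned to the nearest of
  `n_groups` equidistant centers over the electrode span (default 46 so
  the concatenated feature dimension is 31 + 46 = 77; 22 — one group per
  electrode — is available via config), counted on a 1 ms grid, smoothed
  by a Gaussian FIR (sd 2 ms) then a 10 ms recursive integrator, sampled
  at the acoustic frame centers, multiplied by Gaussian noise of mean 1
  and variance 0.1 (central degradation), and finally normalized to
  per-feature zero mean / unit variance over each *training* set (test
  features reuse the training statistics).

## Recognizer

Whole-word left-to-right HMMs with single diagonal-Gaussian emissions
(variance floor 1e−3): 8 states per word, 3 for the start and end
models, 6 for silence (desk: 2/2/2). Training is Baum-Welch
(`hmmlearn`) from a flat start (uniform-segmentation means, global
variance), tolerance 1e−4, max 20 iterations; the left-to-right zero
pattern is preserved by EM. Because Baum-Welch does not model sequence
termination, word-exit probabilities are fixed at 0.5 in the composite
grammar rather than trained. Decoding is exact Viterbi over the composed
grammar — start model, five slots of 10 parallel word models with
optional per-junction silence copies, end model — i.e. the a-priori
sentence structure of the matrix test. Score = correct words / (5 ×
sentences) × 100.

For each training SNR, 8 noise mixtures of the corpus (960 sentences at
study scale) train a model set, which is tested on a held-out mixture at
every testing SNR, giving the train × test recognition matrix. The SRT
is the lowest testing SNR whose linearly-interpolated first upward 50 %
crossing is minimal over training rows; the "lowest testing SNR" wording
is taken literally (minimum over rows, not the matrix diagonal). A
matrix with no crossing raises an error asking for a wider grid, echoing
the range-adjustment procedure of grid-based simulations. Default grids per
beamformer × scenario span the ranges where the thresholds are
expected for each condition (3 dB steps).

## SII chain

The speech input is speech-shaped noise (a macroscopic model only
regards the long-term spectrum). After phase-inversion separation, the
right-side pair is auralized: ACE envelopes → 22×22 exponential spread
matrix → envelopes (as modulation depths re the electric dynamic range)
re-modulate deterministic tone carriers at the channel center
frequencies. Tone carriers make the auralization reproducible and, like
any vocoder, destroy interaural fine structure. The left side keeps its
acoustic signal; hearing loss enters as an additive internal noise whose
band levels sit at the ISO 226 + audiogram threshold (per-ERB shaping).

Per gammatone band (30 bands, ERB-spaced 146–7840 Hz, 4th-order IIR) and
1024-sample window: left and right SNRs from band powers, and an EC SNR
obtained by equalizing the interaural delay (cross-correlation search
over ±10 ms on the sample grid) and level (analytic optimal gain,
clamped to ±40 dB) of the *noise* and cancelling; both orientations and
the pass-through candidates are searched, so ideal EC is never worse
than the better ear. Processing inaccuracies add a deterministic
residual-noise floor of `σ_amp_lin² + (2πf σ_t)²` (σ_amp 1.5 dB,
σ_t 105 µs) — at high frequencies this exceeds unity and EC degenerates
to better-ear listening, which is also why a vocoded CI side never makes
the EC path win there. Window SNRs are capped at ±40 dB and averaged in
dB across windows (dip-listening weighting).

Band SNRs combine across sides by a configurable electro-acoustic
weighting: the default is the plain band-wise maximum ("best SNR per
band"); a crossover variant (acoustic weighted below 1 kHz, electric
above, one-octave crossfade expressed as dB offsets) is available. SII =
importance-weighted mean of `clip((SNR+15)/30, 0, 1)` with uniform
importance by default. The SRT search shifts the speech term of all band
SNRs by a broadband gain (the separation and auralization are computed
once at the base SNR — a linear-shift approximation documented here) and
bisects until the SII meets the reference: 0.26 (acoustic side), 0.42
(CI side); for bimodal listening the reference of the side dominating
the band selection is used and flagged in the result. Bisection
converges in both SII (tol 0.001) and gain (interval < 0.02 dB), within
0.005 dB of a fine-grid search.

## Problem sizes

The `desk` profile — used by the test suite and the acceptance script —
caps the corpus at 4 alternatives × 8 sentences (150 ms tokens), 300
nerve cells, 10 spatial groups, 2-state word models, 2 training mixtures
and a −30…+12 dB test grid with training at {−24, −12, 0} dB: a complete
two-beamformer ASR comparison runs in about a minute on one core. The
`full` profile restores the study-scale settings (120 × 10 corpus, 2200
cells, 46 groups, 8-state words, 8 mixtures, wide SNR ranges).

## Known limitations

* Absolute SRTs depend on the synthetic tokens and the anechoic
  parametric head; only qualitative orderings (beamformer benefit,
  scenario effects) are expected to transfer to real material.
* The SII chain's gain search uses the linear-shift approximation above;
  the compressor's SNR-dependent nonlinearity is captured at the base
  SNR only.
* The ER-4 insert-earphone transfer is an identity by default (a
  configurable FIR), and the exact THL/MCL map of the clinical reference
  is not published; defaults are stated above and exposed in config.
* `spread_current` materializes a pulses × cells matrix; at the full
  2200-cell scale long signals should be processed sentence-wise.
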