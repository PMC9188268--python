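"""Cochlear-implant (electric) pathway.

Chain: ACE n-of-m coding strategy (22 analysis channels, 8 maxima per
cycle, 900 pulses per second per channel) -> exponential spatial spread of
the electrode currents along the cochlea -> stochastic leaky
integrate-and-fire auditory-nerve population (2200 cells over 35 mm) ->
spatially and temporally integrated "internal representation" used as the
electric feature matrix of the speech recognizer.

The ACE analysis frame is 128 samples of 16 kHz audio (8 ms) advanced at
the channel rate, i.e. 1/900 s (~6.89 ms overlap); with all 8 maxima
active the total stimulation rate is 8 x 900 = 7200 pps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .scene import FS


# ---------------------------------------------------------------------------
# ACE coding strategy
# ---------------------------------------------------------------------------

@dataclass
class AceConfig:
    M: int = 22                      # analysis channels
    N: int = 8                       # maxima per cycle
    channel_rate: float = 900.0      # pulses per second per channel
    frame_len: int = 128             # samples per analysis frame
    fs: int = FS
    f_lo: float = 188.0              # analysis band edges [Hz]
    f_hi: float = 7938.0
    thl: float = 100.0               # threshold current level (clinical units)
    mcl: float = 200.0               # most comfortable current level
    base_level: float = 4.0 / 256.0  # envelope below this emits no pulse
    sat_level: float = 150.0 / 256.0
    rho: float = 416.2               # steepness of the loudness growth map

    def __post_init__(self) -> None:
        if self.N > self.M:
            raise ValueError("cannot select more maxima than channels (N <= M)")

    @property
    def cycle_period(self) -> float:
        return 1.0 / self.channel_rate

    def cycle_starts(self, n_samples: int) -> np.ndarray:
        """Frame start samples at the channel rate, drift-compensated."""
        n_cycles = int(np.floor(
            (n_samples - self.frame_len) / (self.fs * self.cycle_period))) + 1
        k = np.arange(max(n_cycles, 0))
        return np.round(k * self.fs * self.cycle_period).astype(int)


def ace_bin_groups(cfg: AceConfig) -> list[np.ndarray]:
    """Quasi-logarithmic FFT-bin-to-channel map over f_lo..f_hi.

    Low channels take single FFT bins, high channels progressively more,
    approximating the log spacing of the electrode filterbank.  Group
    sizes are found by fitting a geometric progression to the available
    bins.
    """
    bin_width = cfg.fs / cfg.frame_len
    first = int(np.ceil(cfg.f_lo / bin_width))
    last = int(np.floor(cfg.f_hi / bin_width))
    n_bins = last - first + 1
    if n_bins < cfg.M:
        raise ValueError("not enough FFT bins for the requested channels")
    # geometric group sizes starting at one bin: sum g^i = n_bins
    if n_bins == cfg.M:
        growth = 1.0
    else:
        from scipy.optimize import brentq
        growth = brentq(
            lambda g: (g ** cfg.M - 1.0) / (g - 1.0) - n_bins, 1.0001, 2.0)
    sizes = np.maximum(1, np.round(growth ** np.arange(cfg.M))).astype(int)
    # adjust the largest groups so the sizes consume exactly n_bins
    while sizes.sum() > n_bins:
        sizes[np.argmax(sizes)] -= 1
    sizes[-1] += n_bins - sizes.sum()
    groups, pos = [], first
    for s in sizes:
        groups.append(np.arange(pos, pos + s))
        pos += s
    return groups


def ace_center_freqs(cfg: AceConfig) -> np.ndarray:
    bin_width = cfg.fs / cfg.frame_len
    return np.array([g.mean() * bin_width for g in ace_bin_groups(cfg)])


@dataclass
class Electrodogram:
    """Timed current pulses; within a cycle ordered base-to-apex."""

    times: np.ndarray                # [s]
    electrodes: np.ndarray           # 1..M, 1 = most apical / lowest freq
    amplitudes: np.ndarray           # clinical current units
    duration: float
    cfg: AceConfig = field(default_factory=AceConfig)

    def __len__(self) -> int:
        return len(self.times)

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.times, self.electrodes, self.amplitudes])

    @classmethod
    def from_table(cls, table: np.ndarray, duration: float,
                   cfg: AceConfig | None = None) -> "Electrodogram":
        table = np.atleast_2d(table)
        return cls(table[:, 0], table[:, 1].astype(int), table[:, 2],
                   duration, cfg or AceConfig())


def select_maxima(envelopes: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest envelopes; ties go to the lower channel."""
    order = np.lexsort((np.arange(len(envelopes)), -envelopes))
    return np.sort(order[:n])


def loudness_growth(env: np.ndarray, cfg: AceConfig) -> np.ndarray:
    """Log-compressive map of envelope onto the [THL, MCL] current range."""
    x = np.clip((env - cfg.base_level) / (cfg.sat_level - cfg.base_level),
                0.0, 1.0)
    frac = np.log1p(cfg.rho * x) / np.log1p(cfg.rho)
    return cfg.thl + (cfg.mcl - cfg.thl) * frac


def ace_envelopes(signal: np.ndarray, cfg: AceConfig | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Framewise channel envelopes and the n-of-m selection mask.

    Returns ``(cycle_start_samples, envelopes, selected)`` with envelopes
    of shape (cycles, M); ``selected`` marks the N largest envelopes per
    cycle that also exceed the base level.
    """
    cfg = cfg if cfg is not None else AceConfig()
    x = np.asarray(signal, float)
    starts = cfg.cycle_starts(len(x))
    if len(starts) == 0:
        raise ValueError("signal shorter than one ACE analysis frame")
    groups = ace_bin_groups(cfg)
    win = np.hanning(cfg.frame_len)
    win_gain = win.sum() / 2.0
    frames = x[starts[:, None] + np.arange(cfg.frame_len)[None, :]] * win
    spec = np.fft.rfft(frames, cfg.frame_len) / win_gain
    env = np.stack([np.abs(spec[:, g].sum(axis=1)) for g in groups], axis=1)
    selected = np.zeros(env.shape, bool)
    for c in range(env.shape[0]):
        sel = select_maxima(env[c], cfg.N)
        selected[c, sel] = env[c, sel] >= cfg.base_level
    return starts, env, selected


def ace_encode(signal: np.ndarray, cfg: AceConfig | None = None,
               ) -> Electrodogram:
    """Encode a 16 kHz mono signal into an ACE electrodogram.

    Hann-windowed 128-sample frames at the channel-rate advance; FFT-bin
    grouping into M band envelopes (magnitude of the complex bin sum); the
    N largest envelopes per cycle stimulate their electrodes base-to-apex,
    current mapped log-compressively between THL and MCL.  Envelopes below
    the base level emit no pulse.
    """
    cfg = cfg if cfg is not None else AceConfig()
    x = np.asarray(signal, float)
    starts, env, selected = ace_envelopes(x, cfg)
    pulse_slot = 1.0 / (cfg.N * cfg.channel_rate)
    times, electrodes, amps = [], [], []
    for c, t0 in enumerate(starts / cfg.fs):
        # base-to-apex: highest center frequency (highest channel) first
        slot = 0
        for ch in np.nonzero(selected[c])[0][::-1]:
            times.append(t0 + slot * pulse_slot)
            electrodes.append(ch + 1)
            amps.append(loudness_growth(env[c, ch], cfg))
            slot += 1
    return Electrodogram(np.array(times), np.array(electrodes, int),
                         np.array(amps), len(x) / cfg.fs, cfg)


# ---------------------------------------------------------------------------
# auditory-nerve population
# ---------------------------------------------------------------------------

@dataclass
class NervePopulation:
    """Integrate-and-fire nerve population along a 35 mm cochlea.

    Electrode positions are distances from the apex (apical electrode 1 at
    8.125 mm up to basal electrode 22 at 23.875 mm, 0.75 mm spacing); the
    current of each pulse decays as exp(-d / lambda) with distance d to
    the cell.
    """

    n_cells: int = 2200
    cochlea_len: float = 35.0        # [mm]
    elec_first: float = 8.125        # most apical electrode [mm from apex]
    elec_spacing: float = 0.75       # [mm]
    n_electrodes: int = 22
    lambda_spread: float = 1.0       # current-spread constant [mm]
    threshold: float = 100.0         # firing threshold, current units
    tau_mem: float = 0.5e-3          # membrane time constant [s]
    t_abs: float = 0.5e-3            # absolute refractory period [s]
    tau_rel: float = 1.0e-3         # relative-refractory recovery [s]
    rel_strength: float = 1.0        # threshold elevation factor at t_abs
    noise_sd: float = 0.05           # membrane noise sd re threshold
    latency: float = 0.5e-3          # spike latency [s]
    jitter_sd: float = 50e-6         # spike-time jitter sd [s]

    @property
    def cell_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.cochlea_len, self.n_cells)

    @property
    def electrode_positions(self) -> np.ndarray:
        return self.elec_first + self.elec_spacing * np.arange(self.n_electrodes)


def spread_factor(distance_mm, lambda_mm: float = 1.0):
    """Exponential current decay: factor exp(-|d| / lambda)."""
    return np.exp(-np.abs(np.asarray(distance_mm, float)) / lambda_mm)


@dataclass
class CellStimuli:
    """Per-cell stimulus amplitudes on the pulse-time grid."""

    times: np.ndarray                # (n_pulses,) [s], sorted
    amplitudes: np.ndarray           # (n_pulses, n_cells)
    duration: float


def spread_current(electrodogram: Electrodogram,
                   pop: NervePopulation) -> CellStimuli:
    """Spread each pulse's current over the population.

    Stimulus at a cell = pulse amplitude x exp(-|cell - electrode| / lambda).
    """
    epos = pop.electrode_positions
    if np.any(electrodogram.electrodes < 1) or \
            np.any(electrodogram.electrodes > pop.n_electrodes):
        raise ValueError("electrode index outside the array")
    order = np.argsort(electrodogram.times, kind="stable")
    times = electrodogram.times[order]
    dist = np.abs(pop.cell_positions[None, :]
                  - epos[electrodogram.electrodes[order] - 1][:, None])
    amps = electrodogram.amplitudes[order][:, None] * \
        spread_factor(dist, pop.lambda_spread)
    return CellStimuli(times, amps, electrodogram.duration)


@dataclass
class SpikeTrain:
    times: np.ndarray
    cells: np.ndarray
    duration: float
    n_cells: int


def simulate_population(stimuli: CellStimuli, pop: NervePopulation,
                        seed: int = 0) -> SpikeTrain:
    """Leaky integrate-and-fire simulation of the whole population.

    The membrane potential of every cell decays exponentially between
    pulses and integrates each arriving stimulus; a spike is emitted when
    the noisy potential crosses the (refractory-elevated) threshold, at
    the crossing time plus latency plus Gaussian jitter.  Absolute
    refractoriness blocks firing outright; relative refractoriness raises
    the effective threshold with an exponentially recovering factor.
    """
    if not np.all(np.isfinite(stimuli.amplitudes)):
        raise ValueError("non-finite stimulus amplitude")
    rng = np.random.default_rng(seed)
    n_cells = stimuli.amplitudes.shape[1]
    v = np.zeros(n_cells)
    t_prev = 0.0
    last_spike = np.full(n_cells, -np.inf)
    spike_times, spike_cells = [], []
    for p, t in enumerate(stimuli.times):
        v *= np.exp(-(t - t_prev) / pop.tau_mem)
        t_prev = t
        v += stimuli.amplitudes[p]
        since = t - last_spike
        ready = since > pop.t_abs
        theta = pop.threshold * (
            1.0 + pop.rel_strength * np.exp(-(since - pop.t_abs) / pop.tau_rel))
        noise = (rng.standard_normal(n_cells) * pop.noise_sd * pop.threshold
                 if pop.noise_sd > 0 else 0.0)
        fired = ready & (v + noise >= theta)
        if np.any(fired):
            idx = np.nonzero(fired)[0]
            jit = (rng.standard_normal(len(idx)) * pop.jitter_sd
                   if pop.jitter_sd > 0 else np.zeros(len(idx)))
            spike_times.append(t + pop.latency + jit)
            spike_cells.append(idx)
            v[idx] = 0.0
            last_spike[idx] = t
    if spike_times:
        times = np.concatenate(spike_times)
        cells = np.concatenate(spike_cells)
        order = np.argsort(times, kind="stable")
        times, cells = times[order], cells[order]
    else:
        times, cells = np.array([]), np.array([], int)
    return SpikeTrain(times, cells, stimuli.duration, n_cells)


# ---------------------------------------------------------------------------
# internal representation
# ---------------------------------------------------------------------------

@dataclass
class IrConfig:
    """Spatio-temporal integration of the spike pattern into features."""

    n_groups: int = 46               # spatial groups over the electrode span
    gauss_sd: float = 2e-3           # temporal Gaussian filter sd [s]
    tau_int: float = 10e-3           # recursive integrator time constant [s]
    noise_var: float = 0.1           # multiplicative Gaussian noise, mean 1
    frame_shift_s: float = 0.010     # output frame grid (matches log-Mel)
    frame_len_s: float = 0.025
    internal_fs: float = 1000.0      # integration grid [Hz]

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one spatial group")


def group_centers(pop: NervePopulation, ir_cfg: IrConfig) -> np.ndarray:
    epos = pop.electrode_positions
    return np.linspace(epos[0], epos[-1], ir_cfg.n_groups)


def internal_representation(spikes: SpikeTrain, pop: NervePopulation,
                            ir_cfg: IrConfig | None = None, seed: int = 0,
                            n_frames: int | None = None,
                            apply_noise: bool = True,
                            normalize: bool = False) -> np.ndarray:
    """Bin, smooth and resample the spike pattern to (frames, n_groups).

    Spikes are assigned to the spatial group whose center is nearest to
    their cell's cochlear position, counted on a 1 ms grid, smoothed by a
    Gaussian FIR (temporal-resolution reduction) followed by a first-order
    recursive integrator, sampled at the acoustic frame centers, and
    multiplied by Gaussian noise of mean 1 (central degradation).
    Normalization to per-feature zero mean / unit variance is done over a
    training corpus (see ``fade.FeatureNormalizer``), or here when
    ``normalize`` is set.
    """
    ir_cfg = ir_cfg if ir_cfg is not None else IrConfig()
    centers = group_centers(pop, ir_cfg)
    dt = 1.0 / ir_cfg.internal_fs
    if n_frames is None:
        n_frames = int((spikes.duration - ir_cfg.frame_len_s)
                       / ir_cfg.frame_shift_s) + 1
    n_bins = int(np.ceil(spikes.duration / dt)) + 1
    counts = np.zeros((n_bins, ir_cfg.n_groups))
    if len(spikes.times):
        pos = pop.cell_positions[spikes.cells]
        gidx = np.argmin(np.abs(pos[:, None] - centers[None, :]), axis=1)
        tidx = np.clip((spikes.times / dt).astype(int), 0, n_bins - 1)
        np.add.at(counts, (tidx, gidx), 1.0)

    # Gaussian FIR then recursive one-pole integrator, per group
    half = int(np.ceil(4 * ir_cfg.gauss_sd / dt))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) * dt / ir_cfg.gauss_sd) ** 2)
    kern /= kern.sum()
    smooth = sps.fftconvolve(counts, kern[:, None], mode="same", axes=0)
    a = np.exp(-dt / ir_cfg.tau_int)
    smooth = sps.lfilter([1.0 - a], [1.0, -a], smooth, axis=0)

    frame_centers = (ir_cfg.frame_len_s / 2
                     + ir_cfg.frame_shift_s * np.arange(n_frames))
    fidx = np.clip((frame_centers / dt).astype(int), 0, n_bins - 1)
    ir = smooth[fidx]
    if apply_noise and ir_cfg.noise_var > 0:
        rng = np.random.default_rng(seed)
        ir = ir * (1.0 + np.sqrt(ir_cfg.noise_var)
                   * rng.standard_normal(ir.shape))
    if normalize:
        mu = ir.mean(axis=0)
        sd = ir.std(axis=0)
        ir = (ir - mu) / np.maximum(sd, 1e-12)
    return ir


def electric_features(signal: np.ndarray, ace_cfg: AceConfig,
                      pop: NervePopulation, ir_cfg: IrConfig,
                      seed: int = 0, n_frames: int | None = None,
                      ) -> np.ndarray:
    """Full electric pathway: audio -> ACE -> spread -> spikes -> IR."""
    eg = ace_encode(signal, ace_cfg)
    if len(eg) == 0:
        dur = len(signal) / ace_cfg.fs
        empty = SpikeTrain(np.array([]), np.array([], int), dur, pop.n_cells)
        return internal_representation(empty, pop, ir_cfg, seed, n_frames)
    stim = spread_current(eg, pop)
    spikes = simulate_population(stim, pop, seed)
    return internal_representation(spikes, pop, ir_cfg, seed + 1, n_frames)
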