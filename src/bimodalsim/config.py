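"""Experiment configuration, validation and orchestration.

An :class:`ExperimentConfig` describes a scenario x beamformer matrix of
model runs (``fade``, ``bsim`` or ``isnr``), the SNR grids, and all
physics/feature parameters.  Two scale profiles exist: ``full`` uses the
full-scale settings (120-sentence corpus, 10 alternatives per slot,
2200 nerve cells, the full SNR ranges), ``desk`` caps corpus size,
nerve-cell count, HMM size and grid so a complete run finishes on a
single desktop core in minutes.  Every completed run writes its resolved
configuration (including all derived seeds) so it can be replayed
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acoustic import AcousticFeatureConfig, Audiogram
from .bsim import BsimConfig, EaWeighting
from .electric import AceConfig, IrConfig, NervePopulation
from .fade import HmmConfig, SnrGrid
from .frontend import BEAMFORMERS, CompressorConfig
from .pipeline import (DeviceChain, FeatureChain, bsim_predict, fade_srt,
                       isnr_improvements)
from .scene import SCENARIOS, HeadModel, generate_corpus

#: training/testing SNR ranges [dB] per (beamformer, scenario)
DEFAULT_SNR_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("NoBF", "S0N-90"): (-13, 5), ("NoBF", "S0N0"): (-9, 6),
    ("NoBF", "S0N+90"): (-13, 5), ("NoBF", "S0N20TB"): (-10, 8),
    ("ADM", "S0N-90"): (-18, 0), ("ADM", "S0N0"): (-9, 6),
    ("ADM", "S0N+90"): (-18, 0), ("ADM", "S0N20TB"): (-16, 2),
    ("MVDR", "S0N-90"): (-24, -6), ("MVDR", "S0N0"): (-9, 6),
    ("MVDR", "S0N+90"): (-21, -3), ("MVDR", "S0N20TB"): (-18, 0),
}


def default_grid(beamformer: str, scenario: str,
                 n_train_mixtures: int = 8) -> SnrGrid:
    lo, hi = DEFAULT_SNR_RANGES[(beamformer, scenario)]
    return SnrGrid.from_range(lo, hi, 3.0, n_train_mixtures=n_train_mixtures)


@dataclass
class CorpusSpec:
    n_alternatives: int = 10
    n_sentences: int = 120
    token_dur: float = 0.4


@dataclass
class ExperimentConfig:
    scenarios: list[str] = field(default_factory=lambda: ["S0N0"])
    beamformers: list[str] = field(default_factory=lambda: ["NoBF"])
    model: str = "fade"              # fade | bsim | isnr
    side_mode: str = "bimodal"
    profile: str = "desk"            # desk | full
    seed: int = 1
    corpus: CorpusSpec = field(default_factory=CorpusSpec)
    head: HeadModel = field(default_factory=HeadModel)
    audiogram: Audiogram = field(default_factory=Audiogram.moderate_sloping)
    compressor: CompressorConfig = field(default_factory=CompressorConfig)
    acoustic: AcousticFeatureConfig = field(
        default_factory=AcousticFeatureConfig)
    ace: AceConfig = field(default_factory=AceConfig)
    pop: NervePopulation = field(default_factory=NervePopulation)
    ir: IrConfig = field(default_factory=IrConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    bsim: BsimConfig = field(default_factory=BsimConfig)
    weighting: EaWeighting = field(default_factory=EaWeighting)
    grid: SnrGrid | None = None      # None: per-cell defaults
    n_train_mixtures: int = 8

    def __post_init__(self) -> None:
        if self.profile == "desk":
            self.apply_desk_profile()

    def apply_desk_profile(self) -> None:
        """Cap problem sizes for a minutes-scale single-core run."""
        self.corpus = CorpusSpec(n_alternatives=4, n_sentences=8,
                                 token_dur=0.15)
        self.pop = dataclasses.replace(self.pop, n_cells=300)
        self.ir = dataclasses.replace(self.ir, n_groups=10)
        self.hmm = dataclasses.replace(self.hmm, states_word=2,
                                       states_edge=2, states_silence=2,
                                       max_iter=10)
        self.n_train_mixtures = 2
        if self.grid is None:
            self.grid = SnrGrid(np.array([-24.0, -12.0, 0.0]),
                                np.arange(-30.0, 12.1, 6.0),
                                n_train_mixtures=2)

    def make_corpus(self):
        return generate_corpus(self.corpus.n_alternatives,
                               self.corpus.n_sentences, self.seed,
                               token_dur=self.corpus.token_dur)

    def device_chain(self, beamformer: str) -> DeviceChain:
        return DeviceChain(beamformer, self.head, self.audiogram,
                           self.compressor)

    def feature_chain(self, beamformer: str) -> FeatureChain:
        return FeatureChain(self.device_chain(beamformer), self.acoustic,
                            self.ace, self.pop, self.ir, self.side_mode)

    def grid_for(self, beamformer: str, scenario: str) -> SnrGrid:
        if self.grid is not None:
            return self.grid
        return default_grid(beamformer, scenario, self.n_train_mixtures)


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Cross-field validation; returns a list of error messages."""
    errors = []
    for s in cfg.scenarios:
        if s not in SCENARIOS:
            errors.append(f"unknown scenario '{s}' (choose from {SCENARIOS})")
    for b in cfg.beamformers:
        if b not in BEAMFORMERS:
            errors.append(f"unknown beamformer '{b}' "
                          f"(choose from {BEAMFORMERS})")
    if cfg.model not in ("fade", "bsim", "isnr"):
        errors.append(f"unknown model '{cfg.model}'")
    if cfg.side_mode not in ("bimodal", "acoustic", "ci"):
        errors.append(f"unknown side_mode '{cfg.side_mode}'")
    if cfg.ace.N > cfg.ace.M:
        errors.append(f"ACE maxima N={cfg.ace.N} exceeds channels "
                      f"M={cfg.ace.M} (need N <= M)")
    for name, ref in (("sii_ref_acoustic", cfg.bsim.sii_ref_acoustic),
                      ("sii_ref_ci", cfg.bsim.sii_ref_ci)):
        if not 0.0 < ref < 1.0:
            errors.append(f"{name}={ref} outside (0, 1)")
    if cfg.grid is not None:
        if np.any(np.diff(cfg.grid.train_snrs) <= 0):
            errors.append("training SNR grid not strictly increasing")
        if np.any(np.diff(cfg.grid.test_snrs) <= 0):
            errors.append("testing SNR grid not strictly increasing")
    if cfg.corpus.n_sentences % cfg.corpus.n_alternatives:
        errors.append("n_sentences must be divisible by n_alternatives "
                      "for a balanced corpus")
    return errors


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj) if not f.name.startswith("_")}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def run_experiment(cfg: ExperimentConfig,
                   out_dir: str | Path | None = None) -> dict:
    """Run the configured model over the scenario x beamformer matrix.

    Returns a results dictionary; with ``out_dir`` set, also writes the
    per-cell results, the recognition matrices and the resolved
    configuration (seeds included) for exact replay.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(errors))
    corpus = cfg.make_corpus()
    results: dict = {"model": cfg.model, "cells": []}
    for scenario in cfg.scenarios:
        for bf in cfg.beamformers:
            cell: dict = {"scenario": scenario, "beamformer": bf}
            if cfg.model == "fade":
                chain = cfg.feature_chain(bf)
                srt, matrix = fade_srt(corpus, scenario, chain,
                                       cfg.grid_for(bf, scenario),
                                       cfg.hmm, cfg.seed)
                cell["srt_db"] = srt
                cell["matrix"] = matrix.rates.tolist()
                cell["train_snrs"] = matrix.train_snrs.tolist()
                cell["test_snrs"] = matrix.test_snrs.tolist()
            elif cfg.model == "bsim":
                pred = bsim_predict(corpus, scenario, cfg.device_chain(bf),
                                    cfg.bsim, cfg.ace, cfg.pop,
                                    cfg.weighting, cfg.side_mode,
                                    seed=cfg.seed)
                cell["srt_db"] = pred.result.srt_db
                cell["sii_reference"] = pred.result.reference
                cell["note"] = pred.result.note
            else:
                cell["isnr_db"] = isnr_improvements(
                    corpus, scenario, cfg.device_chain(bf), seed=cfg.seed)
            results["cells"].append(cell)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(_to_plain(results),
                                                     indent=2))
        (out / "resolved_config.yaml").write_text(
            yaml.safe_dump(_to_plain(cfg)))
    return results
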