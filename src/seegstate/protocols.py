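"""Canned experiment protocols at desk scale.

These wrap the pipeline into the two synthetic cohorts the package's
headline analyses run on:

* the *high-SNR cohort* — 30 sentences x 3 repetitions, 40 channels of
  which 12 are informative at snr 2, spread over cortical and
  subcortical regions; used for discretized and continuous decoding;
* the *split-informative cohort* — same size, but with exactly 6
  informative channels inside the classical speech-region set and 6
  outside it; used for the region-exclusion robustness analysis.

Both train the default architecture for 30 epochs (with the usual
early stopping) over several sentence-level split seeds on a single
simulated session — one recording per cohort, resampled by the
sentence-level splitter, as in a single-session clinical experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .interpret import AblationSpec, ablated_channel_indices
from .pipeline import (PreparedRecordings, build_dataset, derive_seed,
                       prepare_recordings, run_split_experiment)

#: Informative-region layout for the split-informative cohort:
#: six classical speech regions, six regions outside that set.
SPEECH_SET_REGIONS = ["SFG", "IFG", "STG", "MTG", "Precen", "Angular"]
NON_SPEECH_SET_REGIONS = ["Tha", "Hipp", "Amyg", "CG", "INS", "Postcen"]


def high_snr_config(seed: int = 1) -> ExperimentConfig:
    cfg = ExperimentConfig()
    cfg.paradigm.n_sentences = 30
    cfg.paradigm.n_repetitions = 3
    cfg.channels.n_channels = 40
    cfg.channels.fraction_informative = 0.3
    cfg.channels.snr = 2.0
    cfg.training.epochs = 30
    cfg.evaluation.n_split_seeds = 5
    cfg.seed = seed
    return cfg


def demo_config(seed: int = 0) -> ExperimentConfig:
    """A minutes-scale session for the narrative analysis scripts:
    12 sentences x 2 repetitions, 16 channels (5 informative, snr 2)."""
    cfg = ExperimentConfig()
    cfg.paradigm.n_sentences = 12
    cfg.paradigm.n_repetitions = 2
    cfg.channels.n_channels = 16
    cfg.channels.fraction_informative = 0.3
    cfg.channels.snr = 2.0
    cfg.training.epochs = 10
    cfg.evaluation.n_split_seeds = 3
    cfg.seed = seed
    return cfg


def split_informative_config(seed: int = 1) -> ExperimentConfig:
    cfg = high_snr_config(seed)
    cfg.channels.informative_regions = SPEECH_SET_REGIONS + NON_SPEECH_SET_REGIONS
    cfg.evaluation.continuous = False
    return cfg


@dataclass
class CohortResult:
    """Per-split-seed outcomes of one cohort run."""

    discretized: list[float] = field(default_factory=list)
    continuous: list[pd.DataFrame] = field(default_factory=list)
    n_eval_segments: list[int] = field(default_factory=list)
    split_seeds: list[int] = field(default_factory=list)

    @property
    def median_discretized(self) -> float:
        return float(np.median(self.discretized))

    @property
    def mean_continuous_per_sentence(self) -> float:
        accs = np.concatenate([df.accuracy.to_numpy() for df in self.continuous])
        return float(accs.mean())

    @property
    def n_continuous_trials(self) -> int:
        return int(sum(len(df) for df in self.continuous))


def run_cohort(
    cfg: ExperimentConfig,
    n_seeds: int | None = None,
    channel_indices: np.ndarray | None = None,
    prepared: PreparedRecordings | None = None,
    continuous: bool | None = None,
) -> tuple[CohortResult, PreparedRecordings]:
    """Simulate (or reuse) a session and run it over split seeds.

    Returns the per-seed results together with the prepared recordings
    so further conditions (ablations) can reuse the same session and
    the same split seeds for paired comparisons.
    """
    if prepared is None:
        dataset = build_dataset(cfg)
        prepared = prepare_recordings(dataset, cfg)
    n_seeds = n_seeds if n_seeds is not None else cfg.evaluation.n_split_seeds
    result = CohortResult()
    for i in range(1, n_seeds + 1):
        split_seed = derive_seed(cfg.seed, f"split-{i}")
        run = run_split_experiment(prepared, cfg, split_seed,
                                   channel_indices=channel_indices,
                                   continuous=continuous)
        result.discretized.append(run.discretized_accuracy)
        result.n_eval_segments.append(run.n_eval_segments)
        result.split_seeds.append(split_seed)
        if run.continuous is not None:
            result.continuous.append(run.continuous)
    return result, prepared


def region_exclusion_indices(prepared: PreparedRecordings) -> np.ndarray:
    """Selected-channel indices that survive the speech-region exclusion."""
    return ablated_channel_indices(prepared.offline.channels,
                                   AblationSpec(kind="region_exclusion"))
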