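"""Experiment configuration: nested dataclasses with lossless YAML round-trip.

Defaults throughout reproduce the reference protocol: the 100x3 reading
paradigm, broadband preprocessing to 500 Hz / 100 ms windows, the plain
CNN architecture and its Adam/cosine training recipe, an 80/20
sentence-level split repeated over seeds, the 0/10/30/50% dropout and
speech-region-exclusion ablations, and gradient saliency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .cnn import ModelConfig, TrainConfig
from .paradigm import ParadigmConfig
from .preprocess import PreprocConfig
from .simulate import NoiseParams


@dataclass
class ChannelGenConfig:
    """Synthetic montage parameters."""

    n_channels: int = 40
    fraction_informative: float = 0.3
    snr: float = 1.0
    informative_regions: list[str] | None = None

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 <= self.fraction_informative <= 1.0:
            raise ValueError("fraction_informative must lie in [0, 1]")


@dataclass
class EvaluationConfig:
    eval_fraction: float = 0.2
    n_split_seeds: int = 20
    continuous: bool = True
    continuous_window: float = 0.100
    continuous_step: float = 0.005

    def validate(self) -> None:
        if not 0.0 < self.eval_fraction < 1.0:
            raise ValueError("eval_fraction must lie strictly between 0 and 1")
        if self.n_split_seeds < 1:
            raise ValueError("n_split_seeds must be >= 1")
        if self.continuous_window <= 0 or self.continuous_step <= 0:
            raise ValueError("continuous window/step must be positive")


@dataclass
class AblationRunConfig:
    run_dropout: bool = True
    dropout_fractions: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5)
    run_region_exclusion: bool = True
    run_saliency: bool = True


@dataclass
class ExperimentConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    channels: ChannelGenConfig = field(default_factory=ChannelGenConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    ablation: AblationRunConfig = field(default_factory=AblationRunConfig)
    seed: int = 0
    output_dir: str = "results/run"

    def validate(self) -> None:
        self.paradigm.validate()
        self.channels.validate()
        self.preprocessing.validate()
        self.training.validate()
        self.evaluation.validate()


_TUPLE_FIELDS = {
    "prep_duration_range", "rest_duration_range", "syllables_per_sentence_range",
    "syllable_duration_range", "pause_duration_range", "line_freqs", "line_amps",
    "lowfreq_band", "hga_band", "notch_freqs", "dropout_fractions",
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "paradigm", "channels", "noise", "preprocessing", "model",
                "training", "evaluation", "ablation"):
            sub_cls = {
                "paradigm": ParadigmConfig, "channels": ChannelGenConfig,
                "noise": NoiseParams, "preprocessing": PreprocConfig,
                "model": ModelConfig, "training": TrainConfig,
                "evaluation": EvaluationConfig, "ablation": AblationRunConfig,
            }[f.name]
            kwargs[f.name] = _from_plain(sub_cls, v)
        elif f.name == "blocks":
            kwargs[f.name] = tuple(tuple(b) for b in v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def to_yaml(cfg: ExperimentConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def from_yaml(text: str) -> ExperimentConfig:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    cfg = _from_plain(ExperimentConfig, data)
    cfg.validate()
    return cfg


def save_config(path, cfg: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        fh.write(to_yaml(cfg))


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return from_yaml(fh.read())
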