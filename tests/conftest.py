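import numpy as np
import pytest

from seegstate import config, pipeline


@pytest.fixture(scope="session")
def small_cfg() -> config.ExperimentConfig:
    """A small but fully featured experiment: 8 sentences x 2 reps, 12 channels."""
    cfg = config.ExperimentConfig()
    cfg.paradigm.n_sentences = 8
    cfg.paradigm.n_repetitions = 2
    cfg.channels.n_channels = 12
    cfg.channels.fraction_informative = 0.3
    cfg.channels.snr = 2.0
    cfg.training.epochs = 8
    cfg.evaluation.n_split_seeds = 1
    cfg.seed = 0
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return pipeline.build_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_prepared(small_cfg, small_dataset):
    return pipeline.prepare_recordings(small_dataset, small_cfg)


@pytest.fixture(scope="session")
def small_run(small_cfg, small_prepared):
    """One trained split (discretized + continuous) on the small session."""
    return pipeline.run_split_experiment(small_prepared, small_cfg, split_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
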