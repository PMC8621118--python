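import numpy as np
import pytest

from bbscore.preprocessing import downsample, minmax_normalize
from bbscore.simulate import SimConfig, generate_task_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Three tasks, six segments per class: enough for spectral statistics."""
    return SimConfig(task_ids=(1, 2, 3), class_counts={s: 6 for s in range(5)}, seed=0)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return [generate_task_dataset(small_config, t) for t in small_config.task_ids]


@pytest.fixture(scope="session")
def separable_dataset():
    """One task, 12 per class, strong class separation, ready for training."""
    cfg = SimConfig(
        task_ids=(1,),
        class_counts={s: 12 for s in range(5)},
        separation=2.5,
        seed=5,
    )
    ds = generate_task_dataset(cfg, 1)
    return downsample(minmax_normalize(ds), 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
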