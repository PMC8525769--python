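import numpy as np
import pytest

from dualhgf.task import experiment_config, generate_task


@pytest.fixture(scope="session")
def exp1_task():
    """Experiment-1 task (80 trials, 50% accurate bets), fixed seed."""
    cfg = experiment_config(1, seed=11)
    return generate_task(cfg)


@pytest.fixture(scope="session")
def c2_trials(exp1_task):
    return exp1_task[1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
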