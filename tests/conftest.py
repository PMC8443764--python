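import warnings

import numpy as np
import pandas as pd
import pytest

import tempodisc as td

# arviz emits a refactor FutureWarning on import; irrelevant to these tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: fewer subjects and repetitions, same task structure."""
    return td.SimulationConfig(n_subjects=8, reps_per_combo=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return td.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def tiny_sampler():
    return td.SamplerConfig(chains=2, iterations=400, warmup=150, seed=5)


def make_timing_frame(records):
    """Build a timing-trial table from (subject, task, actual, reported) tuples."""
    return pd.DataFrame(
        records, columns=["subject_id", "task", "actual_s", "reported_s"]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
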