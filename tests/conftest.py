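import numpy as np
import pytest

from saltpursuit import BodyParams, RunConfig, TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def body():
    return BodyParams()


@pytest.fixture
def task():
    return TaskConfig()


@pytest.fixture
def ri_config():
    return RunConfig.for_condition("RI")


@pytest.fixture
def ud_config():
    return RunConfig.for_condition("UD")


@pytest.fixture
def short_task():
    """A short trial (T=30, T_T=10) for integration-path tests."""
    return TaskConfig(duration=30, transient=10, signal_intervals=10)
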