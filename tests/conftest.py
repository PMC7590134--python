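from pathlib import Path

import numpy as np
import pytest

from imucodec.predictors import SignalChannel, predictor_from_name

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def all_specs():
    """One PredictorSpec per shipped method name."""
    from imucodec.predictors import METHOD_NAMES

    return {name: predictor_from_name(name) for name in METHOD_NAMES}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_walk_channel(
    rng: np.random.Generator, n: int = 2000, step_sd: float = 10.0
) -> SignalChannel:
    """Random walk with integer-rounded Gaussian increments, clipped to int16."""
    steps = np.rint(rng.normal(0.0, step_sd, n)).astype(np.int64)
    return SignalChannel(np.clip(np.cumsum(steps), -32000, 32000))
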