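import math

import numpy as np
import pytest

from rrmi import ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binary_spec():
    """Headline binary scenario with MI settings shrunk for unit-test speed."""
    return ScenarioSpec(
        exposure_type="binary",
        prevalence=0.30,
        beta1=math.log(3),
        beta2=math.log(3),
        assoc=2.0,
        mechanism="coordinated",
        lam=2.0,
        n=500,
        reps=5,
        m=4,
        cycles=5,
        burn_in=40,
        between=10,
        seed=7,
    )


@pytest.fixture
def continuous_spec():
    return ScenarioSpec(
        exposure_type="continuous",
        prevalence=0.30,
        beta1=math.log(3),
        beta2=math.log(3),
        assoc=0.70,
        mechanism="coordinated",
        lam=2.0,
        n=500,
        reps=5,
        m=4,
        cycles=5,
        burn_in=40,
        between=10,
        seed=7,
    )
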