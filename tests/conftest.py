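import numpy as np
import pytest
from hypothesis import settings

from milkbot import Lactation, MilkBotParams, TestDay

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def p1_means() -> MilkBotParams:
    """Population-mean parameters for first-parity (P1) cows."""
    return MilkBotParams(scale=38.66, ramp=31.43, offset=-0.5, decay=0.000974)


@pytest.fixture
def p2_means() -> MilkBotParams:
    """Population-mean parameters for mature (P2+) cows."""
    return MilkBotParams(scale=53.65, ramp=26.13, offset=-0.37, decay=0.002213)


#: A highly irregular real-world 10-test lactation (herd "N" in the source
#: survey); milk weights in kg at an assumed monthly schedule starting DIM 15.
HERD_N_MILK = (47.7, 83.1, 84.4, 32.2, 8.2, 55.4, 77.2, 64.5, 34.0, 24.1)
HERD_N_DIM = tuple(range(15, 286, 30))


@pytest.fixture
def herd_n_lactation() -> Lactation:
    return Lactation(
        lactation_id="N-outlier",
        herd_id="N",
        parity_group="P2plus",
        tests=tuple(TestDay(d, m) for d, m in zip(HERD_N_DIM, HERD_N_MILK)),
    )


def random_valid_params(rng: np.random.Generator) -> MilkBotParams:
    """A random parameter vector spanning the realistic envelope."""
    return MilkBotParams(
        scale=rng.uniform(15.0, 80.0),
        ramp=rng.uniform(5.0, 60.0),
        offset=rng.uniform(-10.0, 10.0),
        decay=rng.uniform(1e-4, 6e-3),
    )
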