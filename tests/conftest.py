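import numpy as np
import pytest

from aeqsim import CohortParams, generate_cohort
from aeqsim.cohort import GROUPS


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(5, CohortParams(), seed=11)


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    return {g: [s for s in default_cohort if s.group == g] for g in GROUPS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class ScriptedRNG:
    """Stand-in generator replaying a fixed script of draws (for oracles)."""

    def __init__(self, randoms=(), integers=()):
        self._randoms = list(randoms)
        self._integers = list(integers)

    def random(self):
        return self._randoms.pop(0)

    def integers(self, n):
        value = self._integers.pop(0)
        assert value < n
        return value


@pytest.fixture()
def scripted_rng_cls():
    return ScriptedRNG
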