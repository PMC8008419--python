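import numpy as np
import pytest

from ssdopt import EGOConfig, PSOSettings
from ssdopt.problems import ClusterTrialParams, make_cluster_problem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cluster_problem():
    return make_cluster_problem(ClusterTrialParams())


@pytest.fixture
def small_ego_config():
    """Cheap settings for loop-mechanics tests (not operating-characteristic tests)."""
    return EGOConfig(
        iterations=4,
        initial_design_size=10,
        n_per_eval=40,
        root_seed=3,
        pso=PSOSettings(swarm_size=15, iterations=40),
        gp_restarts=4,
    )


class BernoulliSimulator:
    """Rejects with a fixed known probability; the simplest calibration target."""

    hypotheses = frozenset({"null", "alternative"})

    def __init__(self, p_reject: float):
        self.p_reject = p_reject

    def simulate_once(self, x, hypothesis, rng):
        return int(rng.random() < self.p_reject)


class AlwaysRejectSimulator:
    hypotheses = frozenset({"null", "alternative"})

    def simulate_once(self, x, hypothesis, rng):
        return 1


class BrokenSimulator:
    hypotheses = frozenset({"null"})

    def simulate_once(self, x, hypothesis, rng):
        return 0.5


@pytest.fixture
def bernoulli_simulator_factory():
    return BernoulliSimulator


@pytest.fixture
def always_reject_simulator():
    return AlwaysRejectSimulator()


@pytest.fixture
def broken_simulator():
    return BrokenSimulator()
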