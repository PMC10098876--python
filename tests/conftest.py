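import numpy as np
import pytest

from seamtte import SelectionRule, StageSummaries, apply_rule
from seamtte.io import worked_example_inputs


@pytest.fixture(scope="session")
def worked_example():
    """Stage summaries, rule and outcome of the packaged worked example."""
    summaries, rule = worked_example_inputs()
    outcome = apply_rule(rule, summaries.theta1, summaries.V1)
    return summaries, rule, outcome


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_summaries_1arm(theta1, V1, theta_full, V_full):
    """Single-arm summaries helper used by closed-form bias tests."""
    return StageSummaries.build(
        np.array([theta1]),
        np.array([V1]),
        np.array([[1.0 / V1]]),
        {1: theta_full},
        {1: V_full},
    )


@pytest.fixture()
def exchangeable_config():
    """Balanced 4-arm stage-1 configuration with shared-control
    correlation 0.5, a typical interim state."""
    K = 4
    V1 = np.full(K, 150.0)
    s1 = 1.0 / V1
    Sigma1 = np.diag(s1) + 0.5 * np.sqrt(np.outer(s1, s1)) * (
        1 - np.eye(K)
    )
    sigma2sq = np.full(K, 1.0 / 160.0)
    return np.zeros(K), Sigma1, sigma2sq, V1
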