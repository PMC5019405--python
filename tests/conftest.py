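"""Shared fixtures: small pattern sets and quickly trained networks.

Everything is generated at run time from fixed seeds; the "small" training
fixture uses a reduced task (N=50, K=M=2) so that most tests stay fast,
while the session-scoped ``paper_net`` fixture trains one full-size network
with the default study conditions for the acceptance checks.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from hiermem import (
    LearningConfig,
    PatternSpec,
    generate_pattern_set,
    train,
)


@pytest.fixture(scope="session")
def small_patterns():
    return generate_pattern_set(PatternSpec(n=50, k=2, m=2, p_flip=0.15, seed=42))


@pytest.fixture(scope="session")
def small_config():
    return LearningConfig(epochs=30, presentation_time=5.0, seed=7)


@pytest.fixture(scope="session")
def small_trained(small_patterns, small_config):
    return train(small_patterns, small_config)


@pytest.fixture(scope="session")
def paper_ensemble():
    """Two independently trained full-size networks (default conditions)."""
    out = []
    for seed in (1, 2):
        ps = generate_pattern_set(PatternSpec(seed=seed))
        out.append((ps, train(ps, LearningConfig(seed=seed))))
    return out


@pytest.fixture(scope="session")
def paper_patterns(paper_ensemble):
    return paper_ensemble[0][0]


@pytest.fixture(scope="session")
def paper_net(paper_ensemble):
    """One fully trained network with the default study conditions."""
    return paper_ensemble[0][1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
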