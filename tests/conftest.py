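"""Shared fixtures: canonical strategy set and reference payoff matrices."""

import numpy as np
import pytest

import altpd


@pytest.fixture(scope="session")
def strategies():
    return altpd.enumerate_strategies()


@pytest.fixture(scope="session")
def named(strategies):
    return {s.name: s for s in strategies}


@pytest.fixture(scope="session")
def reference_params():
    """Benefit 3, cost 1, 5% error rate, 100 rounds: the headline condition."""
    return altpd.GameParameters(benefit=3.0, cost=1.0, epsilon=0.05, rounds=100)


@pytest.fixture(scope="session")
def matrix_b3(reference_params):
    return altpd.payoff_matrix(reference_params)


@pytest.fixture(scope="session")
def matrix_b5():
    return altpd.payoff_matrix(
        altpd.GameParameters(benefit=5.0, cost=1.0, epsilon=0.05, rounds=100)
    )


@pytest.fixture(scope="session")
def forgiver_alliance(matrix_b3):
    """A converged cooperative-alliance state at b = 3 (mu = 0)."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        report = altpd.integrate(altpd.sample_simplex(26, rng), matrix_b3)
        if report.attractor is altpd.AttractorClass.MIXED_FORGIVER:
            return report
    raise RuntimeError("no cooperative-alliance trajectory found in 50 starts")
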