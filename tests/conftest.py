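import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def example_counts():
    """A moderately associated table with every cell populated."""
    from xci_assoc import GenotypeCounts

    return GenotypeCounts(
        female_case=[80, 60, 70, 40],
        female_control=[120, 50, 45, 35],
        male_case=[150, 100],
        male_control=[200, 50],
    )


def random_counts(rng, n_tables, low=1, high=200):
    """Random strictly positive count tables for oracle sweeps."""
    from xci_assoc import GenotypeCounts

    out = []
    for _ in range(n_tables):
        out.append(
            GenotypeCounts(
                female_case=rng.integers(low, high, 4),
                female_control=rng.integers(low, high, 4),
                male_case=rng.integers(low, high, 2),
                male_control=rng.integers(low, high, 2),
            )
        )
    return out
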