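import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal22():
    from mechelix.geometry import build_ideal_helix
    return build_ideal_helix(22)


@pytest.fixture(scope="session")
def toy_trajectory():
    """Five frames with longest runs 5, 3, 6, 0, 8 and end-to-end distances
    3.4, 3.1, 2.8, 4.0, 3.3 nm over a 10-residue chain."""
    from mechelix.helicity import StateTrajectory
    states = [
        "HHHHHCCCCC",  # run 5
        "CHHHCCCCCC",  # run 3
        "HHHHHHCCCC",  # run 6
        "CCCCCCCCCC",  # run 0
        "HHHHHHHHCC",  # run 8
    ]
    e2e = [3.4, 3.1, 2.8, 4.0, 3.3]
    return StateTrajectory.from_strings([1.0, 2.0, 3.0, 4.0, 5.0],
                                        states, e2e)
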