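import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    """Seeded stdlib RNG for reproducible randomized tests."""
    return random.Random(1234)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(length))
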