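import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-phantom cohort reused by segmentation/feature tests."""
    from mammoteo import phantom

    samples, manifest = phantom.generate_dataset(12, seed=5)
    return samples, manifest


def dice(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * float(np.sum(a & b)) / float(s)
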