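import pytest
from hypothesis import settings

import trackermine as tm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return tm.default_cohort_spec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """Canonical synthetic cohort used across the suite."""
    return tm.generate(default_spec, seed=1)


@pytest.fixture(scope="session")
def transactions(cohort):
    return tm.build_transactions(cohort)
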