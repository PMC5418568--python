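import pytest

from lynchscreen.cohort import fixture_cohort
from lynchscreen.pipeline import classify_cohort


@pytest.fixture(scope="session")
def cohort():
    return fixture_cohort()


@pytest.fixture(scope="session")
def calls(cohort):
    return classify_cohort(cohort)
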