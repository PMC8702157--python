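import pytest

from rrms_cea import make_study_fixture


@pytest.fixture(scope="session")
def study_cohort():
    """The deterministic 146-patient study fixture (immutable; session-wide)."""
    return make_study_fixture()
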