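import pytest

from osmotip import run, standard_lilium


@pytest.fixture(scope="session")
def params():
    return standard_lilium()


@pytest.fixture(scope="session")
def baseline_tc(params):
    """The 2000-s baseline run shared by several tests."""
    return run(params, duration=2000.0)
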