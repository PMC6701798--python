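import pytest

from avhsim import run_experiment_suite


@pytest.fixture(scope="session")
def suite():
    """The four preset experiments, run once per test session (argmax mode)."""
    trials, labels, summary = run_experiment_suite(seed=0)
    return trials, labels, summary
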