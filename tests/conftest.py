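import pytest

from hclat import StudyDesign, TruthModel, simulate_study


@pytest.fixture(scope="session")
def truth():
    return TruthModel(seed=7)


@pytest.fixture(scope="session")
def small_study(truth):
    """A reduced-size simulated study shared across tests (read-only)."""
    design = StudyDesign(substance="test NP", dose_top=200.0, n_events=1500)
    return simulate_study(truth, design, seed=7)
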