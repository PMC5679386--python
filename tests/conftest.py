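import pytest

from radcea import evaluate_config, study_fixture


@pytest.fixture(scope="session")
def study_config():
    """The calibrated IORT-vs-EBRT study configuration."""
    return study_fixture()


@pytest.fixture(scope="session")
def study_comparison(study_config):
    """Baseline comparison of the study fixture (full pipeline)."""
    return evaluate_config(study_config)
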