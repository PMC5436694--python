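import pytest

from rrtcea import AnalysisSettings, Policy, default_parameters


@pytest.fixture(scope="session")
def params():
    """Bundled default parameter set (the study's input table)."""
    return default_parameters()


@pytest.fixture()
def settings():
    return AnalysisSettings()


@pytest.fixture()
def pd_settings():
    return AnalysisSettings(policy=Policy.PD_FIRST)


@pytest.fixture()
def hd_settings():
    return AnalysisSettings(policy=Policy.HD_FIRST)


@pytest.fixture()
def supportive_settings():
    return AnalysisSettings(policy=Policy.SUPPORTIVE)
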