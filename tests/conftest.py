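import pytest

from revdosim.fixtures import archetype_schedule, cnpa_like_profile, dtac_like_profile
from revdosim.pbpk import build_model, simulate
from revdosim.physiology import DosingSchedule, default_human


@pytest.fixture(scope="session")
def human():
    return default_human()


@pytest.fixture(scope="session")
def dtac_like():
    return dtac_like_profile()


@pytest.fixture(scope="session")
def cnpa_like():
    return cnpa_like_profile()


@pytest.fixture(scope="session")
def hourly24():
    """The display schedule: hourly 1 mg/kg oral bolus, 24 doses."""
    return DosingSchedule("oral", 1.0, 1.0, 24)


@pytest.fixture(scope="session")
def dtac_hourly_result(human, dtac_like):
    return simulate(build_model(dtac_like, human, archetype_schedule(dtac_like)))


@pytest.fixture(scope="session")
def cnpa_hourly_result(human, cnpa_like):
    return simulate(build_model(cnpa_like, human, archetype_schedule(cnpa_like)))
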