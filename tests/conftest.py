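import datetime

import pytest
from hypothesis import HealthCheck, settings

import thyrodose as td

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> td.PathwayParameterSet:
    return td.default_params()


@pytest.fixture
def dep() -> td.DepositionRecord:
    return td.DepositionRecord("L1", 15.0, 0.55, 10.0)


@pytest.fixture
def depmap(dep) -> dict:
    return {
        dep.location_id: dep,
        "L2": td.DepositionRecord("L2", 40.0, 0.55, 10.0),
    }


def make_person(
    person_id="P1",
    sex="F",
    residences=None,
    followup_day=td.FOLLOWUP_DAYS,
    end_reason="administrative",
    birth_date=datetime.date(1960, 1, 1),
):
    if residences is None:
        residences = (td.Residence("L1", 0, followup_day),)
    return td.PersonRecord(
        person_id=person_id,
        sex=sex,
        birth_date=birth_date,
        residences=tuple(residences),
        followup_end=td.EPOCH + datetime.timedelta(days=followup_day),
        end_reason=end_reason,
    )


@pytest.fixture
def person():
    return make_person()
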