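import pytest

from polypsurv import (
    ColonoscopyFindings,
    Histology,
    PatientProfile,
    PolypGroup,
)
from polypsurv.rules import default_ruleset


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture
def screening_patient():
    return PatientProfile(age_years=55)


@pytest.fixture
def normal_exam():
    return ColonoscopyFindings()


def group(histology=Histology.TUBULAR_ADENOMA, count=1, size=5, **kw):
    return PolypGroup(histology=histology, count=count, max_size_mm=size, **kw)


def exam(*groups, **kw):
    return ColonoscopyFindings(polyp_groups=tuple(groups), **kw)
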