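import numpy as np
import pytest

from pulmopk import (
    DosingRegimen,
    PopulationParameters,
    SamplingSchedule,
    SubjectCovariates,
)

#: ka (1/h) used by the test reference configuration; the absorption rate
#: has no published value, this stands in for the fixed value of the prior
#: plasma model (fast absorption relative to elimination).
KA_TEST = 2.0


@pytest.fixture(scope="session")
def ref_params() -> PopulationParameters:
    """The published final model with the package's ka choice."""
    return PopulationParameters(ka=KA_TEST)


@pytest.fixture
def standard_subject() -> SubjectCovariates:
    return SubjectCovariates("std", "male", 70.0, 1.75)


@pytest.fixture
def qd_regimen() -> DosingRegimen:
    """600 mg once daily for five days."""
    return DosingRegimen(dose_amount=600.0, interval=24.0, n_doses=5)


@pytest.fixture
def day5_schedule() -> SamplingSchedule:
    """Plasma at 2 and 4 h and BAL (ELF + AC) at 4 h after the day-5 dose."""
    return SamplingSchedule(((98.0, "plasma"), (100.0, "plasma"),
                             (100.0, "elf"), (100.0, "ac")))
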