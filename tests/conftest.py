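import numpy as np
import pytest

from odontosurvey.model import (
    DECIDUOUS_CROWN_CODES,
    DECIDUOUS_TEETH,
    Odontogram,
    PERMANENT_CROWN_CODES,
    PERMANENT_TEETH,
    TREATMENT_CODES,
    ToothRecord,
    dentition_of,
)
from odontosurvey.sync import CentralStore
from odontosurvey.synthetic import SimulationConfig, simulate_survey


def random_odontogram(rng: np.random.Generator, teeth=PERMANENT_TEETH) -> Odontogram:
    """A random valid odontogram drawing from the *full* code alphabets,
    including the non-component codes (sealant, bridge, trauma, ...)."""
    records = {}
    for tooth in teeth:
        alphabet = (
            PERMANENT_CROWN_CODES
            if dentition_of(tooth) == "permanent"
            else DECIDUOUS_CROWN_CODES
        )
        records[tooth] = ToothRecord(
            tooth=tooth,
            crown=alphabet[int(rng.integers(0, len(alphabet)))],
            treatment=TREATMENT_CODES[int(rng.integers(0, len(TREATMENT_CODES)))],
        )
    return Odontogram(teeth=tuple(teeth), records=records)


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey shared by read-only tests."""
    return simulate_survey(
        SimulationConfig(seed=11, n_schools=6, students_per_school=25)
    )


@pytest.fixture()
def small_store(small_survey):
    """A fresh central store holding the small survey (function-scoped:
    tests may mutate it)."""
    store = CentralStore()
    for batch in small_survey.batches:
        store.merge_batch(batch)
    return store


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
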