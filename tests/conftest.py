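from __future__ import annotations

import numpy as np
import pytest

from bcrecur import CodeSet, aalen_johansen


@pytest.fixture(scope="session")
def code_set() -> CodeSet:
    return CodeSet()


@pytest.fixture(scope="session")
def four_patient_estimate():
    """The worked 4-woman example: recurrence day 365, death day 730,
    censoring day 1095, recurrence day 1460."""
    times = [365, 730, 1095, 1460]
    causes = ["recurrence", "death", "censored", "recurrence"]
    return aalen_johansen(times, causes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
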