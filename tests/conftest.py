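import datetime as dt

import numpy as np
import pytest

from phenanom.anomaly import CumCurve
from phenanom.ringing import SPRING, CaptureRecord, SeasonCounts


def rec(ring_id: str, iso_date: str, age: str = "full_grown") -> CaptureRecord:
    from phenanom.ringing import AgeClass

    return CaptureRecord(
        ring_id=ring_id,
        capture_date=dt.date.fromisoformat(iso_date),
        age_class=AgeClass.parse(age),
        site="bukowo",
    )


@pytest.fixture
def toy_baseline() -> CumCurve:
    return CumCurve(owner="baseline", values=(50.0, 80.0, 100.0))


@pytest.fixture
def toy_curve() -> CumCurve:
    return CumCurve(owner=2012, values=(20.0, 60.0, 100.0))


@pytest.fixture
def spring_counts():
    def make(year: int, counts: list[int]) -> SeasonCounts:
        padded = list(counts) + [0] * (SPRING.n_days() - len(counts))
        return SeasonCounts(year=year, window=SPRING, counts=padded)

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
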