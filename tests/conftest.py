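import numpy as np
import pytest

from interosat import (
    AnalysisConfig,
    CohortTable,
    Condition,
    ParticipantRecord,
)


def make_record(pid="P001", condition=Condition.GLUCOSE, **overrides) -> ParticipantRecord:
    """A valid participant with plausible defaults, overridable per test."""
    fields = dict(
        id=pid,
        condition=condition,
        dif_score=17,
        bmi=24.0,
        exp_satiety_bt=50.0,
        exp_satiety_at=55.0,
        esc_bt=60.0,
        esc_at=65.0,
        fullness_15=48.0,
        hunger_t=(60.0, 40.0, 45.0, 55.0),
        glucose_t=(5.0, 7.0, 7.5, 6.0),
        sweetness=50.0,
        liking=60.0,
    )
    fields.update(overrides)
    return ParticipantRecord(**fields)


def random_record(rng: np.random.Generator, pid: str, condition: Condition) -> ParticipantRecord:
    """Randomised valid record for round-trip and compositional tests."""
    vas = lambda: float(np.round(rng.uniform(1.0, 99.0), 3))
    return make_record(
        pid=pid,
        condition=condition,
        dif_score=int(rng.integers(7, 36)),
        bmi=float(np.round(rng.uniform(18.0, 38.0), 3)),
        exp_satiety_bt=vas(),
        exp_satiety_at=vas(),
        esc_bt=vas(),
        esc_at=vas(),
        fullness_15=vas(),
        hunger_t=tuple(vas() for _ in range(4)),
        glucose_t=tuple(float(np.round(rng.uniform(3.5, 9.0), 3)) for _ in range(4)),
        sweetness=vas(),
        liking=vas(),
    )


def random_cohort(rng: np.random.Generator, n_per_arm: int = 6) -> CohortTable:
    records = []
    for i in range(2 * n_per_arm):
        cond = Condition.GLUCOSE if i % 2 == 0 else Condition.SUCRALOSE
        records.append(random_record(rng, f"P{i + 1:03d}", cond))
    return CohortTable(records=tuple(records), metadata={"source": "test"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def analysis_config():
    return AnalysisConfig()
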