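import numpy as np
import pytest

from scoregate import GoalSpec, PredictionTable
from scoregate.tuning import ThresholdEntry, ThresholdSet


@pytest.fixture
def f1_table() -> PredictionTable:
    """Five single-class records (Y, C(X), S(X)) exercising every rate branch."""
    return PredictionTable.from_records(
        [
            ("r1", "a", "a", 0.95),
            ("r2", "a", "a", 0.80),
            ("r3", "a", "b", 0.90),
            ("r4", "a", "a", 0.60),
            ("r5", "a", "b", 0.55),
        ]
    )


@pytest.fixture
def f2_table() -> PredictionTable:
    """Two-class table for the decision rule and application rates."""
    return PredictionTable.from_records(
        [
            ("q1", "a", "a", 0.95),
            ("q2", "a", "a", 0.80),
            ("q3", "a", "b", 0.55),
            ("q4", "b", "b", 0.45),
        ]
    )


@pytest.fixture
def f2_thresholds() -> ThresholdSet:
    """Hand-set thresholds {a: 0.90, b: 0.50} for the F2 table."""
    return ThresholdSet(
        goal=GoalSpec(goal_id="g3"),
        entries={
            "a": ThresholdEntry("a", 0.90, None),
            "b": ThresholdEntry("b", 0.50, None),
        },
    )


def make_random_table(rng: np.random.Generator, n_records: int, n_classes: int = 3) -> PredictionTable:
    """A small random prediction table with arbitrary (not simulator) structure."""
    labels = [f"c{i}" for i in range(n_classes)]
    records = []
    for i in range(n_records):
        true = labels[rng.integers(n_classes)]
        pred = labels[rng.integers(n_classes)]
        records.append((f"r{i}", true, pred, float(np.round(rng.random(), 3))))
    return PredictionTable.from_records(records, class_set=labels)
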