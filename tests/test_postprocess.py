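import numpy as np
import pytest

from scoregate import (
    ALWAYS_UNSURE,
    UNSURE_LABEL,
    GoalSpec,
    PredictionTable,
    ScoreRecord,
    apply,
    decide,
    evaluate,
    raw_rates,
    tune,
)
from scoregate.errors import DecisionError, EvaluationError
from scoregate.postprocess import application_rates
from scoregate.simulate import SimulationConfig, simulate
from scoregate.tuning import ThresholdEntry, ThresholdSet

from conftest import make_random_table


def _threshold_set(taus: dict, fallback: str = "always_unsure") -> ThresholdSet:
    return ThresholdSet(
        goal=GoalSpec("g3"),
        entries={c: ThresholdEntry(c, t, None) for c, t in taus.items()},
        fallback=fallback,
    )


# -- single-record decisions ----------------------------------------------

def test_decide_confirms_above_and_rejects_at_or_below(f2_thresholds):
    assert decide(ScoreRecord("q1", "a", "a", 0.95), f2_thresholds) == "a"
    assert decide(ScoreRecord("q2", "a", "a", 0.80), f2_thresholds) == UNSURE_LABEL
    # boundary: score exactly equal to the threshold is rejected
    assert decide(ScoreRecord("x", "b", "a", 0.90), f2_thresholds) == UNSURE_LABEL


def test_decide_always_unsure_sentinel_and_fallbacks():
    ts = _threshold_set({"a": ALWAYS_UNSURE})
    assert decide(ScoreRecord("x", "a", "a", 0.99), ts) == UNSURE_LABEL
    # predicted class missing from the set, per policy:
    assert decide(ScoreRecord("x", "a", "z", 0.99), ts) == UNSURE_LABEL
    ts_accept = _threshold_set({"a": 0.5}, fallback="accept")
    assert decide(ScoreRecord("x", "a", "z", 0.01), ts_accept) == "z"
    ts_error = _threshold_set({"a": 0.5}, fallback="error")
    with pytest.raises(DecisionError, match="'z'"):
        decide(ScoreRecord("x", "a", "z", 0.01), ts_error)


def test_decide_never_consults_ground_truth(f2_thresholds):
    for truth in ("a", "b", "zzz"):
        assert decide(ScoreRecord("x", truth, "a", 0.95), f2_thresholds) == "a"


# -- table-wise application -----------------------------------------------

def test_apply_f2(f2_table, f2_thresholds):
    post = apply(f2_table, f2_thresholds)
    assert post.frame["decision"].tolist() == ["a", UNSURE_LABEL, "b", UNSURE_LABEL]
    assert post.frame["item_id"].tolist() == ["q1", "q2", "q3", "q4"]  # order kept


def test_apply_matches_elementwise_decide(f2_table):
    rng = np.random.default_rng(6)
    table = make_random_table(rng, 100, n_classes=3)
    ts = _threshold_set({c: float(t) for c, t in zip(table.class_set, (0.2, 0.5, 0.9))})
    post = apply(table, ts)
    expected = [decide(r, ts) for r in table.records()]
    assert post.frame["decision"].tolist() == expected


def test_apply_zero_thresholds_is_identity(f2_table):
    post = apply(f2_table, _threshold_set({"a": 0.0, "b": 0.0}))
    assert (post.frame["decision"] == post.frame["predicted_class"]).all()


def test_apply_all_always_unsure_rejects_everything(f2_table):
    post = apply(f2_table, _threshold_set({"a": ALWAYS_UNSURE, "b": ALWAYS_UNSURE}))
    assert (post.frame["decision"] == UNSURE_LABEL).all()


def test_apply_missing_class_error_policy(f2_table):
    with pytest.raises(DecisionError, match="'b'"):
        apply(f2_table, _threshold_set({"a": 0.5}, fallback="error"))


# -- application rates and evaluation -------------------------------------

def test_application_rates_f2(f2_table, f2_thresholds):
    post = apply(f2_table, f2_thresholds)
    rates_a, accuracy_a = application_rates(post, "a")
    assert (rates_a.cc, rates_a.mc, rates_a.uc) == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert accuracy_a == 1.0
    # class b: the only kept b-prediction (q3) has ground truth a
    _, accuracy_b = application_rates(post, "b")
    assert accuracy_b == 0.0


def test_application_with_zero_thresholds_equals_raw(f2_table):
    post = apply(f2_table, _threshold_set({"a": 0.0, "b": 0.0}))
    for label in ("a", "b"):
        rates, accuracy = application_rates(post, label)
        raw = raw_rates(f2_table, label)
        assert (rates.cc, rates.mc, rates.uc) == (raw.cc, raw.mc, 0.0)
        kept = f2_table.frame[f2_table.frame["predicted_class"] == label]
        assert accuracy == (kept["true_class"] == label).mean()


def test_application_total_rejection_gives_undefined_accuracy(f2_table):
    post = apply(f2_table, _threshold_set({"a": ALWAYS_UNSURE, "b": ALWAYS_UNSURE}))
    for label in ("a", "b"):
        rates, accuracy = application_rates(post, label)
        assert rates.uc == 1.0
        assert accuracy is None
    result = evaluate(post)
    assert result.n_undefined_accuracy == 2
    assert np.isnan(result.aggregate["accuracy"][0])


def test_evaluate_perfect_classifier(f2_thresholds):
    table = PredictionTable.from_records(
        [("r1", "a", "a", 0.99), ("r2", "b", "b", 0.99)]
    )
    result = evaluate(apply(table, f2_thresholds))
    assert (result.per_class["cc"] == 1.0).all()
    assert (result.per_class["mc"] == 0.0).all()
    assert (result.per_class["uc"] == 0.0).all()


def test_evaluate_conservation_per_class():
    rng = np.random.default_rng(12)
    table = make_random_table(rng, 300, n_classes=5)
    thresholds = tune(table, GoalSpec("g2"))
    result = evaluate(apply(table, thresholds))
    sums = result.per_class[["cc", "mc", "uc"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_evaluate_empty_table_errors():
    post = apply(
        PredictionTable.from_records([], class_set=["a", "b"]),
        _threshold_set({"a": 0.5, "b": 0.5}),
    )
    with pytest.raises(EvaluationError):
        evaluate(post)


# -- invariants ------------------------------------------------------------

def test_shuffling_ground_truth_never_changes_decisions():
    rng = np.random.default_rng(9)
    table = make_random_table(rng, 150, n_classes=4)
    ts = _threshold_set({c: 0.4 for c in table.class_set})
    baseline = apply(table, ts).frame["decision"].tolist()
    shuffled_frame = table.frame.copy()
    shuffled_frame["true_class"] = rng.permutation(shuffled_frame["true_class"].to_numpy())
    shuffled = PredictionTable(frame=shuffled_frame, class_set=table.class_set)
    assert apply(shuffled, ts).frame["decision"].tolist() == baseline


def test_raising_one_threshold_is_anti_monotone():
    """Raising a single class's threshold never increases the number of wrong
    kept predictions of that class, never increases any class's mc', and
    never decreases the total UNSURE count."""
    rng = np.random.default_rng(21)
    table = make_random_table(rng, 250, n_classes=3)
    target = table.class_set[0]
    taus = {c: 0.3 for c in table.class_set}
    prev_unsure = -1
    prev_wrong_kept = len(table)
    prev_mc = {c: 1.0 for c in table.class_set}
    for tau in (0.3, 0.5, 0.7, 0.9, 1.0):
        taus[target] = tau
        post = apply(table, _threshold_set(dict(taus)))
        frame = post.frame
        n_unsure = int((frame["decision"] == UNSURE_LABEL).sum())
        kept = frame[frame["decision"] == target]
        wrong_kept = int((kept["true_class"] != target).sum())
        assert n_unsure >= prev_unsure
        assert wrong_kept <= prev_wrong_kept
        for label in table.class_set:
            mc = application_rates(post, label)[0].mc
            assert mc <= prev_mc[label] + 1e-12
            prev_mc[label] = mc
        prev_unsure, prev_wrong_kept = n_unsure, wrong_kept


def test_cross_table_risk_ordering_over_seeds():
    """Tune on one simulated table, test on an independent one: the mean
    misclassification rate orders g3 <= g2 <= raw in nearly every seed."""
    violations_g3_g2 = 0
    violations_g2_raw = 0
    for seed in range(20):
        labels = [f"s{i}" for i in range(10)]
        probs = dict(zip(labels, np.linspace(0.5, 0.95, 10)))
        base = dict(class_labels=labels, n_per_class=200, correctness_prob=probs)
        tune_table = simulate(SimulationConfig(seed=1000 + seed, **base))
        test_table = simulate(SimulationConfig(seed=2000 + seed, **base))
        mc = {}
        for goal_id in ("g2", "g3"):
            thresholds = tune(tune_table, GoalSpec(goal_id))
            result = evaluate(apply(test_table, thresholds))
            mc[goal_id] = result.per_class["mc"].mean()
        raw_mc = result.per_class["raw_mc"].mean()
        if mc["g3"] > mc["g2"] + 1e-12:
            violations_g3_g2 += 1
        if mc["g2"] > raw_mc + 1e-12:
            violations_g2_raw += 1
    assert violations_g3_g2 <= 2
    assert violations_g2_raw <= 2
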