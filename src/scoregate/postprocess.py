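"""Applying tuned thresholds to predictions: the three-outcome decision rule.

Each record is judged against its *predicted* class's threshold τ_j: the
prediction is confirmed when the top score is strictly above τ_j and
rerouted to the reserved UNSURE label otherwise (including when τ_j is the
ALWAYS_UNSURE sentinel).  Ground truth is never consulted by the rule —
only by the subsequent evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DecisionError, EvaluationError
from .io import ALWAYS_UNSURE, UNSURE_LABEL, PredictionTable, ScoreRecord
from .rates import application_rates, raw_rates, summarize
from .tuning import ThresholdSet

_FALLBACKS = ("always_unsure", "accept", "error")


@dataclass
class PostProcessedTable:
    """Records after the decision rule, each with a final decision.

    ``frame`` extends the prediction columns with ``decision`` (a class
    label or UNSURE) and ``applied_tau`` (the predicted class's threshold,
    or a sentinel string).  Record order is preserved from the input.
    """

    frame: pd.DataFrame
    class_set: tuple[str, ...]
    threshold_provenance: dict = field(default_factory=dict)


def decide(record: ScoreRecord, thresholds: ThresholdSet) -> str:
    """Decision for a single record: its predicted class, or UNSURE."""
    entry = thresholds.entries.get(record.predicted_class)
    if entry is None:
        policy = thresholds.fallback
        if policy == "error":
            raise DecisionError(f"no threshold for predicted class {record.predicted_class!r}")
        if policy == "accept":
            return record.predicted_class
        return UNSURE_LABEL
    if entry.tau == ALWAYS_UNSURE:
        return UNSURE_LABEL
    return record.predicted_class if record.top_score > entry.tau else UNSURE_LABEL


def apply(table: PredictionTable, thresholds: ThresholdSet) -> PostProcessedTable:
    """Apply the decision rule record-wise to a whole prediction table."""
    if thresholds.fallback not in _FALLBACKS:
        raise DecisionError(f"unknown fallback policy {thresholds.fallback!r}")
    pred = table.frame["predicted_class"].to_numpy()
    score = table.frame["top_score"].to_numpy(dtype=float)
    missing = sorted(set(pred) - set(thresholds.entries))
    if missing and thresholds.fallback == "error":
        raise DecisionError(f"no threshold for predicted class {missing[0]!r}")
    # Numeric view of the thresholds: ALWAYS_UNSURE and the always_unsure
    # fallback reject everything (tau = +inf); the accept fallback keeps
    # everything (tau = -inf).
    missing_tau = -np.inf if thresholds.fallback == "accept" else np.inf
    tau_num = {
        label: (np.inf if e.tau == ALWAYS_UNSURE else float(e.tau))
        for label, e in thresholds.entries.items()
    }
    tau = np.array([tau_num.get(p, missing_tau) for p in pred])
    decision = np.where(score > tau, pred, UNSURE_LABEL)
    applied = [
        thresholds.entries[p].tau if p in thresholds.entries
        else ("accept" if thresholds.fallback == "accept" else ALWAYS_UNSURE)
        for p in pred
    ]
    frame = table.frame.copy()
    frame["decision"] = decision
    frame["applied_tau"] = applied
    return PostProcessedTable(
        frame=frame,
        class_set=table.class_set,
        threshold_provenance=dict(thresholds.provenance),
    )


@dataclass
class EvaluationResult:
    """Per-class application rates and accuracies, with aggregate rows.

    ``per_class`` is indexed by class label with columns ``cc, mc, uc,
    accuracy`` (post-decision) and ``raw_cc, raw_mc, raw_accuracy``
    (no-thresholding baseline).  ``aggregate`` maps each column to its
    unweighted (mean, sample sd) across classes; undefined accuracies are
    excluded, with the exclusion count in ``n_undefined_accuracy``.
    """

    per_class: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    n_undefined_accuracy: int


def evaluate(post: PostProcessedTable) -> EvaluationResult:
    """Per-class rates after post-processing, next to the raw baseline."""
    if len(post.frame) == 0:
        raise EvaluationError("cannot evaluate an empty table")
    observed = [c for c in post.class_set if (post.frame["true_class"] == c).any()]
    if not observed:
        raise EvaluationError("no ground-truth labels present")
    baseline = PredictionTable(
        frame=post.frame[["item_id", "true_class", "predicted_class", "top_score"]].copy(),
        class_set=post.class_set,
    )
    rows = {}
    for label in observed:
        rates, accuracy = application_rates(post, label)
        raw = raw_rates(baseline, label)
        kept_raw = baseline.frame[baseline.frame["predicted_class"] == label]
        raw_accuracy = (
            float((kept_raw["true_class"] == label).mean()) if len(kept_raw) else None
        )
        rows[label] = {
            "cc": rates.cc, "mc": rates.mc, "uc": rates.uc,
            "accuracy": accuracy,
            "raw_cc": raw.cc, "raw_mc": raw.mc, "raw_accuracy": raw_accuracy,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    per_class.index.name = "class"
    aggregate = {}
    n_undef = int(per_class["accuracy"].isna().sum())
    for col in per_class.columns:
        vals = per_class[col].dropna().to_numpy()
        aggregate[col] = summarize(vals) if vals.size else (float("nan"), float("nan"))
    return EvaluationResult(per_class=per_class, aggregate=aggregate, n_undefined_accuracy=n_undef)
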