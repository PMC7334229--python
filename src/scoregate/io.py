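"""Reading, validating and writing prediction tables and threshold files.

A prediction table holds one row per classified item: an opaque identifier,
the ground-truth class label, the predicted class label and the top softmax
score (optionally the full score vector over all classes).  Two text
dialects are supported:

``long``
    columns ``item_id, true_class, predicted_class, score`` — the canonical
    form; the method only needs the top score.
``wide``
    columns ``item_id, true_class`` followed by one score column per class;
    the predicted class and top score are derived as the argmax column and
    its value.

Scores are stored internally on the [0, 1] scale.  Files using a 0-100
display scale (any value > 1 present) are detected on read and rescaled,
with a logged notice.

Threshold sets are persisted as versioned JSON (see
:func:`write_thresholds`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Reserved label for rejected predictions; never a valid class name.
UNSURE_LABEL = "UNSURE"

#: Sentinel threshold meaning "reject every prediction of this class".
ALWAYS_UNSURE = "ALWAYS_UNSURE"

THRESHOLD_FORMAT_VERSION = 1

_SCORE_SUM_TOL = 1e-6
_TOP_SCORE_TOL = 1e-9

_LONG_COLUMNS = ["item_id", "true_class", "predicted_class", "score"]
_FLOAT_FORMAT = "%.12g"  # >= 9 significant digits for round-trip fidelity


class ScoreRecord(NamedTuple):
    """One classifier output: (id, ground truth Y, prediction C(X), top score S(X))."""

    item_id: str
    true_class: str
    predicted_class: str
    top_score: float
    score_vector: tuple[float, ...] | None = None


@dataclass
class PredictionTable:
    """An ordered collection of score records plus the declared class set.

    ``frame`` has columns ``item_id, true_class, predicted_class, top_score``;
    ``scores``, when present, has one column per class (in ``class_set``
    order) aligned row-for-row with ``frame``.
    """

    frame: pd.DataFrame
    class_set: tuple[str, ...]
    scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Sequence[ScoreRecord | tuple],
        class_set: Sequence[str] | None = None,
    ) -> "PredictionTable":
        """Build a table from (item_id, Y, C(X), S(X)[, vector]) tuples.

        When ``class_set`` is omitted it is the sorted union of labels
        referenced by the records.
        """
        recs = [ScoreRecord(*r) for r in records]
        frame = pd.DataFrame(
            {
                "item_id": [r.item_id for r in recs],
                "true_class": [r.true_class for r in recs],
                "predicted_class": [r.predicted_class for r in recs],
                "top_score": [float(r.top_score) for r in recs],
            }
        )
        if class_set is None:
            class_set = sorted(set(frame["true_class"]) | set(frame["predicted_class"]))
        scores = None
        if recs and recs[0].score_vector is not None:
            scores = pd.DataFrame(
                [r.score_vector for r in recs], columns=list(class_set)
            )
        return cls(frame=frame, class_set=tuple(class_set), scores=scores)

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any violated table invariant."""
        frame = self.frame
        missing = [c for c in ("item_id", "true_class", "predicted_class", "top_score") if c not in frame.columns]
        if missing:
            raise FormatError(f"prediction frame missing column(s): {', '.join(missing)}")
        dup = frame["item_id"][frame["item_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate item_id: {dup.iloc[0]!r}")
        labels = set(frame["true_class"]) | set(frame["predicted_class"])
        if UNSURE_LABEL in labels or UNSURE_LABEL in self.class_set:
            raise ValidationError(f"{UNSURE_LABEL!r} is a reserved label and cannot be a class name")
        declared = set(self.class_set)
        undeclared = labels - declared
        if undeclared:
            raise ValidationError(f"labels outside the declared class set: {sorted(undeclared)}")
        s = frame["top_score"].to_numpy(dtype=float)
        bad = np.flatnonzero((s < 0.0) | (s > 1.0))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(f"score {s[i]} outside [0, 1] at row {i}")
        if self.scores is not None:
            if list(self.scores.columns) != list(self.class_set):
                raise ValidationError("score-vector columns must match class_set order")
            vec = self.scores.to_numpy(dtype=float)
            if len(vec) != len(frame):
                raise ValidationError("score vectors not aligned with records")
            sums = vec.sum(axis=1)
            off = np.flatnonzero(np.abs(sums - 1.0) > _SCORE_SUM_TOL)
            if off.size:
                i = int(off[0])
                raise ValidationError(f"score vector at row {i} sums to {sums[i]}, not 1")
            argmax = vec.argmax(axis=1)
            pred_idx = np.array([self.class_set.index(c) for c in frame["predicted_class"]])
            if not np.all(vec[np.arange(len(vec)), pred_idx] >= vec[np.arange(len(vec)), argmax] - _TOP_SCORE_TOL):
                raise ValidationError("predicted_class does not attain the maximum score")
            if np.max(np.abs(vec[np.arange(len(vec)), pred_idx] - s)) > _TOP_SCORE_TOL:
                raise ValidationError("top_score does not equal the score vector maximum")

    # -- conveniences -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        """Ground-truth record count per declared class (0 for unobserved)."""
        counts = self.frame["true_class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in self.class_set}

    def records(self) -> list[ScoreRecord]:
        vecs = self.scores.to_numpy().tolist() if self.scores is not None else None
        out = []
        for i, row in enumerate(self.frame.itertuples(index=False)):
            vec = tuple(vecs[i]) if vecs is not None else None
            out.append(ScoreRecord(row.item_id, row.true_class, row.predicted_class, float(row.top_score), vec))
        return out

    def fingerprint(self) -> dict:
        """Content hash plus record counts, for threshold provenance."""
        lines = self.frame.apply(
            lambda r: f"{r.item_id}\t{r.true_class}\t{r.predicted_class}\t{r.top_score:.12g}", axis=1
        )
        digest = hashlib.sha256("\n".join(lines).encode("utf-8")).hexdigest()
        return {
            "n_records": int(len(self.frame)),
            "class_counts": self.class_counts(),
            "sha256": digest,
        }


# -- prediction-table I/O ------------------------------------------------


def _rescale_if_percent(values: np.ndarray, what: str) -> np.ndarray:
    if np.nanmax(values, initial=0.0) > 1.0:
        logger.info("%s uses a 0-100 scale; dividing by 100", what)
        return values / 100.0
    return values


def read_predictions(path, dialect: str = "long") -> PredictionTable:
    """Read a delimited prediction table (comma or tab, sniffed).

    Parameters
    ----------
    path
        Text file with a header row.
    dialect
        ``"long"`` or ``"wide"`` (see module docstring).
    """
    if dialect not in ("long", "wide"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        try:
            scores = df["score"].to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric score: {exc}") from exc
        scores = _rescale_if_percent(scores, f"{path}: score column")
        frame = pd.DataFrame(
            {
                "item_id": df["item_id"],
                "true_class": df["true_class"],
                "predicted_class": df["predicted_class"],
                "top_score": scores,
            }
        )
        class_set = sorted(set(frame["true_class"]) | set(frame["predicted_class"]))
        return PredictionTable(frame=frame, class_set=tuple(class_set))

    required = ["item_id", "true_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    class_cols = [c for c in df.columns if c not in required]
    if not class_cols:
        raise FormatError("wide dialect requires one score column per class")
    try:
        vec = df[class_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric score: {exc}") from exc
    vec = _rescale_if_percent(vec, f"{path}: score columns")
    argmax = vec.argmax(axis=1)
    frame = pd.DataFrame(
        {
            "item_id": df["item_id"],
            "true_class": df["true_class"],
            "predicted_class": [class_cols[i] for i in argmax],
            "top_score": vec[np.arange(len(vec)), argmax],
        }
    )
    class_set = list(class_cols)
    for label in sorted(set(frame["true_class"]) - set(class_cols)):
        class_set.append(label)
        vec = np.hstack([vec, np.zeros((len(vec), 1))])
    scores = pd.DataFrame(vec, columns=class_set)
    return PredictionTable(frame=frame, class_set=tuple(class_set), scores=scores)


def write_predictions(table: PredictionTable, path, dialect: str = "long") -> None:
    """Write a prediction table; ``read_predictions`` round-trips it exactly."""
    if dialect == "long":
        out = table.frame.rename(columns={"top_score": "score"})
        out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    elif dialect == "wide":
        if table.scores is None:
            raise FormatError("wide dialect requires full score vectors")
        out = pd.concat(
            [table.frame[["item_id", "true_class"]].reset_index(drop=True),
             table.scores.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# -- threshold I/O -------------------------------------------------------


def write_thresholds(thresholds, path) -> None:
    """Serialize a :class:`~scoregate.tuning.ThresholdSet` to versioned JSON."""
    payload = {
        "format_version": THRESHOLD_FORMAT_VERSION,
        "goal": thresholds.goal.to_dict(),
        "fallback": thresholds.fallback,
        "entries": [
            {
                "class": label,
                "tau": entry.tau,
                "tuning_cc": entry.rates.cc if entry.rates else None,
                "tuning_mc": entry.rates.mc if entry.rates else None,
                "tuning_uc": entry.rates.uc if entry.rates else None,
                "n_truth": entry.rates.n_truth if entry.rates else 0,
                "feasible": entry.feasible,
            }
            for label, entry in thresholds.entries.items()
        ],
        "provenance": thresholds.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_thresholds(path):
    """Parse a threshold JSON file back into a ThresholdSet."""
    from .rates import ClassRates  # local import: io has no compile-time deps on sibling modules
    from .tuning import GoalSpec, ThresholdEntry, ThresholdSet

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if "goal" not in payload or "entries" not in payload:
        raise FormatError("threshold file missing 'goal' or 'entries'")
    goal = GoalSpec.from_dict(payload["goal"])
    entries = {}
    for raw in payload["entries"]:
        label = raw["class"]
        tau = raw["tau"]
        if tau != ALWAYS_UNSURE:
            tau = float(tau)
            if not (0.0 <= tau <= 1.0) or math.isnan(tau):
                raise ValidationError(f"tau {tau} for class {label!r} outside [0, 1]")
        rates = None
        if raw.get("tuning_cc") is not None:
            cc, mc, uc = (float(raw[k]) for k in ("tuning_cc", "tuning_mc", "tuning_uc"))
            rates = ClassRates(
                class_label=label,
                tau=tau if tau != ALWAYS_UNSURE else None,
                cc=cc, mc=mc, uc=uc, cov=cc + mc,
                n_truth=int(raw.get("n_truth", 0)),
            )
        entries[label] = ThresholdEntry(
            class_label=label, tau=tau, rates=rates, feasible=bool(raw.get("feasible", True))
        )
    return ThresholdSet(
        goal=goal,
        entries=entries,
        fallback=payload.get("fallback", "always_unsure"),
        provenance=payload.get("provenance", {}),
    )
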