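"""Per-class classification rates with and without confidence thresholding.

For a class *i* with threshold τ, over the records whose ground truth is
*i*:

* ``CC_i(τ)`` — fraction predicted as *i* with score strictly above τ
  (correct and kept),
* ``MC_i(τ)`` — fraction predicted as another class with score strictly
  above τ (wrong and kept),
* ``UC_i(τ)`` — fraction with score ≤ τ (rejected as unsure), defined as
  the complement so that ``CC + MC + UC = 1`` holds exactly for every τ,
* ``COV_i(τ) = CC_i(τ) + MC_i(τ)`` — coverage, the fraction of items for
  which a classification is issued at all.

The tuning phase indexes rates by the *ground-truth* class; the
application phase (after the decision rule reroutes low-score predictions
to UNSURE) indexes each record by its *predicted* class's threshold.  The
two are deliberately distinct operations: :func:`rates_at_threshold` vs
:func:`application_rates`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EvaluationError, QuantileUndefinedError, UndefinedRateError, ScoregateError
from .io import UNSURE_LABEL, PredictionTable


@dataclass(frozen=True)
class ClassRates:
    """Rate triple (cc, mc, uc) plus coverage for one class at one threshold.

    ``tau`` is ``None`` for raw (threshold-free) rates.  ``n_truth`` is the
    number of ground-truth records the rates were computed over.
    """

    class_label: str
    tau: float | None
    cc: float
    mc: float
    uc: float
    cov: float
    n_truth: int


@dataclass(frozen=True)
class RateCurve:
    """Step functions CC_i(τ), MC_i(τ), UC_i(τ) evaluated at their breakpoints.

    Breakpoints are {0} ∪ {distinct scores of the class's ground-truth
    records} ∪ {1}, strictly increasing.  Because the rates are step
    functions of τ that only change at observed scores, every achievable
    (cc, mc, uc) operating point over τ ∈ [0, 1] appears at some
    breakpoint.
    """

    class_label: str
    breakpoints: tuple[float, ...]
    rates: tuple[ClassRates, ...]

    @property
    def cc(self) -> np.ndarray:
        return np.array([r.cc for r in self.rates])

    @property
    def mc(self) -> np.ndarray:
        return np.array([r.mc for r in self.rates])

    @property
    def uc(self) -> np.ndarray:
        return np.array([r.uc for r in self.rates])


def _truth_subset(table: PredictionTable, class_label: str) -> pd.DataFrame:
    subset = table.frame[table.frame["true_class"] == class_label]
    if subset.empty:
        raise UndefinedRateError(f"no ground-truth records for class {class_label!r}")
    return subset


def raw_rates(table: PredictionTable, class_label: str) -> ClassRates:
    """Threshold-free correct/misclassification rates for one class."""
    subset = _truth_subset(table, class_label)
    n = len(subset)
    n_cc = int((subset["predicted_class"] == class_label).sum())
    return ClassRates(
        class_label=class_label, tau=None,
        cc=n_cc / n, mc=(n - n_cc) / n, uc=0.0, cov=1.0, n_truth=n,
    )


def rates_at_threshold(table: PredictionTable, class_label: str, tau: float) -> ClassRates:
    """Tuning-phase rates for one class at threshold ``tau``.

    A record is kept when its score is strictly above ``tau``; records at
    or below the threshold count as unsure.
    """
    if not (0.0 <= tau <= 1.0):
        raise ScoregateError(f"tau {tau} outside [0, 1]")
    subset = _truth_subset(table, class_label)
    n = len(subset)
    kept = subset["top_score"].to_numpy() > tau
    correct = (subset["predicted_class"] == class_label).to_numpy()
    n_cc = int((kept & correct).sum())
    n_mc = int((kept & ~correct).sum())
    n_uc = n - n_cc - n_mc
    return ClassRates(
        class_label=class_label, tau=float(tau),
        cc=n_cc / n, mc=n_mc / n, uc=n_uc / n, cov=(n_cc + n_mc) / n, n_truth=n,
    )


def rate_curve(table: PredictionTable, class_label: str) -> RateCurve:
    """Evaluate the class's rate step-functions at all of their breakpoints."""
    subset = _truth_subset(table, class_label)
    points = np.unique(np.concatenate(([0.0], subset["top_score"].to_numpy(dtype=float), [1.0])))
    rates = tuple(rates_at_threshold(table, class_label, float(t)) for t in points)
    return RateCurve(class_label=class_label, breakpoints=tuple(float(t) for t in points), rates=rates)


def application_rates(post, class_label: str) -> tuple[ClassRates, float | None]:
    """Post-decision rates for one class, plus that class's accuracy.

    Over the records whose ground truth is ``class_label``: cc′ is the
    fraction whose final decision equals the class, mc′ the fraction
    rerouted to a *different* class (kept because the score cleared the
    predicted class's threshold), uc′ the fraction decided UNSURE.

    Accuracy is the precision of kept predictions of ``class_label`` over
    the whole table: #(decision = class AND truth = class) / #(decision =
    class).  It is ``None`` when no prediction of the class was kept.
    """
    frame = post.frame
    subset = frame[frame["true_class"] == class_label]
    if subset.empty:
        raise UndefinedRateError(f"no ground-truth records for class {class_label!r}")
    n = len(subset)
    n_cc = int((subset["decision"] == class_label).sum())
    n_uc = int((subset["decision"] == UNSURE_LABEL).sum())
    n_mc = n - n_cc - n_uc
    kept_as_class = frame[frame["decision"] == class_label]
    accuracy = None
    if len(kept_as_class):
        accuracy = float((kept_as_class["true_class"] == class_label).mean())
    rates = ClassRates(
        class_label=class_label, tau=None,
        cc=n_cc / n, mc=n_mc / n, uc=n_uc / n, cov=(n_cc + n_mc) / n, n_truth=n,
    )
    return rates, accuracy


def correct_score_quantile(
    table: PredictionTable, class_label: str, q: float = 0.05
) -> tuple[float, float]:
    """Low quantile of correct-classification scores, and the misclassified mass above it.

    Returns ``(sq, mis_share)`` where ``sq`` is the smallest observed
    correct-classification score with at least a fraction ``q`` of correct
    scores at or below it (so at least ``1 - q`` of correct scores lie at
    or above ``sq``), and ``mis_share`` is the fraction of the class's
    misclassified records whose score is ≥ ``sq``.  Values are on the
    [0, 1] scale; reports multiply by 100 for display.
    """
    if not (0.0 < q < 1.0):
        raise ScoregateError(f"q {q} outside (0, 1)")
    subset = _truth_subset(table, class_label)
    correct_mask = subset["predicted_class"] == class_label
    correct = subset.loc[correct_mask, "top_score"].to_numpy(dtype=float)
    if correct.size == 0:
        raise QuantileUndefinedError(f"no correct classifications for class {class_label!r}")
    sq = float(np.quantile(correct, q, method="inverted_cdf"))
    wrong = subset.loc[~correct_mask, "top_score"].to_numpy(dtype=float)
    mis_share = float((wrong >= sq).mean()) if wrong.size else 0.0
    return sq, mis_share


def summarize(per_class: list[float] | np.ndarray) -> tuple[float, float]:
    """Unweighted mean and sample (n−1) standard deviation across classes."""
    values = np.asarray(per_class, dtype=float)
    if values.size == 0:
        raise ScoregateError("cannot summarize an empty list")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd
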