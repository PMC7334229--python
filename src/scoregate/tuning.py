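"""Per-class confidence-threshold selection on a tuning dataset.

Given a scored tuning set with ground truth, each class gets one threshold
τ_i chosen from its rate curve's breakpoints under a lexicographic goal:

* ``g1`` — maximize CC, then minimize MC (keep the best correct-
  classification rate while reducing misclassification);
* ``g2`` — restrict to thresholds with MC strictly below a bound
  (default 5%), then maximize CC; if no threshold meets the bound, fall
  back to the MC-minimizing thresholds and flag the class infeasible;
* ``g3`` — minimize MC, then maximize CC (lowest possible risk);
* ``custom`` — any ordered list of (quantity, direction, optional bound)
  objectives with the same bound-fallback semantics.

Remaining ties are broken toward the smallest τ by default (equal tuning
rates, larger future coverage margin); ``largest_tau`` is available.

Classes declared in the table's class set but never observed in the
ground truth receive the ``ALWAYS_UNSURE`` sentinel: with no data there is
no risk estimate, and rejecting every prediction of that class is the
conservative action.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SelectionError, TuningError
from .io import ALWAYS_UNSURE, PredictionTable
from .rates import ClassRates, RateCurve, rate_curve

logger = logging.getLogger(__name__)

_QUANTITIES = ("cc", "mc", "uc")
_DIRECTIONS = ("max", "min")
_TIE_BREAKS = ("smallest_tau", "largest_tau")
_GOALS = ("g1", "g2", "g3", "custom")

DEFAULT_MC_BOUND = 0.05


@dataclass(frozen=True)
class Objective:
    """One lexicographic stage: optimize ``quantity`` in ``direction``.

    With a ``bound``, the stage filters instead of optimizing: ``min``
    keeps breakpoints with quantity strictly below the bound, ``max``
    strictly above.  An empty filter falls back to optimizing and marks
    the selection infeasible.
    """

    quantity: str
    direction: str
    bound: float | None = None

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITIES:
            raise ConfigurationError(f"unknown quantity {self.quantity!r}")
        if self.direction not in _DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class GoalSpec:
    """Which lexicographic objective to tune under, plus its parameters."""

    goal_id: str = "g3"
    mc_bound: float = DEFAULT_MC_BOUND
    objectives: tuple[Objective, ...] = ()
    tie_break: str = "smallest_tau"

    def __post_init__(self) -> None:
        if self.goal_id not in _GOALS:
            raise ConfigurationError(f"unknown goal {self.goal_id!r}")
        if self.tie_break not in _TIE_BREAKS:
            raise ConfigurationError(f"unknown tie_break {self.tie_break!r}")
        if self.goal_id == "g2" and not (0.0 < self.mc_bound <= 1.0):
            raise ConfigurationError(f"g2 requires mc_bound in (0, 1], got {self.mc_bound}")
        if self.goal_id == "custom" and not self.objectives:
            raise ConfigurationError("custom goal requires at least one objective")

    def resolved_objectives(self) -> tuple[Objective, ...]:
        """The lexicographic stages this goal expands to."""
        if self.goal_id == "g1":
            return (Objective("cc", "max"), Objective("mc", "min"))
        if self.goal_id == "g2":
            return (Objective("mc", "min", bound=self.mc_bound), Objective("cc", "max"))
        if self.goal_id == "g3":
            return (Objective("mc", "min"), Objective("cc", "max"))
        return self.objectives

    def to_dict(self) -> dict:
        d: dict = {"goal_id": self.goal_id, "tie_break": self.tie_break}
        if self.goal_id == "g2":
            d["mc_bound"] = self.mc_bound
        if self.goal_id == "custom":
            d["objectives"] = [
                {"quantity": o.quantity, "direction": o.direction, "bound": o.bound}
                for o in self.objectives
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GoalSpec":
        objectives = tuple(
            Objective(o["quantity"], o["direction"], o.get("bound"))
            for o in d.get("objectives", [])
        )
        return cls(
            goal_id=d.get("goal_id", "g3"),
            mc_bound=float(d.get("mc_bound", DEFAULT_MC_BOUND)),
            objectives=objectives,
            tie_break=d.get("tie_break", "smallest_tau"),
        )


@dataclass(frozen=True)
class ThresholdEntry:
    """Selected threshold for one class with its tuning-set rates."""

    class_label: str
    tau: float | str  # float in [0, 1] or the ALWAYS_UNSURE sentinel
    rates: ClassRates | None
    feasible: bool = True


@dataclass
class ThresholdSet:
    """The tuned map class → τ_i, with goal, fallback policy and provenance."""

    goal: GoalSpec
    entries: dict[str, ThresholdEntry]
    fallback: str = "always_unsure"
    provenance: dict = field(default_factory=dict)

    def tau(self, class_label: str) -> float | str | None:
        entry = self.entries.get(class_label)
        return None if entry is None else entry.tau


def select_threshold(curve: RateCurve, goal: GoalSpec) -> tuple[float, ClassRates, bool]:
    """Pick the goal-optimal threshold from a class's rate-curve breakpoints.

    Returns ``(tau, tuning_rates_at_tau, feasible_flag)``; the flag is
    False when a bounded stage's filter was empty and the fallback
    (optimize that quantity instead) was taken.
    """
    if not curve.breakpoints:
        raise SelectionError(f"degenerate rate curve for class {curve.class_label!r}")
    values = {"cc": curve.cc, "mc": curve.mc, "uc": curve.uc}
    idx = np.arange(len(curve.breakpoints))
    feasible = True
    for obj in goal.resolved_objectives():
        q = values[obj.quantity][idx]
        if obj.bound is not None:
            keep = q < obj.bound if obj.direction == "min" else q > obj.bound
            if keep.any():
                idx = idx[keep]
                continue
            feasible = False  # bound unattainable: optimize instead
        best = q.min() if obj.direction == "min" else q.max()
        idx = idx[q == best]
    i = int(idx[0]) if goal.tie_break == "smallest_tau" else int(idx[-1])
    return curve.breakpoints[i], curve.rates[i], feasible


def tune(table: PredictionTable, goal: GoalSpec) -> ThresholdSet:
    """Select one threshold per class of ``table`` under ``goal``.

    Every class in the table's class set gets an entry; classes with no
    ground-truth records get the ALWAYS_UNSURE sentinel and a warning.
    """
    if len(table) == 0:
        raise TuningError("cannot tune thresholds on an empty table")
    counts = table.class_counts()
    entries: dict[str, ThresholdEntry] = {}
    for label in table.class_set:
        if counts[label] == 0:
            logger.warning("class %r has no tuning records; threshold set to %s", label, ALWAYS_UNSURE)
            entries[label] = ThresholdEntry(class_label=label, tau=ALWAYS_UNSURE, rates=None)
            continue
        curve = rate_curve(table, label)
        tau, rates, feasible = select_threshold(curve, goal)
        logger.info(
            "class %r: tau=%.6g (goal %s, n=%d) cc=%.4f mc=%.4f uc=%.4f feasible=%s",
            label, tau, goal.goal_id, counts[label], rates.cc, rates.mc, rates.uc, feasible,
        )
        entries[label] = ThresholdEntry(class_label=label, tau=tau, rates=rates, feasible=feasible)
    provenance = table.fingerprint()
    provenance["goal"] = goal.to_dict()
    return ThresholdSet(goal=goal, entries=entries, provenance=provenance)
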