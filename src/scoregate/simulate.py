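"""Synthetic classifier-output tables for testing the thresholding pipeline.

Real multi-class image classifiers assign very high softmax scores to many
wrong predictions, with the amount of correct/wrong score overlap varying
strongly between classes.  The simulator reproduces that structure
without any images or trained network, under two score models:

``uniform_pair``
    The top score of a correct prediction is uniform on one interval, of
    a wrong prediction uniform on another (typically overlapping)
    interval.  Deliberately simple so every thresholded rate has a closed
    form (:func:`expected_rates`) to test against.

``dirichlet``
    The full score vector is Dirichlet-distributed with the predicted
    class's concentration boosted, conditioned (by rejection resampling)
    on the predicted class attaining the maximum.  The defaults
    (``alpha0=0.05``, ``beta=2.5``) put roughly 80% of top scores in
    [0.6, 1.0] for a 20-class problem — the concentration of scores near
    the top that makes a single global threshold inadequate — and give
    wrong predictions the same high-score profile as correct ones.

A single integer seed drives all randomness; identical configurations
yield identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UnsupportedModelError
from .io import PredictionTable
from .rates import ClassRates

_MODELS = ("dirichlet", "uniform_pair")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic prediction table.

    ``correctness_prob`` (p_i) and ``n_per_class`` may be a single value
    applied to every class or a per-class mapping.  ``confusion_weights``
    optionally maps each class to a distribution over the *other* labels
    used when a prediction is wrong; the default is uniform.
    """

    class_labels: Sequence[str]
    n_per_class: int | Mapping[str, int] = 500
    correctness_prob: float | Mapping[str, float] = 0.8
    confusion_weights: Mapping[str, Mapping[str, float]] | None = None
    score_model: str = "dirichlet"
    alpha0: float = 0.05
    beta: float = 2.5
    correct_interval: tuple[float, float] = (0.8, 1.0)
    wrong_interval: tuple[float, float] = (0.5, 0.9)
    include_vectors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        labels = list(self.class_labels)
        if len(labels) < 2:
            raise ConfigurationError("need at least 2 class labels")
        if len(set(labels)) != len(labels):
            raise ConfigurationError("class labels must be unique")
        if self.score_model not in _MODELS:
            raise ConfigurationError(f"unknown score model {self.score_model!r}")
        if self.alpha0 <= 0 or self.beta <= 0:
            raise ConfigurationError("dirichlet parameters must be positive")
        for name, (a, b) in (("correct", self.correct_interval), ("wrong", self.wrong_interval)):
            if not (0.0 <= a < b <= 1.0):
                raise ConfigurationError(f"{name}_interval must satisfy 0 <= a < b <= 1, got ({a}, {b})")
        for label in labels:
            p = self.prob_for(label)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"correctness_prob for {label!r} outside [0, 1]: {p}")
            if self.count_for(label) < 0:
                raise ConfigurationError(f"negative n_per_class for {label!r}")
            if self.confusion_weights is not None and label in self.confusion_weights:
                w = self.confusion_weights[label]
                if label in w:
                    raise ConfigurationError(f"confusion weights for {label!r} include the true class")
                if abs(sum(w.values()) - 1.0) > 1e-9 or any(v < 0 for v in w.values()):
                    raise ConfigurationError(f"confusion weights for {label!r} must be a distribution")
                if set(w) - set(labels):
                    raise ConfigurationError(f"confusion weights for {label!r} reference unknown labels")

    def prob_for(self, label: str) -> float:
        if isinstance(self.correctness_prob, Mapping):
            return float(self.correctness_prob[label])
        return float(self.correctness_prob)

    def count_for(self, label: str) -> int:
        if isinstance(self.n_per_class, Mapping):
            return int(self.n_per_class[label])
        return int(self.n_per_class)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "class_labels" not in raw:
            raise ConfigurationError("simulation config must be a mapping with 'class_labels'")
        for key in ("correct_interval", "wrong_interval"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad simulation config: {exc}") from exc


def _draw_wrong_labels(rng, config, label, size):
    others = [c for c in config.class_labels if c != label]
    if config.confusion_weights is not None and label in config.confusion_weights:
        w = config.confusion_weights[label]
        weights = np.array([w.get(c, 0.0) for c in others])
        weights = weights / weights.sum()
    else:
        weights = np.full(len(others), 1.0 / len(others))
    return rng.choice(others, size=size, p=weights)


def _dirichlet_vectors(rng, config, pred_idx):
    """Dirichlet score vectors conditioned on pred_idx being the argmax."""
    n_classes = len(config.class_labels)
    m = len(pred_idx)
    out = np.empty((m, n_classes))
    todo = np.arange(m)
    alpha_base = np.full(n_classes, config.alpha0)
    while todo.size:
        alpha = np.tile(alpha_base, (todo.size, 1))
        alpha[np.arange(todo.size), pred_idx[todo]] += config.beta
        draws = rng.gamma(shape=alpha)  # normalized gamma draws = Dirichlet
        draws /= draws.sum(axis=1, keepdims=True)
        ok = draws.argmax(axis=1) == pred_idx[todo]
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
    return out


def simulate(config: SimulationConfig) -> PredictionTable:
    """Generate a synthetic prediction table under ``config``.

    For each record of true class *i* the prediction is correct with
    probability p_i, otherwise a wrong label is drawn from the confusion
    weights; the top score (and optional full vector) follows the
    configured score model.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.class_labels)
    n_classes = len(labels)
    item_ids, trues, preds, tops = [], [], [], []
    vec_blocks = [] if config.include_vectors else None

    for label in labels:
        n = config.count_for(label)
        if n == 0:
            continue
        p = config.prob_for(label)
        correct = rng.random(n) < p
        pred = np.where(correct, label, None)
        n_wrong = int((~correct).sum())
        if n_wrong:
            pred[~correct] = _draw_wrong_labels(rng, config, label, n_wrong)
        pred = pred.astype(object)

        if config.score_model == "uniform_pair":
            a_c, b_c = config.correct_interval
            a_w, b_w = config.wrong_interval
            top = np.where(
                correct,
                rng.uniform(a_c, b_c, size=n),
                rng.uniform(a_w, b_w, size=n),
            )
            if vec_blocks is not None:
                rest = (1.0 - top) / (n_classes - 1)
                if np.any(rest >= top):
                    raise ConfigurationError(
                        "uniform_pair vectors need top score > 1/n_classes; "
                        "raise the score intervals or drop include_vectors"
                    )
                vecs = np.repeat(rest[:, None], n_classes, axis=1)
                pred_idx = np.array([labels.index(c) for c in pred])
                vecs[np.arange(n), pred_idx] = top
                vec_blocks.append(vecs)
        else:
            pred_idx = np.array([labels.index(c) for c in pred])
            vecs = _dirichlet_vectors(rng, config, pred_idx)
            top = vecs[np.arange(n), pred_idx]
            if vec_blocks is not None:
                vec_blocks.append(vecs)

        start = len(item_ids)
        item_ids.extend(f"{label}_{start + i:06d}" for i in range(n))
        trues.extend([label] * n)
        preds.extend(pred.tolist())
        tops.extend(top.tolist())

    frame = pd.DataFrame(
        {
            "item_id": item_ids,
            "true_class": trues,
            "predicted_class": preds,
            "top_score": np.asarray(tops, dtype=float),
        }
    )
    scores = None
    if vec_blocks is not None and vec_blocks:
        scores = pd.DataFrame(np.vstack(vec_blocks), columns=labels)
    return PredictionTable(frame=frame, class_set=tuple(labels), scores=scores)


def expected_rates(config: SimulationConfig, class_label: str, tau: float) -> ClassRates:
    """Closed-form expected rates under the uniform_pair model.

    E[cc] = p · |(max(τ, a_c), b_c]| / (b_c − a_c) and analogously for
    E[mc] with the wrong-score interval; E[uc] is the complement.  Only
    defined for the uniform_pair model (the Dirichlet top score has no
    tractable closed form).
    """
    if config.score_model != "uniform_pair":
        raise UnsupportedModelError("expected_rates is only defined for the uniform_pair model")
    if class_label not in config.class_labels:
        raise ConfigurationError(f"unknown class {class_label!r}")
    if not (0.0 <= tau <= 1.0):
        raise ConfigurationError(f"tau {tau} outside [0, 1]")
    p = config.prob_for(class_label)

    def surviving(interval):
        a, b = interval
        return min(max((b - max(tau, a)) / (b - a), 0.0), 1.0)

    cc = p * surviving(config.correct_interval)
    mc = (1.0 - p) * surviving(config.wrong_interval)
    uc = 1.0 - cc - mc
    return ClassRates(
        class_label=class_label, tau=float(tau),
        cc=cc, mc=mc, uc=uc, cov=cc + mc, n_truth=config.count_for(class_label),
    )
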