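# Methods

## Model and procedure

`scoregate` implements selective classification by per-class score
thresholding. The classifier is treated as a black box that emits, for
each item X, a score vector over n classes summing to 1; only the top
score S(X) and its class C(X) enter the method. The procedure has two
phases run on two independent datasets:

1. **Tuning.** On a scored dataset with ground truth, each class *i*'s
   rate functions CC_i(τ), MC_i(τ), UC_i(τ) are evaluated over candidate
   thresholds and one τ_i is selected under a lexicographic goal (G1, G2,
   G3 or a custom objective list).
2. **Application.** On new predictions, an item predicted as class *j* is
   confirmed iff S(X) > τ_j and otherwise relabelled `UNSURE`. Ground
   truth plays no role in the decision.

The central assumption is the standard one for post-hoc abstention: the
relationship between score and correctness estimated on the tuning set
transfers to the application set. Nothing is assumed about score
calibration — scores are used only ordinally, which is why one threshold
per class (rather than a global one) matters: the score level that
separates right from wrong answers differs strongly between classes.

### Boundary and tie conventions

* A kept item needs S(X) **strictly** greater than τ; an item with
  S(X) = τ is unsure. Defining UC as the complement of the kept set (S ≤
  τ) rather than by a strict inequality on its own makes
  CC + MC + UC = 1 an identity for every τ, which the test suite asserts
  to 1e−12.
* Candidate thresholds are the breakpoints {0} ∪ {observed scores of the
  class} ∪ {1}. The rates are right-continuous step functions that change
  only when τ crosses an observed score, so the breakpoints realize every
  achievable (CC, MC, UC) operating point; a dense sweep can only be
  coarser, never finer.
* Within a goal, remaining ties are broken toward the **smallest** τ by
  default (equal tuning rates, larger margin of future coverage);
  `largest_tau` is available. Rates at a breakpoint are compared as exact
  count ratios, so tie detection is not subject to float noise.
* G2's bound comparison is strict (MC < bound). If no breakpoint meets
  the bound, selection falls back to minimizing MC and the class is
  flagged infeasible in the threshold file.
* The tuning/application indexing asymmetry is deliberate and preserved:
  tuning rates condition on the ground-truth class, the decision rule
  uses the predicted class's threshold. One consequence worth knowing:
  even a G3 threshold with tuning MC = 0 does not guarantee zero applied
  misclassification, because wrong predictions *of* class j originate in
  other classes whose scores never entered class j's tuning subset. The
  residual is O(1/n) per class under separated score distributions and is
  tested as such.

### Degenerate inputs

A class declared in the class set but absent from the tuning ground truth
gets the sentinel `ALWAYS_UNSURE` (no data → no risk estimate → reject),
with a logged warning. At application time a predicted class missing from
the threshold set follows a configurable fallback (`always_unsure` by
default, `accept` and `error` available). A class with no kept
predictions has undefined accuracy; it is reported as NA and excluded
from Mean/SD rows rather than counted as zero, with the exclusion count
noted in the report.

## Rates and summaries

Per-class accuracy is the precision of kept predictions of the class over
the whole table. The score-quantile diagnostic `correct_score_quantile`
reports, for default q = 0.05, the smallest observed correct-score value
sq with at least a fraction q of correct scores at or below it (the lower
empirical quantile, so ≥ 95% of correct classifications score at or above
sq), paired with the fraction of the class's misclassifications scoring
≥ sq — a one-number summary of how much wrong-answer mass hides inside
the high-score region. Summary rows use the unweighted mean across
classes and the sample (n−1) standard deviation; a single-class summary
reports SD 0.

All computation is on the [0, 1] score scale; the `percent` display
option multiplies rate columns by 100 in reports (accuracies stay as
proportions, as conventionally reported).

## The simulator

The simulator emulates the statistical structure of softmax outputs that
makes per-class thresholding necessary, without any images or trained
network. Per class *i* it draws: correctness with probability p_i
(default 0.8); a wrong label from per-class confusion weights (uniform
over the other classes by default); and scores under one of two models:

* `uniform_pair` — correct top scores uniform on an interval (default
  [0.8, 1.0]), wrong top scores uniform on another (default [0.5, 0.9]).
  Exists because every thresholded rate then has a closed form
  (`expected_rates`), giving an independent oracle for convergence tests:
  E[CC](τ) = p·|(max(τ, a_c), b_c]|/(b_c − a_c), analogously for E[MC].
* `dirichlet` — the full score vector is Dirichlet(α) with base
  concentration α₀ = 0.05 and the predicted class boosted by β = 2.5,
  conditioned by rejection resampling on the predicted class attaining
  the maximum (which keeps every table valid by construction). The
  defaults were calibrated once so that, for 20 classes, roughly 80% of
  top scores fall in [0.6, 1.0] and wrong predictions show the same
  high-score profile as correct ones — the regime in which a single
  global threshold fails — and then frozen.

A single integer seed drives all randomness through one
`numpy.random.Generator`; identical configurations give byte-identical
tables.

What the simulator does **not** emulate: per-class multimodal score
shapes, correlations between items (frames of the same video), covariate
shift between tuning and test sets beyond independent sampling, and
class imbalance dynamics beyond the configured counts. Green tests
therefore demonstrate the correctness and internal consistency of the
thresholding machinery and its qualitative risk ordering under the
stated score structure — not performance claims about any particular
real classifier or dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run on simulated tables of 20
classes × 300–500 records (10,000 per class where a 3-binomial-sd
convergence check needs tight empirical rates), and the cross-validation
risk-ordering check uses 10 classes × 200 records over 20 independent
seeds — sizes at which every stochastic assertion has comfortable margin
while the whole suite runs in a couple of minutes. Conservation is
asserted to 1e−12 (pure count arithmetic; the only float operation is
one division), threshold optimality against a 1e−4-step exhaustive scan,
and stochastic rate checks at 3 binomial standard deviations.

## Known limitations

* Thresholds for classes with few tuning records are noisy; the package
  logs per-class tuning counts but does not model threshold uncertainty
  or flag instability.
* No smoothing or interpolation of rate curves, and no cross-validated
  threshold selection: the contract is one independent tuning set.
* The `UNSURE` stream is only counted, not managed: routing rejected
  items to human review is out of scope.
* Rates come without confidence intervals.
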