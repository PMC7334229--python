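# scoregate

Post-hoc error-rate control for multi-class classifiers with a reject
option. `scoregate` takes the scored outputs of any classifier whose last
layer is a softmax (each item gets a predicted class C(X) and a top score
S(X) ∈ [0, 1]), tunes one confidence threshold τ_i per class on an
independent scored dataset, and then reroutes test predictions whose
score does not clear their predicted class's threshold to a reserved
`UNSURE` class. The practical motivation comes from automated species
identification in ecology — deep networks assign very high scores to many
wrong identifications, and the score/error relationship differs sharply
between species — but nothing in the package is specific to images: it
only ever sees tables of `(item, truth, prediction, score)`.

## The method

For a class *i* with threshold τ, over the items whose ground truth is
*i*:

    CC_i(τ) = #(C(X) = i  AND  S(X) > τ  AND  Y = i) / #(Y = i)
    MC_i(τ) = #(C(X) ≠ i  AND  S(X) > τ  AND  Y = i) / #(Y = i)
    UC_i(τ) = 1 − CC_i(τ) − MC_i(τ)            (items with S(X) ≤ τ)
    COV_i(τ) = CC_i(τ) + MC_i(τ)               (coverage)

These are step functions of τ that change only at observed scores, so the
candidate thresholds for class *i* are exactly the breakpoints
{0} ∪ {observed scores of class *i*} ∪ {1}. One threshold per class is
selected under a lexicographic goal:

* **G1** — maximize CC, then minimize MC (never give up coverage);
* **G2** — require MC < 5% (configurable), then maximize CC; if the bound
  is unattainable, minimize MC and flag the class;
* **G3** — minimize MC, then maximize CC (lowest achievable risk).

At application time an item predicted as class *j* is kept iff
S(X) > τ_j and otherwise becomes `UNSURE`; ground truth is never
consulted by the rule. Note the deliberate asymmetry: thresholds are
*tuned* on each class's ground-truth items but *applied* by predicted
class. Reports give per-class CC′/MC′/UC′ after the decision rule, the
per-class accuracy (precision of kept predictions), and Mean / sample-SD
summary rows.

Because real scored datasets are rarely shareable, the package includes a
simulator that reproduces the qualitative structure of deep-classifier
scores (class-dependent error rates; both correct and wrong predictions
concentrated at high scores) under two models: `dirichlet` (realistic
shape) and `uniform_pair` (closed-form expected rates, used as a test
oracle).

## Worked example

```python
from scoregate import GoalSpec, PredictionTable, apply, evaluate, tune

tuning = PredictionTable.from_records([
    ("r1", "a", "a", 0.95), ("r2", "a", "a", 0.80), ("r3", "a", "b", 0.90),
    ("r4", "a", "a", 0.60), ("r5", "a", "b", 0.55),
    ("r6", "b", "b", 0.85), ("r7", "b", "a", 0.70), ("r8", "b", "b", 0.90),
])
thresholds = tune(tuning, GoalSpec(goal_id="g3"))
for label, entry in thresholds.entries.items():
    print(label, entry.tau, round(entry.rates.cc, 3), entry.rates.mc)
```

prints

```
a 0.9 0.2 0.0
b 0.7 0.667 0.0
```

i.e. the lowest-risk threshold for class `a` is 0.90 — the smallest value
that silences both wrong predictions (tuning MC = 0) while keeping one
correct classification in five (CC = 0.2) — and for class `b` it is 0.70,
keeping two correct items of three. Applying the thresholds to new
predictions and evaluating:

```python
test = PredictionTable.from_records([
    ("t1", "a", "a", 0.97), ("t2", "a", "b", 0.72), ("t3", "b", "b", 0.95),
])
result = evaluate(apply(test, thresholds))
print(result.per_class[["cc", "mc", "uc", "accuracy"]])
```

```
        cc   mc   uc  accuracy
class
a      0.5  0.5  0.0       1.0
b      1.0  0.0  0.0       0.5
```

`t2` (truth `a`, predicted `b` with 0.72 > τ_b = 0.70) stays a
misclassification and costs class `b` its perfect precision; every kept
`a`-prediction is right.

The same pipeline from a shell:

```
scoregate simulate --config sim.yaml --out pred.csv
scoregate tune --predictions pred.csv --goal g2 --out thresholds.json
scoregate apply --predictions pred.csv --thresholds thresholds.json --out decisions.csv
scoregate evaluate --decisions decisions.csv --report report.csv --scale percent
scoregate benchmark --seed 0 --out-dir bench/
```

`benchmark` runs the two standard designs on simulated data — tune and
test on the same table, and tune on one table / test on an independent
one — for all three goals next to the no-post-processing baseline.

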