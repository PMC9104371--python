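# Methods

## The model

`trisent` treats three-class sentiment classification of short free-text
survey answers as a *regression-then-trichotomization* problem. A
continuous sentiment score O ∈ [−1, 1] is learned from an auxiliary
binary-polarity corpus (transfer from plentiful 0/1-labeled reviews to
scarce hand-labeled survey text), and the three ordinal classes are carved
out of the score axis by two interval boundaries t₁ ≤ t₂ calibrated on the
small labeled survey sample:

    negative:  O < t₁        neutral:  t₁ ≤ O < t₂        positive:  O ≥ t₂

The outer limits are fixed at −1 and +1, so the two boundaries fully
determine the decision rule. Boundary membership (half-open intervals,
neutral lower-inclusive, positive owning t₂) is a convention of this
implementation; nothing downstream depends on it beyond determinism.

### Document representation

Documents are lowercased, reduced to alphabetic tokens, and mean-pooled
over per-token embedding vectors (default dimension 20). Mean pooling is
the minimal defensible sentence-from-word construction: it is
permutation-invariant and maps the empty document to the zero vector —
word order is deliberately ignored. Out-of-vocabulary tokens map to the
zero vector.

The default provider (`HashEmbedding`) is deterministic and offline: each
token's vector is drawn from an RNG seeded by a stable hash of
(seed, token), N(0, 0.3²) per coordinate. When a `polarity_axis` is
configured together with a lexicon, positive/negative/neutral lexicon
tokens receive +1/−1/0 on that coordinate. This gives the regressors a
learnable signal of controllable strength and makes every training test
self-contained. An adapter (`TableEmbedding`) loads real pretrained
vectors from TSV when they are available; nothing in the package requires
it.

### Scorers

Two scorers are trained on the binary corpus with labels {0, 1} mapped to
regression targets {−1, +1} (the natural choice given a tanh-bounded
output; the score is then interpretable as a signed degree of positivity):

* **Network scorer** — 20 inputs, one hidden layer of 16 ReLU units, one
  tanh output unit; squared-error loss minimised by minibatch SGD with
  momentum 0.9, learning rate 0.05, batch 32, 50 epochs, all randomness
  seeded. The architecture is fixed by design; the optimizer settings are
  defaults chosen for stable convergence on 20-dimensional inputs at
  corpus sizes of a few thousand and can be overridden in `MLPConfig`.
  The output range is [−1, 1] by construction.
* **SVR scorer** — scikit-learn's ε-SVR, RBF kernel, C = 1.0, ε = 0.1
  (library defaults, deliberately untuned); raw predictions are clipped
  into [−1, 1].

Training uses the corpus's `train` split only; the `validation` split
backs a binary-accuracy diagnostic at score threshold 0.

### Threshold calibration

`calibrate` runs k-fold cross-validation (default k = 5, seeded shuffle,
optional stratification) over (score, gold) pairs. For each fold an
exhaustive search over the grid {−1, −1+δ, …, 1} (default δ = 0.01),
restricted to ordered pairs t₁ ≤ t₂, maximizes plain 3-class accuracy on
the k−1 training folds; the held-out fold's accuracy is recorded as that
fold's validation estimate, and the returned pair is the arithmetic mean
of the per-fold optima (which preserves the ordering invariant).

Two numerical choices matter:

* **Tie-breaking.** The accuracy surface is piecewise constant, so the
  maximizer is almost always a plateau. Among all maximizing grid pairs we
  return the one closest to the centroid of the maximizing set (then the
  lexicographically smallest). The centred choice is the max-margin
  boundary: it is unbiased when scores abut the true boundary from both
  sides, whereas an extreme member of the plateau is biased by the
  plateau's width. It is also what makes boundary-recovery accuracy a
  meaningful test of the search.
* **Search direction.** Optimizing on the k−1 training folds (standard
  cross-validation) rather than on the held-out fold uses 4/5 of the data
  per fold estimate, which stabilises the averaged boundaries on samples
  of a few hundred scores.

The search itself is vectorized with cumulative class counts
(`searchsorted` per class, then an outer sum over grid pairs), and is
property-tested against a brute-force oracle that scores every grid pair
by applying the decision rule directly.

Published threshold presets for the reference study's four
model × cohort combinations ship as a YAML fixture and load via
`load_threshold_presets()` for use without retraining.

### Evaluation

Confusion matrices follow the rows = predicted, columns = real convention
(the transpose of scikit-learn's default; the matrices are built with
scikit-learn and transposed). For each class the 3×3 matrix collapses
one-vs-all to (TP, FP, FN, TN); per-class accuracy, precision, recall and
F1 are weighted by real-class support and summed. Useful identities, both
property-tested:

* support-weighted recall ≡ trace/total ≡ plain accuracy;
* transposition swaps each class's FP and FN, so per-class one-vs-all
  accuracy is transpose-invariant — and the weighted accuracy is
  transpose-invariant *when the support weights are pinned to the
  dataset's class sizes*. Recomputing supports from a transposed matrix
  changes the weights and in general the weighted value;
  `weighted_one_vs_all(cm, supports=...)` therefore accepts explicit
  supports, defaulting to the matrix's column sums.

Percents are exact floats internally; display rounding is half-up to two
decimals, with a truncation formatter alongside because published tables
sometimes truncate (two accuracy cells in the bundled reference table are
truncations of 88.889 and 72.857). A class with no predicted items gets
precision 0 with a warning rather than NaN.

`verify_reference_tables()` recomputes the full metric suite from the
bundled reference confusion matrices and compares against the published
rows within ±0.02 percentage points. Against the printed matrix
orientation, the published "weighted precision" row matches
support-weighted *recall* and the "weighted recall" row matches
support-weighted *precision* — the published row labels are swapped
relative to standard definitions. The package keeps the standard
definitions and maps the rows in the comparison, documented in the fixture
(`src/trisent/data/reference_tables.yaml`).

### Word clouds

Term frequencies are raw corpus-wide counts after preprocessing, with stop
words removed and a minimum-count filter (default 20 repetitions) — raw
counts, not normalised frequencies, because the filter threshold is a raw
repetition count (a `normalized()` view exists). Rendering places words
largest-first on an Archimedean spiral from the canvas centre with
rectangle collision tests and a deterministic grid-scan fallback; font
size is directly proportional to the count (size = 72 pt × count/maxcount
by default). Layout metadata (token, count, font size, position) is
returned to the caller and identical for identical seeds, making the
renderer testable; text extents use approximate monotone glyph metrics, so
collision boxes are estimates, not pixel-exact.

## The synthetic data generator

The generator emulates the structure of the study corpus this pipeline is
designed around, not its language:

* **Survey strata.** Default strata reproduce exactly the study's
  per-country, per-role class counts — Spain students 88/6/12, Colombia
  students 84/26/9, Spain staff 41/14/27, Colombia staff 30/14/14
  (negative/neutral/positive), totalling 225 students + 140 staff = 365.
  Each testimony carries a single gold label, consistent with the
  reference confusion-matrix column totals (172/32/21 students, 71/28/41
  staff). Strata are overridable via YAML.
* **Texts.** A document of class c draws each token from the class-c
  lexicon with probability (1 − noise_rate) × purity, from the filler
  vocabulary with probability noise_rate, otherwise from the competing
  class lexicons. Defaults: purity 0.9, noise 0.2, length uniform on
  [8, 30] tokens — the purity matches the condition used throughout the
  end-to-end tests; noise and length are chosen to resemble short survey
  answers with function-word padding. The three class lexicons are
  pairwise disjoint by contract.
* **Binary corpus.** n documents (default 2,000 in the pipeline, a
  scaled-down stand-in for a 50,000-review corpus), balance 0.5, split
  80/20 into train/validation; class 1 draws from the positive lexicon,
  class 0 from the negative one, with the same purity/noise scheme.

What this does **not** emulate: real lexical ambiguity, negation,
sarcasm, spelling errors, translation artifacts, topic drift, or any
correlation between country/role and writing style. Synthetic corpora at
purity 0.9 are nearly linearly separable along the polarity axis, so the
end-to-end accuracies the tests and the acceptance script report (~99%)
validate the pipeline's mechanics — data flow, training, calibration,
evaluation — and say nothing about accuracy on real survey text. The
published reference accuracies (88.9/88.6% for the network, 83.1/72.9%
for the SVR) depend on the original corpus and trained models and are
deliberately not targets of the synthetic runs; they are verified instead
by recomputing the metric suite from the transcribed confusion matrices.

## Degenerate inputs and edge cases

* Empty token stream → zero document vector; empty corpus → empty score
  list; empty confusion matrix → `UndefinedMetricError`.
* `t₁ = t₂` is legal and yields an empty neutral interval.
* Calibration requires at least k labeled items and all three classes
  present; single-class corpora are rejected at training time.
* Scores outside [−1, 1] are rejected by `decide` (scorers clip, so this
  only triggers on foreign inputs).

## Problem sizes

Default test and acceptance runs use 365 survey testimonies, 2,000 binary
documents, a 201-point threshold grid (δ = 0.01) and 300 scores for
boundary recovery; these sizes give stable, reproducible statistics while
keeping a full end-to-end run in the low seconds. The oracle-equivalence
checks run at δ = 0.05 on ≤ 50-item instances, where brute force is exact
and cheap.
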