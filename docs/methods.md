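# Methods

## The RAD statistic

For a binary case table with symptom indicators `F[m, i]` and syndrome
indicators `L[m, k]` over `N` cases, the package computes:

- appearance probabilities `Pf_i = (Σ_m F[m, i]) / N` and
  `Pl_k = (Σ_m L[m, k]) / N`;
- co-occurrence counts `n_ij = Σ_m F[m, i]·F[m, j]` (and the
  symptom–syndrome analogue);
- the relative associated density
  `C(i → j) = n_ij / n_i = P̂(j = 1 | i = 1)`.

RAD is an empirical conditional frequency, so the pair
`(C(i→j), C(j→i))` obeys the exact mass identity
`C(i→j)·n_i = C(j→i)·n_j = n_ij`, which the test suite asserts on
random tables. The diagonal is reported as 0 (self-association is
uninformative) and a conditioning feature with zero count yields a zero
row plus a logged warning rather than NaNs, keeping matrices total.

**Link classification.** An ordered pair is a *one-way* link when the
forward RAD is at least `hi` and the backward RAD is at most `lo`, and
a *two-way* link when both directions reach `hi` (recorded once per
unordered pair, oriented forward ≥ backward, name order on ties; the
orientation of a two-way link carries no information). Defaults are
`hi = 0.5`, `lo = 0.1`: a one-way link then means "the majority of
i-cases carry j, but at most a tenth of j-cases carry i". Both are
configurable because no canonical cutoff exists; the link report always
records the thresholds used. No significance testing is attached —
RAD is a descriptive screen, and links at these defaults should be read
as hypotheses, not inferences.

## Symptom selection

For a syndrome `k`, symptoms are ranked by contribution
`C(L_k → F_s) = P̂(symptom | syndrome)` (descending, ties keeping
column order). The backward-elimination wrapper removes the
lowest-ranked remaining symptom one at a time (full sweep `S → 1`),
evaluates the classifier at every subset size by stratified k-fold
cross-validation with pooled confusion counts, and keeps the subset
with the best G-means; ties go to the smaller subset (parsimony).

The MRMR baseline ranks greedily: the first pick maximises the plug-in
mutual information (base-2, `0·log 0 ≡ 0`) between symptom and label;
each later pick maximises `MI(F_i; L_k) − mean_{s ∈ selected} MI(F_i; F_s)`
(the MID, difference, criterion; the quotient form MIQ is available by
argument). Nested prefixes of this ranking feed the *same* wrapper, so
RAD and MRMR differ only in the ranking. MID is the default because it
is the common textbook form; with the redundancy weight set to 0 it
reduces to plain MI ranking (asserted in tests).

**Leakage control.** By default rankings are recomputed on the training
portion of every fold, so the evaluated subsets never see held-out
cases; `rank_on_all=True` restores the naive single-ranking variant.
The reported `selected` subset is always the full-data ranking cut at
the best size, which is the subset a practitioner would carry forward.

**Classifiers.** `svm`: a max-margin linear classifier (hinge loss, L2
penalty, regularization strength C = 1.0). `knn`: k-nearest-neighbour
majority vote with k = 5; exact vote ties (possible only for even k)
break toward the positive class, which is the conservative choice for
rare labels. Neither is tuned: the wrapper compares rankings, not
classifier configurations. No resampling or class weighting is applied
by default, so imbalance effects stay visible in TPR/TNR.

## Evaluation

`TPR = TP/(TP+FN)`, `TNR = TN/(FP+TN)`, `G-means = √(TPR·TNR)`.
Confusion counts are pooled across folds before rates are computed
(each case predicted exactly once), so the rates are defined whenever
the label has both classes; a zero denominator is reported as
*undefined*, never as 0. The default protocol is stratified 5-fold
cross-validation with seed 42. Labels with fewer than `max(folds, 10)`
minority cases are excluded from pipeline summaries by default (the
estimates are too unstable to average), with a flag to keep them.
Summaries report the arithmetic means of TPR and TNR and *both* common
summary-G-means conventions, each labelled: the mean of per-syndrome
G-means values, and `√(meanTPR · meanTNR)`; published tables of this
kind mix the two, so neither is forced. Text reports round to three
decimals, half away from zero.

## The synthetic generator

Real inquiry-diagnosis tables are rarely redistributable, so validation
runs on a latent-syndrome noisy-OR model. Per case: syndromes are drawn
in topological order of an acyclic link graph — base prevalence when no
parent is present, otherwise a noisy-OR over the present parents' link
probabilities (so the conditional given a single parent is exactly the
configured link probability); symptom `s` then activates with
probability `1 − (1 − ε_s)·Π_k (1 − E[k][s])` over present syndromes
`k`, with background rate `ε_s`. Symptoms are conditionally independent
given the syndrome state, so every quantity the estimators target —
symptom marginals, directed conditionals `P(j|i)`, and
`P(symptom|syndrome)` — has a closed form by enumerating the `2^K`
syndrome states. Enumeration is exact up to K = 12; beyond that a
Monte-Carlo estimate is recorded with its seed and sample size in the
ground-truth manifest.

The shipped `chd_like_preset` emulates a 555-case coronary-heart-disease
cohort: 10 syndromes with marginals 0.025–0.76 (two planted
dependencies: heart-*qi* deficiency → blood stasis at 0.80, making that
pair two-way at ~0.80/0.64; heart-*yang* deficiency →
heart-kidney-*yang* deficiency, giving `P(yang | kidney-yang) ≈ 0.97`),
and 63 named symptoms whose ground-truth marginals span 0.002–0.786.
Syndrome base rates and symptom background rates are back-solved by
exact enumeration so the model marginals hit those targets to machine
precision. The emission matrix is hand-designed to be clinically
plausible — cardinal symptoms (chest distress, palpitation, short
breath) driven by several syndromes, chills by the *yang*-deficiency
syndromes, night sweat by *yin* deficiency — and plants asymmetric
one-way symptom pairs, e.g. paroxysmal night dyspnea → palpitation
(true conditionals ≈ 0.87/0.04) and lateral thorax distending pain →
aggravating gloom (≈ 0.68/0.05).

**What the simulator does not model:** within-case symptom dependence
beyond shared syndromes, recorder/observer noise, missingness, age/sex
structure, and any particular real cohort's joint distribution. Tests
passing on this generator therefore certify the estimators and the
selection machinery — that empirical RAD converges to the model's true
conditionals, that planted one-way pairs are recovered, that planted
relevant symptoms are ranked highly — not the clinical conclusions one
would draw from any specific data set.

## Validation design and problem sizes

- Estimator consistency: empirical RAD within 0.03 of the true
  conditionals at N = 20 000 (features with marginal ≥ 0.05), and
  cross-RAD within 0.02 at N = 50 000.
- Planted one-way pair (true conditionals 0.9/0.05): classified
  one-way at default thresholds in ≥ 99 of 100 seeds at N = 5 000.
- Planted relevant symptoms (emission 0.8 vs background 0.05, 5 of 40,
  N = 2 000): both selectors place ≥ 4 of 5 in their top 10 in ≥ 90%
  of 20 seeds.
- Wrapper sanity: with one symptom equal to the label among noise
  (N = 500), both selectors keep it and the selected subset's G-means
  is at least the full-set G-means (guaranteed by construction, since
  the full set is in the trace).
- Metric arithmetic is regression-tested against a published
  TPR/TNR/G-means reference table; the handful of cells whose printed
  G-means is inconsistent with the printed rate pair (upstream
  rounding) are skipped explicitly in the test.
- Determinism: a fixed seed makes the simulator, folds, classifiers and
  all JSON artifacts byte-identical across runs (manifests carry no
  timestamps).

## Numerical and degenerate-input choices

- Empty syndrome block (K = 0) is legal; syndrome-level operations
  return empty results rather than erroring.
- Stratified folding requires at least `folds` minority cases; the
  error message advises fewer folds.
- MI uses the plug-in estimate with natural handling of empty cells;
  MIQ adds 1e-12 to the denominator to stay defined at zero redundancy.
- Ranking ties (equal RAD contribution or equal MRMR criterion) resolve
  to the earlier column, making rankings stable and runs reproducible.
- Probabilities are reported at full precision in JSON and rounded only
  in human-readable reports (three decimals; percent tables one
  decimal).

## Known limitations

RAD conditions on single features only: it cannot separate direct from
syndrome-mediated symptom association (no partial-correlation or
conditional-independence adjustment is attempted). Wrapper selection
optimises cross-validated G-means and inherits its variance at small N;
at 555 cases the chosen subset size fluctuates by a few symptoms across
seeds even when the top of the ranking is stable. The MRMR plug-in MI
is biased upward at very low counts, which is immaterial for ranking at
the shipped sample sizes.
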