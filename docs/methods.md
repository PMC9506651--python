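# Methods

This note documents the models, conventions and numerical choices behind
`ctbench`, and what its simulated test conditions do and do not show about
real data.

## Preprocessing model and ordering

The pipeline assumes a nonnegative genes × cells count matrix with a
per-cell cell-type label (possibly unassigned). Normalisation is
counts-per-million followed by log2(cpm + 1), applied to the *full* gene
universe before any gene filtering: cpm denominators use each cell's total
over all genes present at normalisation time, so columns need not re-sum to
10⁶ after filtering. Filtering then proceeds in a fixed order — unassigned
cells, all-zero genes, zero-MGECT-variance genes — and every step logs the
removal count so a run's provenance reads as the familiar
cells-then-genes-then-medians cascade.

MGECT (Median Gene Expression within each Cell Type) is the per-gene vector
of medians over each cluster's cells, in log-normalised units. Medians of
even-sized clusters are the mean of the two central order statistics (the
conventional definition). The zero-variance filter removes rows that are
*exactly* constant. Because medians are nonnegative and all-zero genes were
already removed, a zero-variance row is either all-zero (a gene expressed
in fewer than half of every cluster's cells) or constant-positive;
housekeeping-like genes with merely similar medians across clusters are
retained, which matches the filter's conservative intent.

## Stratified split

Labeled cells are split train/validation/test (default 0.6/0.2/0.2)
independently within each cluster: a cluster of m cells contributes
⌊0.6·m⌋ train, ⌊0.2·m⌋ validation, and the remainder to test. Floor/
floor/remainder is deterministic, partition-exact, and guarantees a
nonempty test part for every cluster; the price is that the test part can
exceed its target proportion by up to two cells (m = 9 gives 5/1/3). Each
cluster's permutation is seeded from the top-level seed plus a CRC32 offset
of the cluster name, so adding or removing one cluster never perturbs
another's assignment. Clusters with fewer than 5 cells are split with a
warning — their train or validation part may be empty, which is the
small-cluster regime the benchmark deliberately exercises.

## Feature-selection conventions

*Binary score.* Score(g, X) = Σᵢ(1 − yᵢ/y_X)⁺/(n − 1), summed over all n
clusters (the i = X term is identically zero, keeping the range [0, 1]).
When y_X = 0 the score is defined as 0: a gene with zero median in the
target cluster cannot be a positive marker for it. Top-fraction selection
takes k = ⌈fraction·G⌉ genes per cluster (minimum 1, so the 1 % cut is
never empty), ranking ties at the cutoff broken by ascending gene id for
cross-platform determinism; the merged set is reported in ascending gene-id
order.

*Coefficient of variation.* CV = σ/μ of the MGECT row, with the population
standard deviation (divide by n) by default and a recorded `ddof_mode`
switch for the sample form — both are defensible and the choice is part of
the output's provenance. Selection is inclusive (CV ≥ threshold). Zero-mean
rows cannot reach this step after upstream filtering and are treated as a
contract violation, not silently scored.

Both selectors nest by construction (smaller fraction ⊆ larger; higher
threshold ⊆ lower), which the tests assert on random tables and generated
data.

## Classifier harness

Backends are the established implementations of the five families —
scikit-learn's LogisticRegression, SVC, RandomForestClassifier and
MLPClassifier, and LightGBM's LGBMClassifier — reached only through a
fit/predict contract keyed by a `ClassifierSpec` (family, mode,
hyperparameters, seed). Hyperparameter names are validated against a
per-family allow-list before any fitting. Class order is the
lexicographically sorted label set everywhere (relabeling, argmax ties,
confusion-matrix axes).

One-vs-all mode (logistic regression and random forest) fits one binary
backend per class on 1-vs-rest relabeled data and predicts by argmax over
per-class confidence — the calibrated probability when the backend exposes
one, otherwise the raw decision value, with the source recorded per class;
argmax ties resolve to the earlier class name. The neural network defaults
to three hidden ReLU layers of 100 neurons trained by Adam under a small
fixed iteration budget (max_iter = 50), all overridable through the spec.
No feature scaling is applied beyond log2(cpm + 1).

Grid search enumerates the declared per-parameter candidate lists
odometer-style (declaration order, last parameter fastest), fits each
configuration on the training split and scores it by the *median
per-cluster validation F-beta*; clusters absent from the validation split
are skipped (not scored 0) and logged; ties go to the first configuration
enumerated.

## Evaluation

Per-cluster precision, recall and Fβ come from the full confusion matrix
with pessimistic zero-denominator conventions (0 when a cluster is never
predicted or has no members), matching the observed "F-beta = 0" outliers
for very small clusters. β defaults to 0.5, weighting precision twice
recall, because dropout makes recall the noisier quantity in sc/snRNA-seq.
Fβ follows the harmonic-mean formula (1 + β²)PR/(β²P + R) — the operative
definition — and model comparison uses the median over clusters, not over
cells.

The Wilcoxon signed-rank test on paired per-cluster F-beta vectors discards
zero differences (the classical convention), ranks absolute differences
with midranks, and takes W = min(W⁺, W⁻). For n ≤ 25 effective pairs the
two-sided p-value is exact: the distribution of W⁺ over all 2ⁿ sign vectors
is built by convolving one rank at a time (arithmetically identical to full
enumeration, including midrank ties), and the lower tail is doubled, capped
at 1. Beyond 25 a normal approximation with continuity correction and the
midrank tie-variance correction is used; the method is recorded in the
result. All-zero differences yield an explicit degenerate signal with no
p-value rather than a silent 1.0. The test is two-sided; no
multiple-testing correction is applied across comparisons.

## Synthetic data: what it emulates, and what it does not

The generator plants four gene roles in a negative-binomial count model
with independent dropout (each nonzero entry zeroed with probability
`dropout_rate`), cluster sizes log2-uniform on [16, 512] by default — the
span where small-cluster instability appears — and explicit sizes where a
fixed design is wanted.

- **Markers** draw 1 + NB(mean ≈ 30, dispersion 2) in their home cluster
  (every home cell expresses before dropout) and are exactly zero
  elsewhere, so at dropout < 0.5 their home median is positive with
  overwhelming probability and their binary score is exactly 1.
- **Graded genes** get cluster means interpolated between the low and high
  levels across a random cluster subset, giving nonzero CV of expected
  medians without exclusivity.
- **Sparse genes** are expressed in an exact, pre-chosen count of cells per
  cluster, strictly below half the cluster size, so every cluster median is
  exactly zero *deterministically* — the exact-count construction (rather
  than Bernoulli expression) is what makes the filter-exactness tests
  assertions rather than probabilities.
- **Baseline genes** emulate housekeeping uniformity with the *same*
  expressing-cell fraction (default 0.25, always below one half) in every
  cluster. A constant positive raw count in all cells would *not* produce a
  constant MGECT row, because library sizes differ cell to cell and
  log2(cpm + 1) is library-size dependent; a uniformly-rare gene whose
  median is exactly zero in every cluster is the only construction whose
  removal by the zero-variance filter is deterministic. This is the one
  place the generator trades verisimilitude for exactness.

The truth oracle (markers + graded survive; sparse + baseline are removed)
refuses dropout ≥ 0.5, where marker medians stop being guaranteed positive.

What passing these tests shows: the pipeline's filters, scores, split and
harness behave exactly as specified on data with planted, separable
structure. What it does not show: performance on real atlas data — the
generator does not reproduce empirical library-size distributions,
gene-detection rates, batch effects, doublets, or the soft transcriptional
boundaries between closely related subtypes that make the real problem
hard. Real-data conclusions require running the pipeline on a real labeled
matrix (both file layouts are supported end-to-end).

## Problem sizes

The standard test conditions are deliberately desk-scale: filter-exactness
runs use 5 clusters × 200 genes over 20 simulated datasets; the end-to-end
classification check uses 10 clusters, 2,000 cells and 500 genes (50
planted markers, dropout 0.2), where multinomial logistic regression on
CV ≥ 1.5 features attains median test F-beta ≥ 0.9 and trains at least as
well as it validates. `scripts/acceptance.py` reruns these conditions from
a single seed.

## Known limitations

- The benchmark treats cluster labels as ground truth; it does not perform
  or audit the clustering that produced them.
- SVM, neural-network and gradient-boosted-tree backends run multiclass
  only; one-vs-all is wired for logistic regression and random forest.
- The exact Wilcoxon path is quadratic in total rank mass and capped at
  n = 25 effective pairs; larger comparisons use the corrected normal
  approximation.
- Persisted models use the backends' native (pickle) serialisation and are
  not portable across backend library versions.
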