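# Methods

## Problem and approach

`omicforest` links several mass-spectrometry feature tables (metabolomics
and lipidomics platforms profiled on the same animals) to two kinds of
outcome: an ordinal dose class per animal, and continuous clinical-chemistry
phenotypes. Both links are modelled with random forests, because forests
handle p ≫ n tables without distributional assumptions, capture non-linear
dose–response shapes, and carry a built-in cross-validation-like error
estimate through the out-of-bag (OOB) mechanism: each of the `ntree` trees
is grown on a bootstrap resample of the n samples, and a sample's prediction
aggregates only the trees whose resample excluded it (on average ~36.8% of
trees). The workflow has two branches:

- **Classification branch.** Each platform is autoscaled and classified
  against the dose classes on its own; platforms are ranked by OOB
  misclassification error. Backward elimination then reduces each platform
  to its discriminatory metabolites, the per-platform selections are pooled
  into one fused matrix (feature IDs prefixed with the platform name), and
  elimination runs once more to produce a final cross-platform panel, which
  feeds a partial-correlation network.
- **Regression branch.** Every (platform, phenotype) pair is fit with an RF
  regression; predictive quality is Q² = 1 − MSE_OOB / Var(y). Significance
  of Q² and of per-feature importances comes from a permutation null
  (phenotype shuffled, forest refit). Each phenotype's significant features,
  plus the phenotype itself as a clinical node, feed a per-phenotype
  partial-correlation network.

Classification uses backward elimination for feature selection; regression
uses the permutation test. That split reflects what each statistic offers:
the OOB error gives elimination a direct minimisation criterion, while Q²
and impurity importances need a null distribution to become decisions.

## Forest settings

| parameter | default | meaning / rationale |
|---|---|---|
| `ntree` | 500 | trees per forest; conventional for metabolomics-scale data, enough for stable OOB votes and importance rankings |
| `mtry` | `"auto"` | candidate features per split: nearest integer to √p (classification) or p/3 (regression), floor 1, ties rounded half up — e.g. p=40 gives 6 and 13 |
| bootstrap | n with replacement | standard bagging |
| node size | 1 (classification), 5 (regression) | conventional defaults; unlimited depth |
| class weights | none | groups are left unweighted even though recovery groups (6) are half the size of dose groups (12) |

Tree induction is delegated to scikit-learn; this package owns the OOB
aggregation (hard per-tree votes for classification, with ties broken
toward the earlier class level; averaged per-tree predictions for
regression), both importance measures, and everything downstream. Permutation
importance is Breiman's: per tree, the drop in OOB accuracy when one
feature's values are shuffled among that tree's OOB samples, averaged over
trees. Impurity importance is the unnormalised total decrease in node
impurity (Gini or RSS), averaged over trees. If `ntree` is small enough
that some sample appears in every bootstrap, its prediction falls back to
the full forest and a warning is raised.

Q² uses the population variance (denominator n), so predicting the mean
scores exactly 0 and values are unbounded below; Q² < 0 means OOB
predictions are worse than the mean and occurs routinely under the null.

## Backward elimination

From the full model, each iteration discards the `drop_fraction` (default
20%, at least one) of features with the smallest permutation importance and
refits; from p=40 the visited sizes are 40, 32, 26, 21, 17, 14, 11, 9, 7,
6, 5, 4, 3, 2. The ranking is frozen at the full-model fit by default:
re-ranking after every drop lets noise features that look good by chance
survive, a known selection-bias mechanism. `recompute_importance=True`
enables the greedier re-ranking variant.

Each iteration records the OOB error and its binomial standard error
√(e(1−e)/n). The final set is chosen by the `"min"` rule — the iteration
with the smallest OOB error, ties going to the smaller set — which is the
selection criterion the underlying procedure defines. In planted-signal
simulations (10 weak dose-responsive features among 190 noise, n=60, five
classes) this rule retains a median 8–9 of the 10 planted features. The
`"within_1se"` alternative (smallest set within one standard error of the
minimum) yields more parsimonious panels but prunes genuinely informative
weak features along the way; it is available when a small panel matters
more than completeness. Note the reduced-model OOB error is optimistically
biased — the same data chose the features — so reported selected-model
errors should be read as internal comparisons, not generalisation estimates.
`min_features` defaults to 2 so partial correlations remain definable on
any selected set.

## Permutation significance

For a (platform, phenotype) pair, the phenotype vector is shuffled `n_perm`
times (default 1000; uniform shuffles, derangements not enforced), the
forest refit each time, and Q² plus all per-feature impurity importances
recorded. Thresholds are the 95th nearest-rank percentile (the ⌈0.95·n⌉-th
smallest value — reproducible, no interpolation): the observed model is
significant when its Q² exceeds the Q² threshold, and a feature is flagged
when its observed importance exceeds the importance threshold. The
importance null pools all features of the pair into a single distribution,
giving one cut-off per model; per-feature nulls are available via
`pooled_importance=False`. No multiple-testing correction is applied across
phenotypes by default; `regress_all(multiple_testing="bh")` additionally
gates model significance on Benjamini–Hochberg-adjusted empirical Q²
p-values ((1 + #null ≥ observed)/(n_perm + 1)) across all pairs. By exchangeability, the Q² flag fires at the nominal
rate under the null — with 200 permutations the exact rate is
10/201 ≈ 4.98% — which holds for any ensemble size, so calibration checks
can run with small forests.

## Partial-correlation networks

Edges carry full-order partial correlations: with P the inverse of the
correlation matrix, ρ_ij·rest = −P_ij/√(P_ii·P_jj) is the correlation of
variables i and j after the linear effect of all other selected variables
is removed. This separates direct from indirect association — on a chain
X1→X2→X3 the marginal correlation of the ends is large while their partial
correlation given the middleman vanishes. Two-sided p-values use
t = r·√((n−2−k)/(1−r²)) with k = p−2 controlled variables and n−2−k degrees
of freedom (for p=2 this reduces to the classic Pearson test). Edges are
drawn at p ≤ α (default 0.05, per edge, uncorrected). No shrinkage
estimator is used; instead the estimator requires n > p+2 and a
non-singular correlation matrix (gated on the reciprocal condition number,
10⁻¹⁰), which the upstream selection stages are expected to satisfy —
the networks of interest have ~10 nodes at n ≈ 60–78. Under the per-edge
α, a network over v null pairs contains at least one false edge with
probability 1−0.95^v, so exact recovery of a planted graph tops out around
74% for a 5-node chain even with perfect power.

Cross-platform screening (`pearson_edges`) keeps variable pairs with
|Pearson r| ≥ 0.8 (inclusive; the absolute value is used even though
positively co-regulated lipid panels dominate in practice) and hands the
union of involved variables to the partial-correlation step.

## Synthetic studies and what they show

The generator emulates a 13-week rodent dose-range design: eight groups —
control, four doses (0/30/100/300/1000 mg/kg/day, 12 animals each) and
three treatment-free recovery groups (control, 300, 1000; 6 each), 78
animals. Defaults:

- **Dose effect.** Informative features shift by δ·log1p(dose)/log1p(1000)
  in noise-SD units, so δ is the shift at the top dose and the 30→1000
  range does not linearly dwarf the low doses. Recovery groups carry their
  dose attenuated by γ = 0.3, keeping them confusable with control — the
  hardest aspect of the real task. Power simulations plant δ = 2.0, a
  strongly dose-responsive metabolite (2 SD at top dose, adjacent dose
  classes ~0.3–0.7 SD apart — individually weak, jointly informative).
- **Platforms.** Nine tables spanning 40–300 features (~1100 total),
  dose-responsiveness strongest in the DI-MS-like lipid platforms and
  absent from the wide open-profile table.
- **Phenotypes.** 35 clinical columns; relative liver weight and five
  enzyme/analyte panels are linear combinations of named platform features
  (β ≈ 0.7–1.0) plus Gaussian noise (σ ≈ 0.4–1.2), the rest pure noise.
- **Correlation structure.** Optional feature blocks drawn from a stated
  precision matrix (e.g. a chain Gaussian graphical model), giving known
  conditional independences for network tests.

The generator does **not** emulate instrument drift, batch effects,
missing values, heteroscedastic abundance-dependent noise, or realistic
lipid co-regulation beyond the planted blocks. Passing tests therefore
demonstrate that the statistical machinery behaves correctly under its own
assumptions — calibrated nulls, recovered planted structure, monotone
power — not that any particular real study's numbers will reproduce.

## Numerical and reproducibility choices

- Autoscaling uses the sample standard deviation (n−1); zero-variance
  features are a hard error (selection must never run on constants) unless
  explicitly downgraded to drop-with-warning. All platforms are autoscaled
  by default, configurable per run.
- Alignment restricts every member of a study to the shared samples in
  lexicographic order and reports what was dropped; missing values are an
  input error, never imputed.
- Every entity gets its own sub-seed derived from the global seed and the
  entity's name via a 4-byte blake2s digest (stable across processes,
  unlike Python's salted `hash`), so adding a platform or phenotype never
  perturbs another's results, and a rerun with the same config is
  byte-identical.
- Scaled-down problem sizes in the test-suite simulations (ensemble sizes
  of 10–500 trees, 15–200 permutations depending on what the check needs)
  are chosen per check: rank-stability checks use the full 500 trees,
  calibration checks exploit ensemble-size-freeness, and smoke tests use
  small forests. The acceptance script runs the full study at ntree=500
  for classification and 100 permutations × 100 trees per regression pair.

## Known limitations

- The reduced-model OOB error after selection is optimistically biased;
  `selection.cross_validated_error` wraps the entire select-then-classify
  procedure in an outer stratified k-fold loop (default k=5, off the main
  workflow path) when an unbiased estimate is needed.
- Full-order partial correlation requires more samples than variables;
  there is no shrinkage fallback for p approaching n.
- The permutation importance null pools features, so a platform with a few
  dominant features can mask weaker genuine associates.
- sklearn's bootstrap bookkeeping is accessed through a private helper
  (`_generate_unsampled_indices`) to recover each tree's OOB set; a major
  sklearn upgrade may require touching that one seam.
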