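# Methods

This note documents the models, conventions and design choices behind
`pvsignal`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Disproportionality analysis

For each (drug, SOC) cell the 2×2 contingency table (a, b, c, d) is
built over the *post-exclusion* SOC universe: the marginals b and d
never count reports in excluded SOCs, because exclusion precedes signal
detection in the workflow. The statistics are

- ROR = (a/b)/(c/d) = a·d/(b·c),
- PRR = [a/(a+b)]/[c/(c+d)],

and a cell is labelled significant iff both strictly exceed the
threshold (default 2). Conventions for degenerate cells:

- a = 0 → both statistics are 0 (a drug never reported in the SOC can
  never be a signal);
- an undefined denominator (b·c = 0 for ROR; c = 0 for PRR) with a > 0
  → the statistic is NaN and the label is 0;
- (drug, SOC) pairs absent from the table behave as a = 0.

No continuity correction is applied by default; a Haldane–Anscombe
+0.5 option exists behind the `continuity` flag for users who want
finite statistics on zero cells. Confidence intervals are deliberately
not offered as a significance criterion: the joint >2 point-estimate
rule is the supported decision rule, applied identically to every
source so that sources remain comparable.

Percentage-valued sources are converted to pseudo-counts as
`round(pct/100 × pseudo_total)` with `pseudo_total = 10,000` by default
(preserves two-decimal percentage resolution); the same labelling path
then applies. Because ROR and PRR are scale-invariant (a property the
tests verify), the choice of `pseudo_total` only matters through
rounding granularity.

The six default-excluded SOCs are the administration-site, injury,
investigations, product-issue, social-circumstance and surgical
categories; applying them to the bundled 27-name SOC vocabulary leaves
21 modelled categories. The vocabulary file contains publicly documented
SOC names only — no licensed terminology content is shipped, and
disease-term matching against deeper hierarchy levels is out of scope
(a user-supplied vocabulary can be passed anywhere a SOC list is
accepted).

## 2. Interaction features

Interaction confidence scores live in [0, 1]; absent pairs and empty
score fields are conservatively 0. The confidence filter zeroes scores
below 0.4 — scores exactly at the boundary are kept, reading "below
0.4 is low confidence" literally. Duplicate (drug, target) rows keep
the maximum score (conservative toward retaining evidence). Drug
alignment between the interaction and report tables is exact matching
after case-folding, trimming and whitespace collapsing; fuzzy merging
of drug identifiers is deliberately avoided because silent false joins
are worse than documented attrition (the alignment report lists every
dropped identifier). Filtering and alignment commute, so their order is
immaterial.

## 3. Per-SOC classification

One binary classifier per retained SOC; features are the drug's full
interaction-score row, the label its significance in that SOC.

- **Split**: stratified 80/20 by default. The test split is inviolate:
  resampling statistics, SMOTE neighbours and model fits only ever see
  training rows, both in the final fit and inside every CV fold of the
  hyperparameter search. Bundles record the train/test indices so the
  no-leakage property is asserted structurally in the tests.
- **Resampling**: SMOTE to parity (synthetic minority rows are convex
  combinations of a minority row and one of its k = 5 nearest minority
  neighbours; k degrades gracefully with a warning for tiny minorities,
  and resampling is skipped entirely below 2 minority members), then
  Tomek-link cleaning (mutual-1-NN pairs with opposite labels; only the
  majority member is removed). Implemented in-package since no
  imbalanced-learning library is available in the target environment.
- **Hyperparameter search**: sequential model-based optimisation.
  Trial 0 is the library-default configuration (so the search can never
  return something worse than the default under the same CV protocol),
  early trials are random, later trials maximise expected improvement
  under a Matérn-5/2 Gaussian-process surrogate over unit-scaled
  encodings of the five tuned hyperparameters (ensemble size, minimum
  split/leaf sizes, feature subsample, class weighting). The objective
  is mean stratified-3-fold CV ROC AUC with fold-internal resampling.
  100 trials is the full-scale setting; the desk-scale preset
  (`DESK_SEARCH_SPACE`, ensemble size 50–200, used by the test suite
  and the acceptance script with 10–20 trials) keeps a six-SOC run in
  minutes on one CPU. Search bounds are configuration, not constants.
- **Metrics**: computed from explicit formulas rather than delegated.
  ROC AUC is the positive/negative pair-concordance probability with
  0.5 tie credit, implemented via average ranks (algebraically
  identical; the tests cross-check against exhaustive pair counting).
  Undefined-metric conventions — precision with tp+fp = 0, recall with
  tp+fn = 0, F1 with precision+recall = 0, MCC with a zero factor, AUC
  with single-class truth — map to 0 (NaN for AUC) and are recorded as
  flags, never silently coerced.
- **Comparison**: a single decision tree is trained per SOC under the
  identical protocol and split; forests vs trees are compared with a
  paired t-test across SOCs on ROC AUC and accuracy. Zero-variance
  difference vectors are reported as degenerate rather than crashing.
  Pooled confusion percentages aggregate all trainable bundles' test
  cells per model kind.
- SOCs with fewer than two drugs in either class are marked
  untrainable, excluded from the paired test, and logged.

## 4. Interpretation and validation

Global importance is the normalized mean decrease in impurity. The
"positive-prediction" mode — used for the headline top-10 ranking —
re-accumulates each node's impurity decrease only along the decision
paths traversed by rows the model predicts positive, weighted by
traversal count, then renormalizes. This isolates the targets the model
actually uses when it calls a drug risky; with no positive predictions
it falls back to global mode with a warning. Rank ties break by higher
importance then lexicographic target id, for determinism.

Disease terms are mapped to SOCs with a token-sort Levenshtein ratio on
a 0–100 scale (case, punctuation, whitespace and word order are
ignored), implemented in-package. The default acceptance threshold of
80 is the conventional default for token-ratio matchers; it is
configurable and the per-term similarities are returned for sensitivity
checks. Terms are matched against SOC names directly. Targets without
any association rows are flagged `no_data` rather than scored.
Alignment counts are conserved: matched-per-SOC plus unmatched equals
the target's association rows.

The drug cross-reference lists every nonzero post-filter (drug, target)
edge for the selected targets; ATC enrichment counts distinct drugs per
level-1 prefix with unclassified drugs excluded from the denominator
and reported separately.

## 5. The synthetic world

The generator emulates the statistical structure the pipeline assumes,
not any real database's content.

| parameter | default | rationale |
|---|---|---|
| n_drugs × n_targets | 300 × 120 | desk-scale; large enough for stable per-SOC splits |
| SOCs | 6 (4 planted, 2 null) | planted/null contrast for calibration checks |
| causal targets per planted SOC | 5 | disjoint sets across SOCs |
| interaction_density | 0.05 | with Beta(2, 2) scores, ≈ 15% of drugs engage a planted SOC — strong class imbalance |
| interaction score distribution | Beta(2, 2) | symmetric, full [0, 1] support; ≈ 65% of present scores survive the 0.4 filter |
| baseline_report_rate | 8 reports/cell | chosen a priori: small enough that Poisson noise yields occasional spurious signals in null SOCs (≈ 1–3% prevalence, keeping null models trainable and the null-calibration check computable), large enough that planted mechanisms reliably push ROR/PRR past 2 |
| relative_risk | 4 | engaged cells' Poisson rate multiplier |
| association_recall | 1.0 | every causal target (bar the designated no-data one) listed under its true SOC |
| name_noise_rate | 0.1 | single-character typos and singular/plural toggles, to exercise the fuzzy matcher |
| ct_miss_rate | 0.3 | fraction of engaged cells whose risk multiplier the clinical-trial-style source misses, producing partial overlap between sources |

Engagement is defined with the same 0.4 threshold the feature filter
uses, so the planted mechanism is exactly what the features can see.
Counts are Poisson per cell — the simplest counting process that
creates realistic disproportionality structure. Decoy association rows
for non-causal targets draw their disease terms from non-focal SOCs
only, so focal alignment counts are bounded by the planted causal
targets present in a top-k list. One causal target of the first planted
SOC (deterministically the lexicographically last) is withheld from the
association table entirely, to exercise the no-data path. The
clinical-trial-style percentage table is an independent Poisson re-draw
with partial signal dropout.

What a green test on this world does **not** establish: robustness to
media-driven reporting surges, report-level covariates (age, dose,
co-medication), sub-SOC terminology granularity, drug-identifier chaos
across real databases, or non-Poisson overdispersion of real report
counts. The generator's geometry matters: with very few SOCs a drug's
off-focal report mass shrinks and engaged drugs inflate the comparator
column, dragging PRR toward 1 — planted-effect worlds should keep ≥ 5–6
SOCs (the defaults do).

## 6. Reproducibility

Everything is seeded: the generator from `SyntheticConfig.seed`, the
model suite from `RunSettings.seed` via fixed-order child-seed draws
per SOC, the pipeline from `RunConfig.seed`. A pipeline run writes a
`manifest.json` with the full configuration, seed, library versions and
per-stage row counts; rerunning the same configuration reproduces
`metrics.tsv` byte-identically (a test asserts this). Worlds written
with the same config and seed are byte-identical on disk.

## 7. Known limitations

- Disproportionality labels are frequency-based; severity is ignored.
- The GP optimiser proposes from random candidate pools (128/step);
  it is a practical SMBO, not a provably optimal acquisition scheme.
- Positive-prediction importance is one defensible reading of
  "contribution to positive predictions"; global importance is always
  reported alongside it.
- ATC codes and association tables are consumed as given; no identifier
  resolution (SMILES/InChI) or live database querying is performed.
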