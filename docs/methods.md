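# Methods

## The positive-unlabelled ranking problem

targetrank scores every gene in a feature table for druggability — the
likelihood that a gene's product can be modulated by a therapeutic agent to
produce a desired effect. Training data for this problem is one-sided: a
small set of *seed* genes (targets of approved or clinical-phase drugs) is
known positive, while no gene is a confirmed negative. Everything outside the
seed set is merely *unlabelled*. Standard supervised classification is
therefore inappropriate; targetrank instead uses a stochastic semi-supervised
positive-unlabelled (PU) ensemble.

## Stochastic PU ensemble

Let P be the positive set, U the unlabelled set, and ρ (`rho`) the balancing
ratio. Per stochastic iteration ℓ = 1..L:

1. U is shuffled and cut into disjoint chunks of ≈ ρ·|P| genes; each chunk is
   paired with the *full* positive set to form a balanced partition. A final
   chunk shorter than max(½·ρ·|P|, k) is merged into its predecessor, so the
   chunks always cover U exactly.
2. Within each partition, a stratified k-fold cross-validation (default
   k = 10) is run: the classifier is fitted on the training folds and
   probabilities are predicted for the held-out fold. Each partition member
   thus receives exactly one out-of-bag (OOB) prediction per partition.

After L iterations the final score of a gene is the plain arithmetic mean of
all its OOB probabilities: an unlabelled gene accrues exactly L predictions
(one per iteration, since the chunks partition U), a positive gene one per
partition per iteration. Positive genes' many OOB predictions are averaged
with equal weight; no down-weighting is applied. Percentile ranks use
ascending average ranks (ties share the mean rank), scaled to [100/n, 100].

All randomness flows from a single integer seed through named substreams
(one per module, one per stochastic iteration), so any run is bit-reproducible
from its configuration alone.

Defaults L = 10 and ρ = 1.5 are package choices: L = 10 makes the Monte Carlo
error of the mean OOB probability small relative to fold-level noise, and
ρ = 1.5 keeps partitions close to balanced while using more of U per
iteration than exact 1:1 pairing would.

### Classifiers

The registry provides gradient boosting (default), random forest, extra
trees, an SVC wrapped in Platt-style probability calibration
(`CalibratedClassifierCV`), and Gaussian naive Bayes — all scikit-learn
estimators behind a uniform `fit`/`predict_probability` contract. The tuned
gradient-boosting defaults are `n_estimators=200`, `learning_rate=0.1`,
`max_depth=5`, `max_features='sqrt'`, `min_samples_leaf=4`,
`min_samples_split=5`.

`grid_search_gb` reproduces the two-stage tuning protocol that produced
those values: depth is scanned first — grid (1, 2, 3, 5) by default — with
the other hyperparameters fixed at the pre-tuning inherited values
(`n_estimators=500`, `max_depth=20`, otherwise as above); then estimators ×
learning rate — grids (10, 50, 100, 200, 300, 400, 500) × (0.001, 0.01, 0.1,
1) — are scanned jointly at the chosen depth. Selection is by highest mean CV
AUC with exact ties broken toward fewer estimators, reflecting the observed
AUC plateau beyond 200 estimators.

## Pre-processing

Fixed order, idempotent on its own output; the gene universe never changes:

1. **Sparsity filter** — features whose missing fraction exceeds
   `missing_data_thres` (default 0.99) are dropped; even a feature observed
   for only 1% of genes is kept by default.
2. **Correlation pruning** — pairwise Pearson correlations over jointly
   observed cells; of any pair with |r| strictly above
   `correlation_threshold` (default 0.8), only the earlier column is kept.
   The earlier-column tie-break is a determinism choice; features with fewer
   than 3 jointly observed values against every other feature cannot be
   tested and are retained.
3. **Imputation** — missing values in `binary_flag`, `subset_signal`
   (signals measured only on a study-specific subset of genes) and `network`
   features are zero-filled (absence of evidence is the signal's natural
   zero); `continuous_global` features take their observed median, the
   defensible extrapolation for attributes measured on different global
   reference sets.
4. **Standardization** — zero mean, unit variance using population (ddof=0)
   moments, matching scikit-learn's `StandardScaler` convention. Features
   that are constant after imputation are mapped to all-zeros rather than
   dropped, keeping column bookkeeping aligned; tree ensembles and Boruta
   treat them as uninformative.

## Network feature engineering

For each gene g and interaction channel, targetrank computes the
seed-overlap ratio at exact shortest-path distance d ∈ {1, 2}:

    r_d(g) = |{v : dist(g, v) = d} ∩ P| / |{v : dist(g, v) = d}|

with r_d = 0 when the distance-d shell is empty (including isolated or
absent genes). Two deliberate choices:

- The distance-2 shell **excludes** the gene and its direct neighbours —
  "two edges apart" names a distance, and mixing shells would double-count.
- A seed gene's own label never enters its own ratios (only neighbours are
  counted), so the feature cannot leak the training label.

The summary `hmean = 2·r1·r2 / (r1 + r2)` (0 when both are 0) is the
harmonic mean of the two hop ratios with zero-annihilation; the harmonic
mean is the assumed reading of the combined overlap score, chosen because it
rewards genes connected to seeds at *both* distances. The denominator of the
2-hop ratio counts distance-2 **nodes**, not 2-step walks.

Annotation featurization uses percentile frequency filters with linear
interpolation and an "at or above" (≥) rule:

- interaction-type counts: types at/above the 50th percentile of total
  frequency keep individual count columns; the tail is aggregated into
  `other_types`, plus a per-gene `unique_interactions` count;
- pathway memberships: pathways at/above the 90th percentile of size become
  0/1 flags, the rest a membership count;
- domain/family memberships: unfiltered 0/1 flags.

## Boruta feature selection

Per iteration: (1) append a shadow matrix — every column independently
permuted; (2) fit a random forest on the augmented matrix (impurity-based
importances, 100 trees by default); (3) find s′, the largest shadow
importance; (4) record a hit for every original feature with importance
strictly greater than s′. After R iterations, hits are compared against
Binomial(R, ½): Confirmed if hits exceed the smallest q with CDF ≥ 0.95,
Rejected if below the largest q with CDF ≤ 0.05, Tentative otherwise.

This implementation keeps all features in play for all R iterations and
classifies once at the end; the classic sequential variant instead removes
already-rejected features mid-run. The terminal binomial rule is identical,
and keeping features simplifies the hit bookkeeping at a modest cost in
forest size. Feature rankings use z = (mean importance − mean shadow
importance) / sd of the feature's per-iteration importances, with a +∞
sentinel (ranked first) when the sd is zero.

## Validation statistics

- **AUC** — Mann-Whitney construction, ties ½.
- **DeLong test** — paired comparison of two models' AUCs on identical
  cases via placement values (midranks); two-sided normal p. Zero variance
  of the difference returns p = 1.
- **Fisher 2×2** — two-sided exact p by the minimum-likelihood convention
  (scipy); the reported odds ratio is the sample OR a·d/(b·c), with Haldane
  +0.5 added to all cells only when some cell is zero. The sample OR (not
  the conditional MLE) matches the worked intracellular-localisation
  example: (182, 999, 7544, 7057) → OR 0.17.
- **Rank-interval enrichment** — the ranking is cut into B (default 20)
  near-equal intervals; remainder genes are assigned to the *bottom*
  intervals, so the top interval of a 19,846-gene universe holds exactly
  992 genes (⌊19846/20⌋). Each interval is Fisher-tested against the rest of
  the universe. Ranking ties are broken by input order for deterministic
  interval membership.
- **Evidence CDF** — cumulative fraction of evidence genes found at or above
  each interval; ends at 1 by construction.
- **Stepwise hypergeometric curve** — at cutoffs k = step, 2·step, …, N
  (default step 50; N appended when not a multiple), the upper-tail
  hypergeometric probability of the observed top-k overlap with a reference
  set. The enriched-region AUC is Σ −log₁₀(p)·(Δk/N) over cutoffs with
  p < 0.05 — a rectangle-rule area of the −log₁₀ p curve restricted to the
  enriched region, normalised by the universe size. This area definition is
  a reconstruction of the "area under the enriched region of the curve"
  summary; it is exposed via the `alpha` parameter and p-values are floored
  at the smallest positive double before taking logs.

## Synthetic data

The generators emulate the four input kinds with a planted, tunable signal:

- **Features** — informative columns ~ Normal(effect·1[positive], 1);
  noise ~ Normal(0, 1); binary flags ~ Bernoulli with the positive-class
  odds multiplied by exp(effect/2), so effect = 0 silences every feature at
  once. Missingness is completely at random (MCAR) at `missing_frac`
  (default 0.1), uniformly or per feature class.
- **Graph** — a G(n, p) background at the requested mean degree (default 6)
  overlaid with extra seed–seed edges at p·(boost − 1), giving seed pairs
  ≈ boost-fold (default 5) the background edge probability. This plants the
  assortativity that makes neighbour-overlap ratios informative: druggable
  genes preferentially interact with other druggable genes.
- **Annotations** — interaction-type rates and pathway sizes follow a 1/rank
  (Zipf-like) law so percentile thresholds are non-trivial; pathway sizes
  span over an order of magnitude.

What the generators do **not** emulate: structured (per-source) missingness,
correlated feature blocks, realistic marginals of real annotation databases,
scale-free degree distributions, or label noise in the seed sets. Passing
recovery tests therefore demonstrates that the machinery extracts a planted
signal of the stated form and stays calibrated under the null — not that
real-data AUCs or enrichments will match any particular value.

## Problem sizes used in tests and the acceptance script

End-to-end parameter recovery runs at n = 800 genes, 80 positives, L = 2,
k = 5, ρ = 1.5: large enough that the null AUC's sampling error (≈0.034 SE)
keeps the [0.4, 0.6] null band meaningful, small enough for a laptop-scale
test suite. Boruta recovery runs the stated design exactly (n = 400, 5
informative at effect 2.0 + 45 noise, R = 40). The acceptance script reports
mean AUCs over 3 seeds per condition.

## Known limitations

- Correlation pruning is order-dependent (earlier columns win); a graph-based
  minimum-vertex-cover prune would drop fewer features but lose determinism
  of which member is kept.
- Positives' scores average many more OOB predictions than unlabelled genes'
  (partitions-per-iteration × L vs L), so their scores are less noisy; no
  reweighting is applied.
- The SVC path is an order of magnitude slower than the tree ensembles due
  to internal calibration CV.
- `stepwise_hypergeom` treats the ranking as strictly ordered; upstream score
  ties are resolved by stable sort order.
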