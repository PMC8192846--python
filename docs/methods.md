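# Methods

## The problem and the model

`famrank` ranks the members of a large, partly pseudogenized gene family by
the likelihood that they are functionally active. It combines three layers:

1. an **evidence-tier categorization** (Groups I–IV) that converts
   annotation flags into labels — substrate-characterized genes are treated
   as known-active, never-studied genes as presumed-inactive;
2. an **unsupervised layer** (consensus k-means over z-scored features,
   PCA) that shows whether the feature space carries activity structure at
   all; and
3. a **supervised two-tier resampling-consensus classifier** that turns the
   noisy labels into high-confidence calls for the unlabeled majority.

The central statistical idea is double consensus. A single train/test split
of a small labeled pool (tens of positives) yields unstable classifiers, so
the pipeline demands near-unanimity across two levels of resampling: within
a round a gene must win at least `vote_threshold` of `n_resamples`
independently retrained votes (reference 950/1,000), and across rounds at
least `min_rounds` of `n_rounds` rounds must agree (reference 9/10). Both
thresholds are inclusive (≥). Because `min_rounds > n_rounds/2`, the final
active and inactive sets are disjoint by pigeonhole. The price of this
conservatism is a large "unclassified" set; the goal is precision of the
short candidate list, not coverage.

## Labeled pool and splits

Positives are all Group I genes; negatives are Group IV genes downsampled
uniformly (seeded) to a 1:3 positive:negative ratio (41 + 123 of 140 at
reference scale). Each resample draws a fresh stratified split with a
global-count rule: the training side gets `floor(2/3 · n)` genes (109 of
164), allocated per class by floors plus largest fractional remainder, so
the class ratio in training is always within one gene of the pool ratio.
Unstratified splitting is available behind a flag. Group II genes
(phenotype-known, no substrate) never enter the pool; they serve as internal
positive controls when scoring the calls.

## Base classifiers

The reference classifier is a small multilayer perceptron: hidden layers of
10 and 2 logistic units, trained full-batch with L-BFGS from a seeded
initialization until convergence (max 2,000 iterations). A fit that fails to
converge is retried with up to three fresh seeded initializations and then
**abstains** — its votes count in neither tally, keeping vote totals
well-defined; abstention counts are logged per round. Random forest
(`mtry = 4`) and a radial-kernel C-classification SVM (with Platt-style
calibration for probability scores) are contract-level alternatives
delegated to scikit-learn. Scores ≥ 0.5 are called active (inclusive at the
boundary).

`n_publications` is a predictive feature even though it is correlated with
the evidence tiers that define the labels; this mirrors the intended use
(literature evidence genuinely is a signal of activity), and the feature-set
argument accepts any explicit column list for sensitivity analyses that
exclude it.

## Consensus clustering

Each of `reps` resamples draws `floor(0.8 · n)` genes without replacement
(features are never subsampled), partitions them with Euclidean k-means
(single Lloyd run per resample, seeded), and increments co-sample and
co-cluster tallies for every sampled pair. The consensus matrix is the
elementwise ratio (0, flagged, for never-co-sampled pairs); final
assignments cut an average-linkage tree on `1 − M`. The delta-area of the
consensus-CDF advises the cluster number k (suggestion = largest k whose
relative area gain exceeds a configurable floor, default 0.1), but k is
always explicit configuration — consensus diagnostics are read by a person,
not trusted blindly. Inner linkage is irrelevant for a k-means cluster
algorithm and is not exposed.

Features are z-scored (population SD) before clustering, PCA and MLP
training: the 27 characteristics mix counts, ratios and expression units,
and Euclidean k-means is meaningless on raw mixed units. Zero-variance
columns map to zeros with a warning. CV is undefined (missing) at mean 0; a
gene missing any expression summary is incomplete and removed (with a
logged id list) before analysis.

## Statistics

* **Fisher's exact test**: two-sided p by summing hypergeometric
  probabilities ≤ that of the observed table (the R default convention);
  sample odds ratio (a·d)/(b·c). Zero margins give p = 1 and an undefined
  odds ratio. Equivalence with exhaustive enumeration is tested for all
  tables with total ≤ 16 and randomized larger tables.
* **Kruskal–Wallis + Dunn + BH**: tie-corrected KW; Dunn z from pooled mean
  ranks with the standard tie term, BH step-up across the pairwise
  comparisons of one feature at a time.
* **Welch's t** with Welch–Satterthwaite df for two-group figure-style
  comparisons.
* **Normalized prediction precision** = validation accuracy ÷ (number of
  test-set genes called active + inactive). It deliberately uses test-set
  call counts, not validation counts: two methods with equal validation
  accuracy are distinguished by how selective their candidate lists are.
  Undefined (NaN, flagged) when nothing is called.
* **Verification report**: before comparing predicted-active vs
  predicted-inactive vs reference-active genes on expression and
  evolutionary features, the larger called set is downsampled (seeded,
  recorded in the report) to the smaller's size, so rank tests are not
  driven by unequal n.
* Validation accuracy averages per-resample accuracies (per round, then
  across rounds — with equal resample counts per round this equals the
  grand mean); false-negative/positive rates pool class-conditional
  confusion counts across all resamples.

## The synthetic-family generator

The generator (`famrank.simulate`) emulates the joint structure the method
assumes, calibrated at `separation = 1` to the group summaries the analysis
is designed around:

| feature family | active | inactive | distribution |
|---|---|---|---|
| per-sample expression | π₀=0.05, μ=2.5, σ=0.6 | π₀=0.45, μ=0.2, σ=0.6 | zero-inflated log-normal |
| Ka/Ks | 0.23 ± 0.11 | 0.62 ± 0.16 | normal, clipped to (0.001, 1.5] |
| Ks | log-mean ln 1.8 | log-mean ln 0.55 | log-normal (σ_log = 0.5) |
| publications | tier means 27 / 5.8 / 2.2 / 0 (I–IV) | — | gamma-Poisson, r = 0.3 |
| ESTs, cDNAs, introns | 40 / 12 / 3 | 6 / 1.5 / 1.2 | gamma-Poisson |
| T-DNA insertions | regional means (0.8, 2.5, 2, 1.2, 1) | half | gamma-Poisson per region |
| neutral flag | P = 0.05 | P = 0.70 | Bernoulli |
| CTD class | LRR/Kelch-rich | FBA/FBD/rare-rich | categorical |
| F-box-domain e-value exponent | −12 ± 5 | −22 ± 5 | normal |

Default composition: 41 active-labeled (Group I), 140 inactive-labeled
(Group IV), 511 unknown with 20% truly active; truly active unknowns carry
phenotype evidence (→ Group II) with probability 0.4, emulating a realistic
internal-control tier. 60 expression samples stand in for a many-thousand-
sample RNA-seq compendium — enough for stable CV estimates at desk scale.
Publication counts follow the evidence tier (Group IV exactly 0 at the
calibrated separation), other counts follow true activity.

A single `separation` knob linearly interpolates every class-specific
location parameter about its class midpoint: at 0 the two generative
distributions are identical (any classifier is at chance by construction);
at 1 the calibrated values hold; beyond 1 the classes stretch apart.
Substreams are spawned per feature family from the master seed in a fixed,
append-only order, so adding a feature family never perturbs existing
draws, and identical seeds yield byte-identical outputs. Label noise, when
requested, flips labeled tiers I↔IV independently per gene and never touches
true activities.

**What passing tests do and do not show.** The generator draws features
independently within a gene given its activity; real gene families have
correlated features (expression breadth ↔ Ks ↔ domain class), batch
structure in expression compendia, and phylogenetic dependence among
paralogs. Recovery results on synthetic families therefore demonstrate that
the machinery is correct and well-calibrated — not that any particular
biological family will separate as cleanly.

## Problem sizes and numerical choices

The test suite and the acceptance script run a scaled ensemble — 100
resamples × 3 rounds with thresholds rescaled proportionally (95/100 and
3/3) on the default ~700-gene family and the 10-feature set; the rescaling
knobs are first-class configuration, so the desk-scale experiment is the
reference experiment shrunk, not a different procedure. Consensus
clustering diagnostics use 100 resamples for k = 2…6. Tolerances: oracle
equivalence at 1e-10 (Fisher), 1e-9 relative (k-means objective),
standardization/PCA identities at 1e-9.

Degenerate inputs: empty simulation configs produce empty tables; k-means
rejects k > n; consensus clustering rejects p_item ∉ (0, 1]; average-linkage
merge ties follow the deterministic smallest-index rule of the linkage
implementation; vote thresholds above the resample count and min-rounds
above the round count are configuration errors.

## Known limitations

* The reduced 10-feature list is taken as given; the package does not
  search feature subsets.
* No hyperparameter search for any base classifier; the MLP architecture is
  fixed by design.
* RF/SVM behavior is delegated (contract-level) to scikit-learn; only the
  MLP path is reference-specified.
* The evidence tables are inputs; the package does not mine literature or
  annotation databases.
* Verification compares feature distributions; it cannot prove activity —
  it checks consistency with the purifying-selection/expression signature
  of active genes.
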