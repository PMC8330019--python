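# Methods

## Response grading

Treatment response is graded per metric and per inter-visit interval into
GOOD (1), MODERATE (2), POOR (3). Visits are indexed 0 (baseline, therapy
start) to 3, roughly six months apart; graded intervals are the three
consecutive pairs (0,1), (1,2), (2,3) and the two cumulative pairs (0,2),
(0,3). Cumulative grades are pure functions of their endpoint visits.

* **Lung function** (FEV1, MEF50, as fractions of predicted): the delta is
  the absolute difference of percent-predicted fractions (0.92 − 0.80 =
  +0.12 = "+12 % predicted"), not a relative ratio. GOOD at
  Δ ≥ +0.10 (FEV1) / +0.15 (MEF50), POOR at the mirrored negative cut,
  MODERATE on the open interval between. The boundary follows the
  inequality direction of the rule (a delta exactly at the good cut is
  GOOD).
* **FENO**: the branch is chosen from the *interval's start* value against
  an age-dependent cut — 35 ppb below 12 years, 50 ppb at or above
  (both configurable; `ResponseRuleSet.feno_age_cut` etc.). High branch:
  relative change beyond +20 % is POOR, beyond −20 % GOOD. Low branch:
  absolute change beyond +10 ppb is POOR, beyond −10 ppb GOOD; the
  inclusive ±band is MODERATE. The GOOD region is defined as the
  complement of MODERATE ∪ POOR so the three grades partition the outcome
  space; the (internally overlapping) verbatim wording of the good rule is
  available behind `ResponseRuleSet(literal_feno_good=True)` for
  sensitivity analysis.
* **Control**: the three-level GINA classification (0 controlled,
  1 partly controlled, 2 uncontrolled) is an *input*; any decrease is
  GOOD, any increase POOR, equality MODERATE.

Missingness propagates: an interval's entry exists only if both endpoint
measurements are present. Complete-case filtering applies to the 12
consecutive features only (4 metrics × 3 consecutive intervals — the
clustering matrix); cumulative grades and baseline covariates may be
missing and are handled by pairwise deletion in the statistics stage.

## Synthetic cohort generator

The generator emulates the study conditions: 365 enrolled; four response
archetypes allocated deterministically in proportions 58/87/138/64 (exact
at n = 347, largest-remainder scaled otherwise) and shuffled; 18 patients
(deterministic mode; binomial otherwise) lose all measurements at one
random non-baseline visit, leaving 347 complete cases.

**Archetype planting.** Each archetype carries a per-(metric, interval)
probability triple over the three grades (row-normalized published
per-cluster counts; the missing MEF50 (1,2) row is imputed from the
printed cumulative MEF50 (0,2) row, which reflects the compounded
trajectory and marks archetype 2 as a poor MEF50 responder). Two planting
modes:

* `archetype` (default): every member receives the archetype *prototype* —
  per feature, the modal grade of its distribution. For the control metric
  the prototype is the maximum-probability *feasible* grade sequence,
  because three consecutive improvements cannot be realized on a 3-level
  ordinal scale. At noise 0 archetype members are identical points in
  response space, which makes the planted partition exactly recoverable —
  the regime used for recovery experiments.
* `marginal`: grades are drawn independently per feature from the
  archetype's distribution, so empirical per-archetype frequencies
  reproduce the published tables. The implied within-archetype
  heterogeneity is substantial — the four archetypes then overlap heavily
  in response space (Ward recovery ARI ≈ 0.1–0.2), because the published
  per-cluster marginals describe clusters *after* clustering and
  independent resampling destroys the within-cluster correlation that made
  them compact. This mode is for calibration checks, not recovery studies.

`noise_rate` resamples each planted grade uniformly over the three grades
(the draw may repeat the original); noised control triples are redrawn
until ordinally feasible.

**Trajectory realization.** Visit-0 measurements are drawn from
per-archetype truncated normals at physiologic bounds (percent-predicted
fractions in [0.2, 1.6], FENO in [1, 150] ppb, age 2–22 y, etc. — the
generator has only means/SDs to work from); each later visit's value is
sampled uniformly from the measurement region consistent with the planted
grade given the interval's start value, with a small margin so CSV
rounding cannot cross a grade boundary, and the classification round trip
is verified before a patient is accepted. Some planted sequences constrain
the feasible baseline (two chained >10 ppb FENO decreases require baseline
FENO > 20 ppb); infeasible draws are rejected and visit 0 redrawn from the
archetype distribution, and the realized visit-0 values are written back
into the baseline table so the two tables agree. Consequently the
*baseline lung-function and FENO columns are feasibility-conditioned*
(slightly shifted from their nominal means), while unconstrained
covariates (age, height, labs, genotypes) reproduce their configured
profiles exactly. A planted control grade infeasible from the drawn
baseline level (e.g. improvement from "controlled") triggers a resample of
the visit-0 level from the feasible set.

Baseline covariates without per-archetype published values (sex, atopy,
comorbidity flags) use cohort-wide frequencies; LABA/LTRA usage rates are
fixed at 0.40/0.30 as plausible pediatric step-2/3 therapy shares (they
only enter the tree's feature set). rs37973 genotypes follow the published
per-cluster frequencies; the five other polymorphisms default to
Hardy–Weinberg proportions at allele frequency 0.5. Analysis-facing files
never contain the archetype label; truth lives in a sidecar CSV.

What passing tests on this generator do **not** show about real cohorts:
real within-cluster heterogeneity (archetype mode removes it), real
correlation structure among covariates (covariates are independent given
the archetype), and real missingness mechanisms (here missing completely
at random by design; the driving variables of the study's exclusions are
unknown).

## Clustering

Nominal grades 1/2/3 are treated as equally spaced ordinal values under
Euclidean distance — the only reading under which "Ward on nominal codes"
is defined. The linkage reports heights in the square-root convention
d(A,B) = √(2|A||B|/(|A|+|B|)·‖x̄_A−x̄_B‖²) (square them for twice the ESS
increase), updates by the Lance–Williams recurrence on squared distances,
and breaks exact ties by the smallest (left, right) node-id pair, making
results platform-reproducible. With exactly tied merges the partition
itself is ambiguous, so permutation invariance of the cut holds for
tie-free data only. The pipeline cuts at k = 4 (the study's choice);
`select_k_by_gap` is advisory output.

**Merge-gap heuristic.** The default criterion returns the k in 2..k_max
maximizing the absolute difference of consecutive top merge heights (ties
to smaller k); a `relative` variant maximizes their ratio. On the default
noise-free cohort both return 4. A known limitation, measured on this
generator: under 5 % grade noise the absolute criterion prefers k = 3
(9 of 10 seeds) — √-Ward heights grow with the merged cluster sizes, so
the top gaps favor the coarsest splits whenever two planted archetypes
(here 1 and 2, which differ in only ~2 of 12 prototype features) merge at
a height midway between the noise floor and the top. The relative variant
is less size-sensitive but still modal-3 under the same conditions. k
selection is therefore advisory and never silently applied.

## Statistics

Pearson χ² without continuity correction for every table shape (cells
with expected counts < 5 are flagged, not silently switched to exact
tests; all-zero margins are dropped with a warning); Kruskal–Wallis with
mid-rank ties and the 1 − Σ(t³−t)/(N³−N) correction, p from the χ²
approximation with k−1 df. Constant features are reported but not tested.
The primary screen flags raw p < alpha (strict) with no multiplicity
adjustment, matching the descriptive reporting style the pipeline mirrors;
BH q-values are emitted as an extra column.

## Decision tree

Binary CART on Gini impurity, grown on the full clustered cohort with no
held-out split (a descriptive discriminant analysis, not a predictive
model — the training confusion matrix is reported for transparency).
Numeric splits at midpoints of sorted distinct values; categorical
features one-hot expanded, with indicator importances re-aggregated onto
the parent feature. A node becomes a leaf when its impurity is already
below `impurity_stop` (default 0.2 — a node-purity reading of the
"Gini < 0.2" stopping rule), at `max_depth` 6, under `min_samples_split`
10 / `min_samples_leaf` 5, or when no admissible split decreases impurity.
Ties prefer the smaller threshold, then the earlier column;
`TreeParams.seed` only matters when `shuffle_features=True`. Importances
are weighted impurity decreases summed per feature and normalized to
100 %. Missing baseline values are median/mode imputed with companion
`*_imputed` indicator columns.

## Numerical choices and problem sizes

All randomness flows through one `numpy` Generator per run, seeded from
the configuration. The linkage oracle tests compare against a naive O(n³)
recomputation from raw coordinates at 1e-9; Ward heights against SciPy at
1e-8 on tie-free data. The Kruskal–Wallis calibration uses 2000 null
replicates (four groups of the study's cluster sizes), whose rejection
rate is checked against 99 % binomial bounds around 0.05. Recovery
experiments use cohorts of n = 347 without missingness so archetype sizes
are exactly the published ones; the acceptance script aggregates ten such
cohorts at 5 % noise. Generated CSVs round lung function to 4 decimals and
FENO to 2; sampling margins (1e-3 fraction points, 0.05 ppb) keep rounded
values inside their grade regions.

## Known limitations

* The archetype planting mode trades marginal fidelity for recoverability
  (see above); no single mode can deliver both, and the package makes the
  trade explicit rather than hiding it.
* Asthma control grading consumes an already-assigned GINA level;
  computing control from symptom diaries is out of scope.
* The χ² p-values are asymptotic even for sparse tables (flagged), and no
  post-hoc pairwise cluster comparisons are provided.
* The CART is descriptive; with ~30 baseline features and deep default
  growth it will also split on noise features — the importance ranking is
  a within-cohort summary, not a validated predictor.
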