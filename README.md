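# phenoresp

Treatment-response phenotyping for longitudinal pediatric asthma cohorts.

Children starting inhaled-corticosteroid-based asthma therapy respond very
unevenly: lung function, airway inflammation and symptom control can each
improve, stagnate or deteriorate on their own trajectory. `phenoresp`
implements an end-to-end analysis that turns two years of follow-up visits
into discrete *treatment-outcome phenotypes*:

1. **MCID response grading** — per metric and inter-visit interval, the
   change is graded GOOD / MODERATE / POOR (coded 1/2/3) against minimal
   clinically important differences: ΔFEV1 ≥ +10 % predicted is good and
   ≤ −10 % poor (MEF50: ±15 %); FENO changes are judged relatively (±20 %)
   above an age-dependent cut (35 ppb under 12 years, 50 ppb otherwise) and
   absolutely (±10 ppb) below it; any improvement in the three-level GINA
   control classification is good, any deterioration poor.
2. **Ward clustering** — the complete-case patients × 12 matrix of nominal
   response codes (4 metrics × 3 consecutive intervals) is clustered
   agglomeratively under the Ward criterion with Euclidean distance,

   d(A,B) = √( 2·|A|·|B| / (|A|+|B|) · ‖x̄_A − x̄_B‖² ),

   updated by the Lance–Williams recurrence with deterministic node-id
   tie-breaking, and cut at k = 4.
3. **Cluster statistics** — cluster-by-category contingency tables with row
   percentages, Pearson χ² tests (no continuity correction), tie-corrected
   Kruskal–Wallis tests for continuous baseline covariates, and a raw
   p < 0.05 screen (Benjamini–Hochberg q-values reported alongside).
4. **CART feature importance** — a from-scratch Gini decision tree maps
   baseline phenotype features (demographics, labs, sensitization,
   genotypes, baseline lung function/FENO, medication use) onto the four
   cluster labels; normalized impurity decreases rank the discriminants.

Because cohorts like this are rarely shareable, the package includes a
first-class synthetic-cohort generator that plants four recoverable
response archetypes (sizes 58/87/138/64 among 347 complete cases of 365
enrolled) with realistic per-archetype category distributions, baseline
covariate profiles, GLCCI1 rs37973 genotype frequencies, and a missingness
process — so every downstream stage is testable against known truth.

## Worked example

```bash
python examples/02_simulate_and_cluster.py
```

```
coded matrix: 347 patients x 12 response features
cluster sizes at k=4: [58, 64, 87, 138]
adjusted Rand index vs planted archetypes: 1.000
advisory k from the merge-gap heuristic: 4
```

A noise-free default cohort is simulated, its visit trajectories are graded
and encoded, and Ward + a k = 4 cut recovers the planted archetypes
*exactly* (ARI 1.0) with the study's cluster sizes. Adding category noise
degrades recovery gracefully (ARI ≈ 0.9 at 5 % noise).

The other examples cover response grading on a single patient
(`01_classify_responses.py`), cluster statistics (`03…`), the CART
discriminant ranking (`04…`, which ranks baseline MEF50 % predicted top on
the default cohort), and the full pipeline (`05…`).

The same pipeline is scriptable from the shell:

```bash
phenoresp simulate --seed 1 --out cohort
phenoresp run-all --visits cohort/visits.csv \
    --baselines cohort/baselines.csv --out results --seed 1
```

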