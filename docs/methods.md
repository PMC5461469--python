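# Methods

This note documents the models, conventions and design choices behind
`oratox`, in the spirit of a statistical software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and aggregation

A study row is `(substance_id, endpoint, guideline, klimisch, key_study,
read_across, value, qualifier)` with values in mg/kg body weight. The
guideline constrains the endpoint (TG 401/420/423/425 ⇔ acute oral LD50;
TG 407 ⇔ 28-day NOAEL; TG 408 ⇔ 90-day NOAEL; `other` is unrestricted).
No unit conversion is attempted: a value in other units is an input
error, not a heuristic.

A substance's endpoint value is the **arithmetic mean** of the studies
passing a `SelectionRule` (Klimisch ceiling, guideline set, key-study /
read-across flags). A geometric-mean option exists but is not the
default. Censored results ("≥ 2000") enter the mean at their bound; the
qualifier column preserves the censoring for audit. When several key
studies disagree about censoring direction there is no principled
reconciliation; the qualifier column keeps the conflict visible rather
than resolving it silently.

The toxicant label is strict: mean LD50 < 2,000 mg/kg b.w.; exactly
2,000 is non-toxicant. All downstream 2×2 conventions follow from this:
LD50 ≥ 2,000 is the negative class, NOAEL ≤ 200 mg/kg is the
"predict-toxic" row of the screening rule, and a 90-day NOAEL of exactly
one third of the 28-day NOAEL counts as *within* the factor-3 limit.

The hazard-prevalence percent is positive/(positive+negative) × 100 at
one decimal ("negative" = conclusive but not sufficient for
classification); the oral non-toxic complement is 100 minus the sum of
the four **rounded** per-hazard percents (H300–H303), matching the
convention of quoting each hazard at one decimal.

## Similarity graph and modules

Tanimoto similarity is computed over equal-length binary fingerprints;
the similarity of two empty fingerprints is an error, never silently 0.
The graph connects pairs with similarity ≥ 0.7 (configurable). Module
detection is greedy multi-level (Louvain) modularity maximization at
resolution 1 on the **unweighted** thresholded graph — the analysis
thresholds first and clusters second, so edge weights would mostly
re-encode the threshold; weighted clustering is not offered as a default
because the unweighted reading is the one the module counts below were
calibrated against. Eight seeded restarts are run and the partition with
the highest Q is kept, where Q is scored by an independent closed-form
implementation of Newman–Girvan modularity (Σ_c [e_c/m − (d_c/2m)²]);
on small graphs this reliably reaches the exhaustive-search optimum (a
test enumerates all partitions of ≤ 8-node graphs). Isolated nodes
become singleton modules; an edgeless graph yields the all-singleton
partition with Q = 0 and a warning. Module ids are contiguous from 0,
largest module first, ties by smallest member id, so outputs are stable
across runs.

## KNN classifier

Candidate neighbors are the reference substances with similarity ≥ the
threshold (threshold-first); the k = 5 most similar candidates vote and
the majority wins. Fewer than k candidates still vote; an exact tie (only
possible with an even candidate count below k) resolves to the
configured tie rule, default non-toxicant — the majority class. Zero
candidates means the query is outside the applicability domain
(`in_domain = False`) and the tie rule decides. The query itself is
always excluded from its own reference set: including a similarity-1.0
self-match would leak the label being predicted. Similarity ties at the
k-th rank break by ascending substance id for determinism.

## Supervised models

**Class weights.** Toxicants are weighted n_negative/n_positive (exact
mode equalizes the class totals to machine precision; "paper" mode
rounds the factor to 2 decimals, giving 2.95 for a 268/791 split, and is
what the pipeline uses for its reports).

**Decision tree.** scikit-learn's weighted tree with entropy splits,
default depth 2 — deep enough to express "toxic iff the KNN feature is
positive; otherwise non-toxic when bond polarizability is high", the
two-feature rule family this model exists to illustrate.

**Perceptron.** One hidden sigmoid layer and two sigmoid output units
(column 1 = toxicant; prediction is the larger output), trained by
weighted per-instance stochastic gradient descent on squared error with
momentum. Defaults are pinned numerically so "default parameters" is
reproducible without reference to any toolkit: hidden =
⌈(n_features + 2)/2⌉, learning rate 0.3, momentum 0.2, 500 epochs,
uniform(−0.5, 0.5) initialization from the seed. Instances are visited
in data order each epoch, so training is bit-deterministic under
(data, seed). Features are standardized to zero mean/unit variance on
the training data (descriptors span orders of magnitude; training is
unstable otherwise) and the statistics travel with the model. The inner
loop is JIT-compiled when numba is importable; a pure-numpy twin applies
identical updates (a test asserts the two paths produce equal weights).

**KNN feature hygiene.** For training rows the KNN column is computed
leave-self-out. Inside cross-validation and leave-one-out it is
recomputed against the training fold only (`knn_mode="fold"`), which is
stricter than computing it once globally; the global variant remains
available as `knn_mode="global"` for comparison with analyses that did
not re-fold the feature.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), BAC = their mean, as
percentages. A scope with no observed positives has undefined
sensitivity; by report convention its BAC falls back to the specificity,
with an `undefined_sensitivity` flag retained so the fallback is
auditable. Cross-validation uses stratified folds (class proportions
preserved to ±1 instance), reweights inside each training fold, and
pools the held-out confusion counts (micro pooling conserves counts;
per-fold macro averages are also kept). Leave-one-out trains n models
and warns above a size threshold. Per-module tables restrict to
graph-resident substances and close with an ALL row that is the
column-wise sum of the module rows.

## Feature importance

The dataset is partitioned into 100 subsets (sizes and per-subset class
counts within ±1 of each other) by dealing shuffled positives, then
negatives, round-robin. **Ranker**: per-subset information gain in bits,
H(y) − H(y | x) with continuous features discretized by Fayyad–Irani MDL
binning within the data being scored (a feature the MDL criterion
refuses to split carries zero gain); reported as mean ± sd across
subsets. **WrapperEval**: 100 hold-one-subset-out iterations of greedy
forward selection (≤ 5 features) with a depth-3 entropy tree; candidate
subsets are scored on an internal stratified 75/25 validation split of
the 99 training subsets — the convention of wrapper subset evaluators,
which score on training data; scoring on the ~10-row held-out subset
itself (available as `mode="holdout"`) is so noisy that selection
frequencies become nearly uninformative. A removal-impact variant
(`mode="removal"`) scores a feature by how often deleting it reduces
held-out accuracy. Ties break toward higher training accuracy, then
lower feature index, keeping runs deterministic.

## Synthetic dossier generator

The generator emulates the statistical features the analyses rely on;
its defaults are the study conditions of the modeled corpus.

* **Fingerprints.** Each of the 9 modules owns a disjoint block of core
  bits (block size L/(2·modules), at least 8) in a 256-bit fingerprint.
  A member drops each core bit with rate μ and gains non-core bits at a
  rate that keeps the expected popcount constant; the expected pairwise
  within-module Tanimoto is then (1−μ)²/(1−μ²+2μ), so μ is solved from
  the requested similarity (default 0.9) with a 0.85 safety factor.
  Requests at or below the random-overlap floor K/(2L−K) are rejected.
  Disjoint cores keep between-module similarity near zero, far below the
  0.7 edge threshold.
* **Toxicity.** Exactly round(n × prevalence) toxicants (default
  268/1059). With clustering strength c, a fraction c of them fills
  whole modules (chosen in seeded shuffled order while they fit the
  budget, so full clustering yields label-pure toxic modules); the rest
  scatters uniformly, so c = 0 makes labels independent of modules.
  Latent log10-LD50 is truncated-normal on the correct side of 2,000:
  toxicants around 316 mg/kg (sd 0.35 dex), non-toxicants around 3,550
  (sd 0.30 dex).
* **Acute studies.** 1–3 studies per substance; guideline drawn with
  TG 401 dominant (0.76/0.11/0.11/0.02); study values are truncated
  draws around the latent value (sd 0.12 dex) that never cross the
  class boundary, then snapped with probability 0.5 to the nearest
  same-side dose-grid value ({5, 50, 300, 2000} for the fixed-dose
  guideline, plus 5,000 for the others), producing the pile-ups at
  2,000/5,000; limit-dose results carry a ≥ qualifier with probability
  0.7. Every substance has a Klimisch-1 key study; extra studies draw
  Klimisch 1–4 (0.4/0.3/0.2/0.1) and are read-across with probability
  0.1. Because noise and snapping preserve the latent class, the
  realized prevalence equals the constructed count by construction.
* **Repeated-dose block.** The 28-day log-NOAEL is drawn around 200
  mg/kg/day (sd 0.6 dex) conditioned on the > 200 screening category
  (P = 0.63); the 90-day value follows the conditional normal with
  correlation 0.7 and a −0.15 dex shift (the 90-day marginal sits low).
  When the 28-day NOAEL is ≥ 1,000, the 90-day high/low category is
  resampled to hit P(high 90d | high 28d) = 0.70 (skipped at correlation
  exactly 1, which degenerates to equal pairs). A 2% fraction of pairs
  is overwritten with 90d = 10 × 28d to emulate the grossly discordant
  registrations worth flagging. The acute class is drawn conditional on
  the screening category so the 200 mg/kg rule has NPV 0.945 and PPV
  0.337 in expectation. Because this couples acute toxicity to NOAELs
  rather than to structure, the pipeline keeps two cohorts: a modeling
  cohort (module-driven acute labels) and a concordance cohort
  (NOAEL-coupled acute labels).
* **Hazard flags.** H300–H303 follow the GHS dose bands (≤ 50,
  50–300, 300–2,000, 2,000–5,000 mg/kg) of the latent LD50; the
  aspiration hazards H304/H305 are rare positives with a high
  data-lacking rate; every flag is masked to data_lacking (5%) or
  inconclusive (1%).
* **Streams.** One child RNG stream per artifact (fingerprints,
  toxicity, descriptors, acute, repeated, hazards) is split from the
  master seed, so generating a later artifact never perturbs an earlier
  one.

What the generator does **not** emulate: real substructure chemistry
(fingerprints are abstract bit sets), inter-guideline bias in LD50
extrapolation, natural-language result fields, correlated missingness,
or the long-tailed module-size distribution of a real similarity map.
Passing tests therefore demonstrate that the *algorithms* behave as
specified under the assumed structure, not that the models would reach
any particular accuracy on real registrations.

## Problem sizes

The default pipeline runs the full 1,059-substance dataset (graph, KNN,
models, 10-fold CV, 100-subset importance) in well under two minutes on
one CPU. The test suite uses smaller simulations chosen to keep the whole
run fast while leaving the asserted effects far from their thresholds:
240–270 substances for module recovery and model behavior, 20 seeds ×
1,000 substances for the independence and chance-level nulls, 2,000–5,000
substances for the NOAEL coupling calibrations, 10 seeds × 60 substances
for the leave-one-out sensitivity comparison, and a 20-subset importance
protocol. Leave-one-out in the pipeline is off by default
(`loo_subsample` enables it on a seeded subsample).

## Known limitations

* The perceptron is a faithful small SGD network, not a modern
  classifier; it exists to study feature fusion, not to maximize
  accuracy.
* Wrapper importance counts are nearly deterministic across iterations
  (99% of the training data is shared), so they polarize toward 0 or
  100; the Ranker sd is the better dispersion measure.
* The guideline-agreement diagonal needs ≥ 2 studies under the same
  guideline per substance and is therefore sparse on small synthetic
  datasets.
* Hazard-prevalence percentages are reported at one decimal; the
  non-toxic complement is defined over the rounded per-hazard percents,
  so it can differ by 0.1 from the complement of the unrounded sum.
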