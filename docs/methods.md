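# Methods

## Problem setting

Each record is one cardiopulmonary-bypass operation on a pediatric patient:
five structured covariates (gender, age in months, height, weight, operation
length in minutes), two standardized-code text fields (`diagnosis`,
`operation`; `';'`-separated, first code primary), optional expert cluster
labels per field, and postoperative measurements (serum creatinine, hourly
urine output over 48 h). The prediction target is severe acute kidney
injury, defined below.

## AKI outcomes and KDIGO staging

Five outcomes are derived per record: the postoperative/baseline creatinine
ratio; hours (of 48) with urine output strictly below 0.5 and below 0.3
ml/kg/h; the KDIGO ordinal stage; and the severe-AKI indicator. The ordinal
stage is the maximum of a creatinine stage and a urine-output stage:

| stage | creatinine ratio | urine output |
|---|---|---|
| 1 | [1.5, 2.0) | more than 6 and fewer than 12 h below 0.5 |
| 2 | [2.0, 3.0) | ≥ 12 h below 0.5 |
| 3 | ≥ 3.0 | ≥ 24 h below 0.3 |

Severe AKI = stage 2 or 3. Boundary conventions are explicit choices: the
stage-1 ratio band is read as the half-open interval [1.5, 2.0) so that it
abuts the stage-2 lower bound with no gap at 1.9–2.0, and the stage-1 urine
rule is the open interval (6, 12) h ("more than 6, less than 12"). The
guideline's anuria-based stage-3 criterion is not modelled. The cutoffs live
in a single editable table (`outcomes.KDIGO_STAGE_RULES`).

## Embeddings

All embedders satisfy one contract: a list of raw field strings maps to an
n × d matrix with an honest `normalized` flag (unit L2 rows). Spherical
clustering refuses input whose flag is false, and the flag is validated
against actual row norms at construction.

* **Bag-of-Terms (BoT)** — one binary indicator per vocabulary code;
  duplicates are impossible by construction (fields are parsed to
  duplicate-free code sequences). BoT is deliberately *not* normalized: the
  L1 norm (number of codes) is clinically informative, so BoT is clustered
  with standard k-means rather than spherical.
* **Hash embedder** — each code maps, via a seeded keyed hash, to a fixed
  random unit vector in d dimensions; a field embeds as the normalized sum
  over its codes. It is the offline stand-in for large-language-model
  embedders: deterministic, dependency-free, and it propagates code-usage
  cluster structure into cosine geometry. Default d = 1536 matches the
  output width of the commercial embedders it stands in for; at much
  smaller d, hash-collision cross-talk (code vectors have mutual coherence
  ~1/√d) drowns the code-overlap signal, which is weak per row because
  records carry only 1–6 codes. The hash embedder is order-free by design —
  a documented difference from contextual LLM embedders, which also exploit
  code order and semantics.
* **Doc2Vec adapter** — exposes the dbow/dm variant, epochs and dimension
  hyperparameters and trains on the corpus itself; optional (requires
  gensim) and raises a capability-missing error otherwise.
* **External adapters** — any callable registered under a name serves
  `kind="external-adapter"` specs; the core makes no network calls.

Concatenated two-field embeddings are re-normalized (the concatenation of
two unit vectors has norm √2); this restores cosine geometry and is the
package's explicit choice where conventions differ.

## Spherical k-means

Lloyd iteration under cosine distance: assign each point to the nearest
centroid (ties to the lowest index), update each centroid as the member
mean re-normalized to the unit sphere (standard mode uses the plain mean
and squared Euclidean distance). Empty clusters are re-seeded with the
point farthest from its current centroid, keeping k fixed. Iteration stops
when assignments stabilize or after 300 iterations. Restarts are seeded
from a master seed via spawned seed sequences; the best of `n_init`
restarts by total within-cluster distance is returned. On unit-norm data
squared Euclidean distance to a unit centroid equals twice the cosine
distance, so the two metrics give identical assignments for fixed
centroids; the algorithms still differ through the centroid update.

Soft membership — the feature block used downstream — is the full n × k
matrix of mode-distances to the centroids, computed with the clustering's
own metric (cosine in spherical mode); held-out rows are projected onto
training centroids the same way.

## Partition metrics and protocols

ARI and AMI are implemented from their contingency-table formulas. AMI uses
the permutation-model (hypergeometric) expected mutual information and
**max-normalization**, stated explicitly because AMI has variants; the test
suite pins both metrics to scikit-learn (`average_method="max"`) to 1e-6.
The contingency table is canonically oriented before the AMI sums so that
`ami(a, b) == ami(b, a)` bitwise; partitions identical up to relabeling
short-circuit to exactly 1.0.

Cluster ids across runs are aligned greedily: repeatedly match the
(A-cluster, B-cluster) pair sharing the most members among unmatched
clusters, ties toward the lowest (A-id, B-id), until one side exhausts.
Greedy matching is not always optimal; the test suite carries a constructed
counterexample documenting the gap.

Two protocols wrap these metrics: *consistency* (repeated best-of-n
clusterings scored against expert labels, k defaulting to the expert
cluster count to remove the cluster-count confound; mean and t-based 95% CI
across runs) and *stability* (all run pairs scored with ARI/AMI and
greedy-mapped member overlap, every run also aligned to run 0 for label
comparison).

## Predictive benchmark

Baseline features: male indicator, age, residual height, BMI, operation
minutes. Residual height is the percent deviation of height from a
per-gender LOESS (degree 1, span 0.75) of height on age, requiring ≥ 30
rows per gender; an optional fit mask restricts the smoother to training
rows so held-out rows never influence it. Expert variants append one-hot
expert labels for one field; AI variants append the soft-membership block
(k = 10 by default, matching the predictive protocol; n_init = 100).

Cross-validation uses scikit-learn's `RepeatedKFold` (unstratified) with a
fixed master seed; fold memberships are computed once and shared by every
model variant, making paired per-fold tests valid. By default clustering is
fit **once on the full cohort before CV** (`cluster_scope="global"`),
matching the protocol of generating a single set of clusters; this lets
test-fold rows influence the centroids and is therefore mildly
leakage-prone — `cluster_scope="per-fold"` refits the clustering on each
fold's training rows and projects test rows onto those centroids for a
strictly leak-free variant.

Per-field models (logistic regression on standardized features by default;
random forest selectable) produce probabilities that are averaged across
fields; ensembles are weighted averages of member probabilities, with
(2, 1) for a two-AI-model ensemble and an expert weight of one tenth of
the lead weight when added. A single-class training fold yields a constant
prediction at the class rate and is logged as degenerate.

Metrics: ROC-AUC threshold-free; accuracy, precision, F1, sensitivity and
specificity computed at cutoffs 0.1–0.9 (positive iff probability ≥
cutoff, an explicit convention) and averaged. Precision (and F1) with zero
predicted positives contributes 0 to the average — this depresses averaged
precision/F1 at extreme thresholds and is the package's documented
convention. Model comparisons are paired t-tests on per-(repeat, fold)
metric differences; identical models return t = 0 with p = 1 (two-sided)
rather than the undefined 0/0 statistic.

## Explainability

Clusters are labeled by grouping member code strings under "Group N:"
headings in a deterministic prompt (preamble states row count, fields and
group count; member lines render "Operations: ... || Diagnoses: ...").
Responses must be structured JSON (`group_number`, `short_label`,
`long_label`; exactly one entry per group) and are validated with pydantic.
A deterministic stub labeler — each cluster labeled by its three most
over-represented codes by lift — keeps the pipeline runnable offline and
doubles as a useful fallback. Labels from multiple runs are aligned to run
0 via the greedy mapping. A blind comparison prompt presents two
partitions of the same rows as "Partition 1"/"Partition 2" with no
provenance.

Cluster–outcome association uses Kendall's tau-b (ties are inevitable with
binary membership indicators) between each cluster's indicator and each of
the five outcomes, with Bonferroni adjustment at m = outcomes × clusters
(50 at the default 5 × 10). Constant outcomes report missing tau with a
note rather than a spurious zero.

## Synthetic cohort generator

The generator emulates the *shape* of a real pediatric CPB cohort, not
medical code semantics. Defaults mirror the motivating study's scale: 780
operations, 282/179-code vocabularies, 1–6 codes per field, 26% severe-AKI
prevalence, ages 0.1–188.3 months, operation times log-normal around 86
minutes.

* **Latent structure.** Each of k clusters owns a private ⌊vocab/k⌋-code
  subvocabulary per field; a row draws each code from its cluster's subset
  with probability `cluster_separation`, else uniformly from the whole
  vocabulary. The diagnosis field always follows the row's latent cluster;
  the operation field follows it with probability `field_correlation`
  (default 0.8), giving correlated-but-distinct field structure so that
  matched-field expert agreement exceeds crossed-field agreement.
* **Covariates.** Heights follow a saturating growth curve (50 + 120·(1 −
  e^(−age/60)) cm, small male multiplier) with multiplicative log-normal
  noise of scale `noise_sd` (default 0.07, giving residual-height spread
  comparable to real cohorts); weights derive from log-normal BMI around
  15.3; ages are log-uniform.
* **Outcomes.** Severity is Bernoulli with logistic probability in a
  per-cluster log-odds offset plus `optime_effect` per operation minute;
  the intercept is solved by bisection on the realized linear predictors so
  the analytic prevalence equals `target_prevalence` exactly. The ordinal
  stage is drawn conditionally on severity (stage splits 315:266 within
  non-severe and 121:78 within severe, matching the motivating cohort's
  ordinal distribution), a creatinine or urine "driver" is chosen at
  random, and measurements are constructed so the staging rules recover
  the drawn stage exactly: the creatinine ratio is sampled within the
  driver stage's band, and the 48-hour urine series places a contiguous
  low-output block realizing the target hours-below counts, with remaining
  hours gamma-distributed around a mean depressed for high-stage rows.
* **Expert labels.** Noisy copies of the field's driving cluster
  (`expert_label_noise` fraction of rows relabeled uniformly), emulating
  imperfect expert/algorithm agreement.

Determinism: all randomness flows from `SimConfig.seed` through spawned
seed sequences; identical configs produce byte-identical serialized
cohorts (TSV with JSON-encoded urine series, plus a JSON sidecar carrying
the config and true cluster ids).

**What passing tests do and do not show.** The generator plants cluster
signal directly in code co-occurrence, so recovery results demonstrate
that the pipeline's geometry, clustering and CV plumbing are correct — not
that any embedder captures real clinical semantics, code order, or the
rich confounding of real EHR data. Absolute benchmark numbers on synthetic
cohorts are not comparable to results on real cohorts.

## Problem sizes and numerical choices

Recovery and CV experiments in the test suite run at n = 1000, k = 4,
separation 0.9, 20 × 10 cross-validation — sizes at which the planted
signal is comfortably detectable while the full suite stays fast. The
exhaustive clustering oracle enumerates all partitions for n ≤ 10, k ≤ 3
and tolerates rare local optima (≥ 95/100 instances must match to 1e-9).
Convergence, tie-break and degenerate-input rules: ties to the lowest
cluster index; empty clusters re-seeded; zero-norm spherical centroid
updates retain the previous centroid; zero embedding rows refuse
normalization (naming the row); fields parsing to no codes embed as a
fixed null unit vector with a warning.

## Known limitations

* The hash embedder ignores code order and semantics; it cannot reproduce
  contextual-embedding effects.
* Global (pre-CV) clustering is mildly optimistic; use
  `cluster_scope="per-fold"` for strict out-of-sample claims.
* The urine-output series is hourly and regular; irregular sampling and
  anuria are not modelled.
* Greedy cluster alignment can be suboptimal when a large overlap cell
  blocks a better global matching.
* LOESS residual height assumes enough rows per gender (≥ 30) for a
  stable smooth.
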