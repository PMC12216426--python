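# ehrclust

Feature engineering and benchmarking toolkit for predicting **acute kidney
injury (AKI) after pediatric cardiopulmonary bypass (CPB)** from standardized
EHR text fields.

In pediatric cardiac surgery, each operation record carries two short text
fields — *diagnosis* and *operation* — each an ordered, `';'`-separated list
of standardized medical codes, the first being primary. `ehrclust` turns
those fields into predictive features and interpretable patient groups:

1. **Embed** each field: Bag-of-Terms binary indicators, a deterministic
   hashing embedder (bag-of-codes composition of fixed random unit vectors),
   an optional gensim Doc2Vec adapter, or any external embedding backend
   registered behind the same contract.
2. **Cluster** the embedding with *spherical k-means*, a k-means variant
   that replaces squared Euclidean distance with cosine distance

   $$D_C(\mathbf{x},\mathbf{y}) = 1 - \frac{\mathbf{x}^\top\mathbf{y}}
   {\lVert\mathbf{x}\rVert\,\lVert\mathbf{y}\rVert},$$

   re-normalizing centroids to the unit sphere at each update, with
   best-of-`n_init` restart selection. Bag-of-Terms vectors keep their
   informative L1 norm and are clustered with standard k-means instead.
3. **Predict** severe AKI (KDIGO stage ≥ 2) with classifiers that add each
   record's *soft cluster membership* — its vector of distances to the k
   centroids — to five structured baseline covariates (gender, age, residual
   height, BMI, operation length). One model per text field; the two
   probabilities are averaged, and model families are compared under
   repeated k-fold cross-validation with threshold-averaged metrics and
   paired t-tests. Weighted-average ensembles combine AI, expert and
   baseline models.
4. **Explain** clusters by reverse mapping: group the original code strings
   by cluster and build a labeling prompt for a text-generating model (a
   deterministic lift-based stub labeler works offline), align labels across
   clustering runs by greedy member-overlap matching, and rank-correlate
   cluster membership with five AKI outcomes (Kendall tau-b, Bonferroni
   adjusted over outcomes × clusters tests).

Cluster quality and stability are quantified with owned implementations of
the **adjusted Rand index** and **adjusted mutual information**
(permutation-model expected MI, max-normalization), cross-checked against
scikit-learn in the test suite.

Because no public cohort of this kind exists, the package ships a
first-class synthetic cohort generator with planted latent cluster
structure, calibrated severe-AKI prevalence (26% by default) and KDIGO-exact
outcome measurements, so that every pipeline stage can be tested against
known ground truth.

## Worked example

```python
import ehrclust as ec

cfg = ec.SimConfig(n_patients=1000, n_latent_clusters=4,
                   cluster_separation=0.9, outcome_effects={0: 2.0}, seed=1)
cohort = ec.generate(cfg)
outcomes = ec.outcomes_table(cohort.cohort)
print("severe-AKI prevalence:", round(outcomes.kdigo_binary.mean(), 3))

X = ec.hash_embed(cohort.cohort.diagnosis.tolist(), 1536, 1)
clusters = ec.spherical_kmeans(X, k=4, n_init=20, seed=2)
print("recovery ARI:",
      round(ec.adjusted_rand_index(clusters.assignment, cohort.true_cluster), 3))

spec = ec.EmbedderSpec(name="hash", kind="hash", dimension=1536)
report = ec.run_repeated_cv(
    cohort.cohort, outcomes.kdigo_binary.to_numpy(),
    [ec.ModelVariant(name="baseline", kind="baseline"),
     ec.ModelVariant(name="ai:hash", kind="ai", embedder=spec, k=4, n_init=20)],
    ec.CVConfig(repeats=5, folds=10, master_seed=3),
)
print(ec.summarize_cv_report(report).round(3).to_string(index=False))
t, p = ec.paired_fold_ttest(report, "ai:hash", "baseline", side="greater")
print(f"paired t = {t:.2f}, one-sided p = {p:.2e}")
```

Output:

```
severe-AKI prevalence: 0.26
recovery ARI: 0.857
   model  roc_auc  accuracy  sensitivity  specificity
 ai:hash    0.723     0.679        0.335        0.802
baseline    0.547     0.629        0.242        0.765
paired t = 22.46, one-sided p = 9.48e-28
```

The cohort is generated with one high-risk latent cluster (log-odds +2) and
26% overall severe-AKI prevalence. Spherical k-means on hash embeddings of
the diagnosis field recovers the planted partition (ARI 0.86), and adding
the soft-membership features lifts the cross-validated ROC-AUC from 0.55
(structured covariates only) to 0.72, a difference the paired t-test on
matched folds finds decisive. Accuracy, sensitivity and specificity are
averages over probability cutoffs 0.1–0.9, so their absolute values run
lower than at a tuned threshold.

A thin CLI covers the two batch entry points:

```bash
ehrclust simulate --n 780 --clusters 10 --seed 0 --out cohort.tsv
ehrclust cv-benchmark --cohort cohort.tsv --variants baseline,expert,ai:hash \
    --repeats 250 --folds 10 --seed 0 --out cv/
```

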