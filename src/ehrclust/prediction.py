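"""Predictive benchmarking of severe-AKI classifiers.

Model families compared under repeated k-fold cross-validation:

* ``baseline`` — structured covariates only: gender indicator, age,
  residual height (percent deviation from a per-gender LOESS of height
  on age), BMI, operation length;
* ``expert`` — baseline plus one-hot expert cluster labels, one model
  per text field, predicted probabilities averaged across fields;
* ``ai`` — baseline plus the soft cluster-membership block (distances
  to the k spherical-k-means centroids of a text embedding), again one
  model per field with probabilities averaged;
* weighted-average ensembles of the above.

Metrics follow the threshold-averaging protocol: ROC-AUC is
threshold-free; accuracy, precision, F1, sensitivity and specificity
are computed at each probability cutoff 0.1, 0.2, ..., 0.9 (positive
iff probability >= cutoff) and averaged.  Precision with zero
predicted positives contributes 0 to the average, with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.nonparametric.smoothers_lowess import lowess

from .clustering import ClusteringResult, soft_membership, spherical_kmeans
from .embedding import EmbedderSpec, EmbeddingMatrix, embed

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))
METRIC_NAMES = ("roc_auc", "accuracy", "precision", "f1", "sensitivity", "specificity")
MIN_ROWS_PER_GENDER = 30


def compute_bmi(weight_kg: float, height_m: float):
    """Body-mass index, kg / m^2."""
    weight_kg = np.asarray(weight_kg, dtype=np.float64)
    height_m = np.asarray(height_m, dtype=np.float64)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def residual_height(
    heights,
    ages,
    genders,
    fit_mask=None,
    frac: float = 0.75,
) -> np.ndarray:
    """Percent deviation of height from a per-gender LOESS of height on age.

    ``fit_mask`` restricts the smoother fit to a subset of rows (the
    training rows of a CV fold) while still producing residuals for all
    rows, so held-out rows never influence the smooth.
    """
    heights = np.asarray(heights, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    genders = np.asarray(genders)
    mask = np.ones(len(heights), dtype=bool) if fit_mask is None else np.asarray(fit_mask)
    residuals = np.empty(len(heights))
    for g in np.unique(genders):
        sel = genders == g
        fit_sel = sel & mask
        if fit_sel.sum() < MIN_ROWS_PER_GENDER:
            raise ValueError(
                f"need >= {MIN_ROWS_PER_GENDER} rows to fit the {g!r} growth curve, "
                f"got {int(fit_sel.sum())}"
            )
        smooth = lowess(
            heights[fit_sel], ages[fit_sel], frac=frac, xvals=ages[sel], is_sorted=False
        )
        residuals[sel] = (heights[sel] - smooth) / smooth
    return residuals


@dataclass
class FeatureBlock:
    """Named feature matrix with provenance."""

    matrix: np.ndarray
    names: list[str]
    provenance: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("feature matrix/name mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing values")

    def hstack(self, other: "FeatureBlock") -> "FeatureBlock":
        return FeatureBlock(
            matrix=np.hstack([self.matrix, other.matrix]),
            names=self.names + other.names,
            provenance=f"{self.provenance}+{other.provenance}",
        )


def baseline_features(cohort: pd.DataFrame, fit_mask=None) -> FeatureBlock:
    """The five structured covariates."""
    height_m = cohort["height_cm"].to_numpy() / 100.0
    bmi = compute_bmi(cohort["weight_kg"].to_numpy(), height_m)
    resid = residual_height(
        cohort["height_cm"].to_numpy(),
        cohort["age_months"].to_numpy(),
        cohort["gender"].to_numpy(),
        fit_mask=fit_mask,
    )
    matrix = np.column_stack(
        [
            (cohort["gender"].to_numpy() == "male").astype(float),
            cohort["age_months"].to_numpy(),
            resid,
            bmi,
            cohort["operation_minutes"].to_numpy(),
        ]
    )
    return FeatureBlock(
        matrix=matrix,
        names=["gender_male", "age_months", "residual_height", "bmi", "operation_minutes"],
        provenance="baseline",
    )


def expert_onehot_features(cohort: pd.DataFrame, field: str) -> FeatureBlock:
    labels = cohort[f"expert_{field}"].to_numpy()
    levels = np.unique(labels)
    matrix = (labels[:, None] == levels[None, :]).astype(float)
    return FeatureBlock(
        matrix=matrix,
        names=[f"expert_{field}_{lv}" for lv in levels],
        provenance=f"expert-onehot:{field}",
    )


def soft_membership_features(
    X: EmbeddingMatrix, clustering: ClusteringResult, field: str
) -> FeatureBlock:
    soft = soft_membership(X, clustering)
    return FeatureBlock(
        matrix=soft,
        names=[f"soft_{field}_{j}" for j in range(clustering.k)],
        provenance=f"soft-membership:{field}",
    )


def assemble_features(
    cohort: pd.DataFrame,
    variant: str,
    field: str | None = None,
    clustering: ClusteringResult | None = None,
    embedding: EmbeddingMatrix | None = None,
    fit_mask=None,
) -> FeatureBlock:
    """Feature block for one model variant.

    ``baseline`` needs only the cohort; ``expert`` additionally a text
    field; ``ai`` a field plus its clustering and embedding (soft
    memberships are distances of each row's embedding to the fitted
    centroids).
    """
    base = baseline_features(cohort, fit_mask=fit_mask)
    if variant == "baseline":
        return base
    if field is None:
        raise ValueError(f"variant {variant!r} requires a text field")
    if variant == "expert":
        return base.hstack(expert_onehot_features(cohort, field))
    if variant == "ai":
        if clustering is None or embedding is None:
            raise ValueError("ai variant requires a clustering and an embedding")
        return base.hstack(soft_membership_features(embedding, clustering, field))
    raise ValueError(f"unknown variant {variant!r}")


_CLASSIFIERS = {
    "logistic": lambda seed: make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000)
    ),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=200, random_state=seed
    ),
}


def fit_predict_binary(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    classifier: str = "logistic",
    seed: int = 0,
):
    """Fit the named classifier and return positive-class probabilities
    for the test rows.

    A single-class training fold is recorded as degenerate and yields a
    constant prediction at the training class rate.
    """
    train_y = np.asarray(train_y)
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    if len(np.unique(train_y)) < 2:
        logger.warning("degenerate single-class training fold; constant prediction")
        return np.full(test_X.shape[0], float(train_y.mean())), None
    model = _CLASSIFIERS[classifier](seed)
    model.fit(train_X, train_y)
    return model.predict_proba(test_X)[:, 1], model


def average_field_models(p_diagnosis, p_operation):
    """Elementwise mean of the two per-field model probabilities."""
    p_diagnosis = np.asarray(p_diagnosis, dtype=np.float64)
    p_operation = np.asarray(p_operation, dtype=np.float64)
    if p_diagnosis.shape != p_operation.shape:
        raise ValueError("probability vectors must have equal length")
    return (p_diagnosis + p_operation) / 2.0


def ensemble_predict(model_probabilities: Sequence, weights: Sequence[float]):
    """Weighted average of constituent model probabilities.

    Default framework weights: AI ensemble (2, 1); AI + expert
    (2, 1, 0.2), the expert weight being one tenth of the lead model's.
    """
    probs = [np.asarray(p, dtype=np.float64) for p in model_probabilities]
    weights = np.asarray(weights, dtype=np.float64)
    if len(probs) != len(weights):
        raise ValueError("one weight per model required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    n = probs[0].shape[0]
    if any(p.shape[0] != n for p in probs):
        raise ValueError("probability vectors must have equal length")
    return np.average(np.vstack(probs), axis=0, weights=weights)


def threshold_averaged_metrics(
    probabilities, labels, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict:
    """ROC-AUC plus threshold-averaged classification metrics.

    A record is called positive iff its probability >= threshold.
    Precision (and F1) at a threshold with no predicted positives
    contributes 0 to the average.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    pos = labels == 1
    neg = ~pos
    record = {name: 0.0 for name in METRIC_NAMES}
    record["roc_auc"] = float(roc_auc_score(labels, probabilities))
    acc, prec, f1s, sens, spec = [], [], [], [], []
    for t in thresholds:
        pred = probabilities >= t
        tp = float(np.sum(pred & pos))
        fp = float(np.sum(pred & neg))
        tn = float(np.sum(~pred & neg))
        fn = float(np.sum(~pred & pos))
        acc.append((tp + tn) / labels.size)
        if tp + fp == 0:
            logger.debug("no predicted positives at threshold %.1f", t)
            p = 0.0
        else:
            p = tp / (tp + fp)
        prec.append(p)
        r = tp / (tp + fn)
        sens.append(r)
        spec.append(tn / (tn + fp))
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    record.update(
        accuracy=float(np.mean(acc)),
        precision=float(np.mean(prec)),
        f1=float(np.mean(f1s)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
    )
    return record


@dataclass(frozen=True)
class ModelVariant:
    """Declarative description of one benchmarked model.

    ``ai`` variants name an embedder and the fields whose per-field
    models are probability-averaged; ``k``/``n_init`` configure the
    spherical k-means producing the soft-membership features.
    """

    name: str
    kind: str  # baseline | expert | ai
    fields: tuple[str, ...] = ("diagnosis", "operation")
    embedder: EmbedderSpec | None = None
    k: int = 10
    n_init: int = 100
    mode: str = "spherical"

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "expert", "ai"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "ai" and self.embedder is None:
            raise ValueError("ai variant requires an embedder spec")


@dataclass(frozen=True)
class CVConfig:
    repeats: int = 250
    folds: int = 10
    master_seed: int = 0
    classifier: str = "logistic"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    cluster_scope: str = "global"  # global (pre-CV) or per-fold refit

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        t = np.asarray(self.thresholds)
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        if self.cluster_scope not in ("global", "per-fold"):
            raise ValueError("cluster_scope must be 'global' or 'per-fold'")


def parse_variant_token(token: str) -> ModelVariant:
    """Parse CLI-style tokens: ``baseline``, ``expert``,
    ``ai:hash`` or ``ai:hash:diagnosis``."""
    parts = token.split(":")
    if parts[0] == "baseline":
        return ModelVariant(name="baseline", kind="baseline")
    if parts[0] == "expert":
        fields = tuple(parts[1:]) or ("diagnosis", "operation")
        return ModelVariant(name=token, kind="expert", fields=fields)
    if parts[0] == "ai":
        if len(parts) < 2:
            raise ValueError("ai variant token needs an embedder name, e.g. ai:hash")
        from .embedding import DEFAULT_HASH_DIM

        dim = DEFAULT_HASH_DIM if parts[1] == "hash" else 0
        embedder = EmbedderSpec(name=parts[1], kind=parts[1], dimension=dim)
        fields = tuple(parts[2:]) or ("diagnosis", "operation")
        return ModelVariant(name=token, kind="ai", fields=fields, embedder=embedder)
    raise ValueError(f"cannot parse variant token {token!r}")


def _fit_field_probabilities(
    cohort: pd.DataFrame,
    labels: np.ndarray,
    variant: ModelVariant,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    base_all: FeatureBlock,
    global_artifacts: dict,
    config: CVConfig,
    fold_seed: int,
) -> np.ndarray:
    """Test-row probabilities for one variant in one fold (fields averaged)."""
    field_probs = []
    fields = variant.fields if variant.kind != "baseline" else (None,)
    for field in fields:
        if variant.kind == "baseline":
            block = base_all
        elif variant.kind == "expert":
            block = base_all.hstack(expert_onehot_features(cohort, field))
        else:
            X = global_artifacts[("embedding", variant.name, field)]
            if config.cluster_scope == "global":
                clustering = global_artifacts[("clustering", variant.name, field)]
                soft = soft_membership(X, clustering)
            else:
                train_X = EmbeddingMatrix(
                    values=X.values[train_idx],
                    row_ids=[X.row_ids[i] for i in train_idx],
                    normalized=X.normalized,
                )
                clustering = spherical_kmeans(
                    train_X, k=variant.k, n_init=variant.n_init,
                    seed=fold_seed, mode=variant.mode,
                )
                soft = soft_membership(X, clustering)
            block = base_all.hstack(
                FeatureBlock(
                    matrix=soft,
                    names=[f"soft_{field}_{j}" for j in range(clustering.k)],
                    provenance=f"soft-membership:{field}",
                )
            )
        probs, _ = fit_predict_binary(
            block.matrix[train_idx],
            labels[train_idx],
            block.matrix[test_idx],
            classifier=config.classifier,
            seed=fold_seed,
        )
        field_probs.append(probs)
    out = field_probs[0]
    for extra in field_probs[1:]:
        out = average_field_models(out, extra)
    return out


def run_repeated_cv(
    cohort: pd.DataFrame,
    labels,
    variants: Sequence[ModelVariant],
    config: CVConfig = CVConfig(),
    ensembles: dict[str, tuple[list[str], list[float]]] | None = None,
) -> pd.DataFrame:
    """Repeated k-fold CV with identical folds across all model variants.

    Returns the long-form CV report: one record per (repeat, fold,
    model) with the threshold-averaged metrics.  ``ensembles`` maps an
    ensemble name to (member variant names, weights); member
    probabilities are combined per fold before metrics are computed.

    With ``cluster_scope='global'`` (the default protocol) embeddings
    are clustered once on the full cohort before CV; ``'per-fold'``
    refits the clustering on each fold's training rows only and
    projects test rows onto the training centroids.
    """
    labels = np.asarray(labels)
    n = len(cohort)
    if labels.shape[0] != n:
        raise ValueError("labels must cover every cohort row")
    if not variants:
        raise ValueError("at least one model variant required")
    if n < config.folds:
        raise ValueError("fewer rows than folds")
    names = [v.name for v in variants]
    if len(set(names)) != len(names):
        raise ValueError("variant names must be unique")
    for ens_name, (members, weights) in (ensembles or {}).items():
        missing = set(members) - set(names)
        if missing:
            raise ValueError(f"ensemble {ens_name!r} references unknown variants {missing}")

    # global artifacts: embeddings always; clusterings when scope is global
    global_artifacts: dict = {}
    for variant in variants:
        if variant.kind != "ai":
            continue
        for field in variant.fields:
            X = embed(cohort[field].tolist(), variant.embedder)
            global_artifacts[("embedding", variant.name, field)] = X
            if config.cluster_scope == "global":
                global_artifacts[("clustering", variant.name, field)] = spherical_kmeans(
                    X, k=variant.k, n_init=variant.n_init,
                    seed=config.master_seed, mode=variant.mode,
                )

    splitter = RepeatedKFold(
        n_splits=config.folds, n_repeats=config.repeats, random_state=config.master_seed
    )
    records = []
    for split_idx, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        repeat, fold = divmod(split_idx, config.folds)
        fold_seed = (config.master_seed * 100003 + split_idx) % (2**31)
        base_all = baseline_features(cohort, fit_mask=np.isin(np.arange(n), train_idx))
        fold_probs: dict[str, np.ndarray] = {}
        for variant in variants:
            fold_probs[variant.name] = _fit_field_probabilities(
                cohort, labels, variant, train_idx, test_idx,
                base_all, global_artifacts, config, fold_seed,
            )
        for ens_name, (members, weights) in (ensembles or {}).items():
            fold_probs[ens_name] = ensemble_predict(
                [fold_probs[m] for m in members], weights
            )
        test_labels = labels[test_idx]
        for model_name, probs in fold_probs.items():
            if len(np.unique(test_labels)) < 2:
                logger.warning(
                    "single-class test fold (repeat %d fold %d); metrics skipped",
                    repeat, fold,
                )
                continue
            rec = threshold_averaged_metrics(probs, test_labels, config.thresholds)
            rec.update(repeat=repeat, fold=fold, model=model_name)
            records.append(rec)
    report = pd.DataFrame.from_records(records)
    return report[["repeat", "fold", "model", *METRIC_NAMES]]


def summarize_cv_report(report: pd.DataFrame) -> pd.DataFrame:
    """Model x metric table of CV means (the benchmark summary shape)."""
    return report.groupby("model")[list(METRIC_NAMES)].mean().reset_index()


def paired_fold_ttest(
    report: pd.DataFrame,
    model_a: str,
    model_b: str,
    metric: str = "roc_auc",
    side: str = "two-sided",
) -> tuple[float, float]:
    """Paired t-test on per-(repeat, fold) metric differences A - B.

    ``side='greater'`` tests improvement of A over B (one-sided).
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    a = report[report["model"] == model_a].set_index(["repeat", "fold"])[metric]
    b = report[report["model"] == model_b].set_index(["repeat", "fold"])[metric]
    if len(a) == 0 or not a.index.equals(b.index):
        raise ValueError("models must have matched (repeat, fold) records")
    diffs = a.to_numpy() - b.to_numpy()
    if np.allclose(diffs, 0.0):  # identical models: no evidence either way
        return 0.0, 1.0 if side == "two-sided" else 0.5
    res = stats.ttest_rel(a.to_numpy(), b.to_numpy(), alternative=side)
    return float(res.statistic), float(res.pvalue)
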