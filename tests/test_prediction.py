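import numpy as np
import pytest
from scipy import stats

from ehrclust import (
    CVConfig,
    EmbedderSpec,
    ModelVariant,
    average_field_models,
    assemble_features,
    compute_bmi,
    ensemble_predict,
    fit_predict_binary,
    paired_fold_ttest,
    residual_height,
    run_repeated_cv,
    spherical_kmeans,
    summarize_cv_report,
    threshold_averaged_metrics,
)
from ehrclust.embedding import hash_embed
from ehrclust.outcomes import outcomes_table
from ehrclust.prediction import parse_variant_token


class TestBMI:
    def test_arithmetic(self):
        assert compute_bmi(16.0, 1.0) == pytest.approx(16.0)
        assert compute_bmi(20.0, 2.0) == pytest.approx(5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0.0, 1.0)

    def test_synthetic_cohort_median_in_pediatric_range(self, small_cohort):
        df = small_cohort.cohort
        bmi = compute_bmi(df["weight_kg"].to_numpy(), df["height_cm"].to_numpy() / 100)
        assert 10 < np.median(bmi) < 25


class TestResidualHeight:
    def _growth(self, ages):
        return 50.0 + 120.0 * (1.0 - np.exp(-ages / 60.0))

    def test_heights_on_fitted_line_give_near_zero_residuals(self):
        # degree-1 LOESS reproduces a linear height-age relationship
        # exactly, so such heights sit on their own fitted curve
        rng = np.random.default_rng(0)
        ages = np.sort(rng.uniform(1, 180, size=200))
        heights = 55.0 + 0.6 * ages
        genders = np.repeat("female", 200)
        r = residual_height(heights, ages, genders)
        assert np.max(np.abs(r)) < 1e-6

    def test_mean_residual_near_zero_on_noisy_growth_data(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(1, 180, size=1000)
        genders = np.where(rng.random(1000) < 0.5, "male", "female")
        heights = self._growth(ages) * np.exp(rng.normal(0, 0.05, size=1000))
        r = residual_height(heights, ages, genders)
        assert abs(r.mean()) < 0.01
        assert 0.02 < r.std() < 0.12  # scale comparable to real cohorts

    def test_too_few_rows_per_gender_rejected(self):
        with pytest.raises(ValueError, match="male"):
            residual_height(
                np.full(20, 100.0), np.full(20, 50.0), np.repeat("male", 20)
            )

    def test_held_out_rows_do_not_influence_fit(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(1, 180, size=300)
        heights = self._growth(ages) * np.exp(rng.normal(0, 0.05, size=300))
        genders = np.repeat("female", 300)
        mask = np.zeros(300, dtype=bool)
        mask[:200] = True
        r1 = residual_height(heights, ages, genders, fit_mask=mask)
        heights2 = heights.copy()
        heights2[250:] *= 2.0  # corrupt held-out rows only
        r2 = residual_height(heights2, ages, genders, fit_mask=mask)
        assert np.allclose(r1[:200], r2[:200])


class TestFeatureAssembly:
    def test_baseline_has_exactly_five_features(self, small_cohort):
        block = assemble_features(small_cohort.cohort, "baseline")
        assert block.matrix.shape[1] == 5
        assert block.names == [
            "gender_male", "age_months", "residual_height", "bmi", "operation_minutes",
        ]

    def test_expert_adds_one_hot_width(self, small_cohort):
        block = assemble_features(small_cohort.cohort, "expert", field="diagnosis")
        n_levels = small_cohort.cohort["expert_diagnosis"].nunique()
        assert block.matrix.shape[1] == 5 + n_levels

    def test_ai_adds_soft_membership_width(self, small_cohort):
        X = hash_embed(small_cohort.cohort["diagnosis"].tolist(), 64, 0)
        clustering = spherical_kmeans(X, k=3, n_init=3, seed=0)
        block = assemble_features(
            small_cohort.cohort, "ai", field="diagnosis",
            clustering=clustering, embedding=X,
        )
        assert block.matrix.shape[1] == 5 + 3

    def test_ai_without_clustering_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            assemble_features(small_cohort.cohort, "ai", field="diagnosis")


class TestClassifierContract:
    def test_linearly_separable_data_gets_perfect_auc(self):
        X = np.r_[np.full((20, 2), -2.0), np.full((20, 2), 2.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        probs, _ = fit_predict_binary(X, y, X)
        assert threshold_averaged_metrics(probs, y)["roc_auc"] == 1.0

    def test_single_class_fold_gives_constant_class_rate(self):
        X = np.ones((5, 2))
        probs, model = fit_predict_binary(X, np.ones(5), np.ones((3, 2)))
        assert model is None
        assert np.allclose(probs, 1.0)

    def test_label_permutation_destroys_signal(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((400, 3))
        y = (X[:, 0] > 0).astype(int)
        y_perm = rng.permutation(y)
        probs, _ = fit_predict_binary(X[:300], y_perm[:300], X[300:])
        auc = threshold_averaged_metrics(probs, y_perm[300:])["roc_auc"]
        assert 0.35 < auc < 0.65

    def test_logistic_recovers_planted_effect_direction(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-2 * x))).astype(int)
        X = np.column_stack([x, rng.standard_normal(500)])
        _, model = fit_predict_binary(X, y, X)
        coef = model.named_steps["logisticregression"].coef_[0]
        assert coef[0] > 0 and abs(coef[0]) > abs(coef[1])

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_binary(np.ones((4, 1)), np.array([0, 1, 0, 1]), np.ones((1, 1)),
                               classifier="svm")


class TestProbabilityCombination:
    def test_field_average(self):
        assert average_field_models([0.2], [0.4])[0] == pytest.approx(0.3)
        assert np.allclose(average_field_models([0.5, 0.1], [0.5, 0.1]), [0.5, 0.1])

    def test_field_average_bounded_by_inputs(self, rng):
        a, b = rng.random(50), rng.random(50)
        avg = average_field_models(a, b)
        assert np.all(avg >= np.minimum(a, b)) and np.all(avg <= np.maximum(a, b))

    def test_ensemble_weighted_average(self):
        assert ensemble_predict([[0.6], [0.3]], [2, 1])[0] == pytest.approx(0.5)
        assert ensemble_predict([[0.6], [0.3], [0.9]], [2, 1, 0.2])[0] == pytest.approx(0.525)
        assert ensemble_predict([[0.7]], [1.0])[0] == pytest.approx(0.7)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([[0.5], [0.5]], [0, 0])
        with pytest.raises(ValueError):
            average_field_models([0.5], [0.5, 0.6])


class TestThresholdAveragedMetrics:
    def test_perfect_probabilities_score_one_everywhere(self):
        labels = np.array([0, 0, 1, 1])
        probs = labels.astype(float)
        rec = threshold_averaged_metrics(probs, labels)
        for name in ("roc_auc", "accuracy", "precision", "f1", "sensitivity", "specificity"):
            assert rec[name] == pytest.approx(1.0)

    def test_constant_half_probability_enumeration(self):
        # probability 0.5 is called positive at thresholds 0.1..0.5 (5 of 9)
        labels = np.array([1, 1, 0, 0])
        rec = threshold_averaged_metrics(np.full(4, 0.5), labels)
        assert rec["sensitivity"] == pytest.approx(5 / 9)
        assert rec["specificity"] == pytest.approx(4 / 9)
        assert rec["accuracy"] == pytest.approx(0.5)

    def test_probability_reversal_flips_auc(self, rng):
        labels = rng.integers(2, size=100)
        probs = rng.random(100)
        auc = threshold_averaged_metrics(probs, labels)["roc_auc"]
        rev = threshold_averaged_metrics(1 - probs, labels)["roc_auc"]
        assert auc + rev == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            threshold_averaged_metrics(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_all_metrics_within_unit_interval(self, rng):
        labels = rng.integers(2, size=60)
        rec = threshold_averaged_metrics(rng.random(60), labels)
        assert all(0.0 <= rec[m] <= 1.0 for m in rec)


class TestRepeatedCV:
    @pytest.fixture()
    def cv_inputs(self, small_cohort):
        labels = outcomes_table(small_cohort.cohort)["kdigo_binary"].to_numpy()
        return small_cohort.cohort, labels

    def test_record_counts_and_partition_law(self, cv_inputs):
        cohort, labels = cv_inputs
        report = run_repeated_cv(
            cohort, labels, [ModelVariant(name="baseline", kind="baseline")],
            CVConfig(repeats=2, folds=5, master_seed=1),
        )
        assert len(report) == 10
        assert set(report["model"]) == {"baseline"}
        sizes = report.groupby("repeat")["fold"].count()
        assert (sizes == 5).all()

    def test_same_master_seed_reproduces_report(self, cv_inputs):
        cohort, labels = cv_inputs
        variants = [ModelVariant(name="baseline", kind="baseline")]
        cfg = CVConfig(repeats=2, folds=4, master_seed=5)
        a = run_repeated_cv(cohort, labels, variants, cfg)
        b = run_repeated_cv(cohort, labels, variants, cfg)
        assert a.equals(b)

    def test_paired_ttest_identical_models(self, cv_inputs):
        cohort, labels = cv_inputs
        report = run_repeated_cv(
            cohort, labels, [ModelVariant(name="baseline", kind="baseline")],
            CVConfig(repeats=2, folds=4, master_seed=2),
        )
        clone = report.copy()
        clone["model"] = "clone"
        both = np.r_[report.to_records(index=False), clone.to_records(index=False)]
        import pandas as pd

        both = pd.DataFrame(both)
        t, p = paired_fold_ttest(both, "baseline", "clone")
        assert t == 0.0 and p == 1.0

    def test_paired_ttest_matches_reference_t_distribution(self, rng):
        import pandas as pd

        n = 40
        a = rng.normal(0.7, 0.05, size=n)
        b = a - rng.normal(0.02, 0.01, size=n)
        report = pd.DataFrame(
            {
                "repeat": np.r_[np.arange(n), np.arange(n)],
                "fold": 0,
                "model": ["A"] * n + ["B"] * n,
                "roc_auc": np.r_[a, b],
            }
        )
        for m in ("accuracy", "precision", "f1", "sensitivity", "specificity"):
            report[m] = 0.5
        t, p = paired_fold_ttest(report, "A", "B", side="greater")
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p_ref = stats.t.sf(t_ref, n - 1)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)
        assert p < 0.05

    def test_fewer_rows_than_folds_rejected(self, cv_inputs):
        cohort, labels = cv_inputs
        with pytest.raises(ValueError):
            run_repeated_cv(
                cohort.head(3), labels[:3],
                [ModelVariant(name="baseline", kind="baseline")],
                CVConfig(repeats=1, folds=5),
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CVConfig(folds=1)
        with pytest.raises(ValueError):
            CVConfig(thresholds=(0.5, 0.4))
        with pytest.raises(ValueError):
            CVConfig(cluster_scope="everywhere")

    def test_variant_token_parsing(self):
        v = parse_variant_token("ai:hash:diagnosis")
        assert v.kind == "ai" and v.fields == ("diagnosis",)
        assert v.embedder.kind == "hash" and v.embedder.dimension >= 256
        assert parse_variant_token("baseline").kind == "baseline"
        assert parse_variant_token("expert").fields == ("diagnosis", "operation")
        with pytest.raises(ValueError):
            parse_variant_token("ai")

    def test_ensemble_references_validated(self, cv_inputs):
        cohort, labels = cv_inputs
        with pytest.raises(ValueError):
            run_repeated_cv(
                cohort, labels, [ModelVariant(name="baseline", kind="baseline")],
                CVConfig(repeats=1, folds=4),
                ensembles={"ens": (["missing"], [1.0])},
            )

    def test_summary_has_one_row_per_model(self, cv_inputs):
        cohort, labels = cv_inputs
        spec = EmbedderSpec(name="hash", kind="hash", dimension=64)
        report = run_repeated_cv(
            cohort, labels,
            [
                ModelVariant(name="baseline", kind="baseline"),
                ModelVariant(
                    name="ai:hash", kind="ai", embedder=spec, k=3, n_init=3,
                    fields=("diagnosis",),
                ),
            ],
            CVConfig(repeats=1, folds=4, master_seed=3),
            ensembles={"ens": (["ai:hash", "baseline"], [2.0, 1.0])},
        )
        summary = summarize_cv_report(report)
        assert set(summary["model"]) == {"baseline", "ai:hash", "ens"}
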