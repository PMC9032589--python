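import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from conftest import REDUCED_GRIDS
from wristfunc import modeling as md
from wristfunc.features import FEATURE_NAMES
from wristfunc.taxonomy import TaskSpec


def toy_table(rng, n_subjects=12, windows_per_subject=8, informative=None):
    """Random feature table with optional planted signal columns."""
    rows = []
    for s in range(n_subjects):
        for w in range(windows_per_subject):
            row = {name: rng.standard_normal() for name in FEATURE_NAMES}
            row.update(
                subject_id=f"s{s:02d}",
                activity_name="LEISURE WALK",
                window_index=w,
                type_category="Locomotion",
                intensity_category="Moderate",
                group="LPP" if s % 2 else "HPP",
                mets=float(rng.uniform(1, 5)),
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    if informative:
        y = rng.integers(0, 2, size=len(table))
        table["type_category"] = np.where(y == 1, "Sedentary", "Locomotion")
        for name in informative:
            table[name] = y + 0.01 * rng.standard_normal(len(table))
    return table


BINARY_SED = TaskSpec("binary_type", "Sedentary", "boosted_trees", "ALL")


class TestBuildDesign:
    def test_weight_ratio_9_to_1(self, rng):
        table = toy_table(rng, n_subjects=10, windows_per_subject=10)
        table["type_category"] = ["Sedentary"] * 10 + ["Locomotion"] * 90
        design = md.build_design(table, BINARY_SED)
        w_pos = design.sample_weights[design.y == 1]
        w_neg = design.sample_weights[design.y == 0]
        assert w_pos[0] / w_neg[0] == pytest.approx(9.0)

    def test_balanced_classes_equal_weights(self, rng):
        table = toy_table(rng, n_subjects=10, windows_per_subject=10)
        table["type_category"] = ["Sedentary", "Locomotion"] * 50
        design = md.build_design(table, BINARY_SED)
        assert np.allclose(design.sample_weights, 1.0)

    def test_unknown_positive_class_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("binary_type", "Swimming", "boosted_trees", "ALL")

    def test_single_class_cohort_rejected(self, rng):
        table = toy_table(rng)  # all Locomotion
        with pytest.raises(ValueError, match="single class"):
            md.build_design(table, BINARY_SED)

    def test_cohort_filter(self, rng):
        table = toy_table(rng, informative=["mvm"])
        design = md.build_design(
            table, TaskSpec("binary_type", "Sedentary", "boosted_trees", "LPP")
        )
        lpp_subjects = set(table.loc[table.group == "LPP", "subject_id"])
        assert set(design.subject_ids) <= lpp_subjects

    def test_regression_targets_mets(self, rng):
        table = toy_table(rng)
        design = md.build_design(
            table, TaskSpec("regression_ee", None, "boosted_trees", "ALL")
        )
        np.testing.assert_array_equal(design.y, table["mets"].to_numpy())
        assert np.all(design.sample_weights == 1.0)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = md.compute_metrics(y, y, y_score=y.astype(float), kind="binary")
        assert m["f1"] == m["auc"] == m["accuracy"] == m["balanced_accuracy"] == 1.0

    def test_hand_confusion(self):
        # TP=8, FP=2, FN=4, TN=6 -> precision .8, recall 2/3, F1 = 8/11
        y_true = [1] * 8 + [0] * 2 + [1] * 4 + [0] * 6
        y_pred = [1] * 8 + [1] * 2 + [0] * 4 + [0] * 6
        m = md.compute_metrics(y_true, y_pred, kind="binary")
        assert m["f1"] == pytest.approx(8 / 11)

    def test_rmse_constant_offset(self):
        y = np.linspace(0, 5, 20)
        m = md.compute_metrics(y, y + 0.5, kind="regression")
        assert m["rmse"] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            md.compute_metrics([], [], kind="binary")

    def test_balanced_accuracy_equals_accuracy_when_balanced(self, rng):
        y_true = np.array([0, 1] * 50)
        y_pred = rng.integers(0, 2, size=100)
        # equal class counts: mean of recalls == overall accuracy
        m = md.compute_metrics(y_true, y_pred, kind="binary")
        assert m["balanced_accuracy"] == pytest.approx(m["accuracy"])

    def test_f1_invariant_under_duplication(self, rng):
        y_true = rng.integers(0, 2, size=60)
        y_pred = rng.integers(0, 2, size=60)
        m1 = md.compute_metrics(y_true, y_pred, kind="binary")
        m2 = md.compute_metrics(
            np.tile(y_true, 2), np.tile(y_pred, 2), kind="binary"
        )
        assert m1["f1"] == pytest.approx(m2["f1"])

    def test_multiclass_per_class_f1(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "a", "b", "c", "c", "c"]
        m = md.compute_metrics(y_true, y_pred, kind="multiclass")
        assert m["f1__a"] == 1.0
        assert m["f1"] == pytest.approx(np.mean([m["f1__a"], m["f1__b"], m["f1__c"]]))


class TestNestedCV:
    def test_subject_disjointness_recorded(self, small_cohort_table):
        design = md.build_design(small_cohort_table, BINARY_SED)
        result = md.nested_cv(
            design, BINARY_SED, outer_k=5, inner_k=3, seed=0,
            grids=REDUCED_GRIDS,
        )
        assert len(result.per_fold_metrics) == 5
        assert result.fold_subjects
        for train, test in result.fold_subjects:
            assert not train & test

    def test_separable_task_high_f1(self, small_cohort_table):
        design = md.build_design(small_cohort_table, BINARY_SED)
        result = md.nested_cv(
            design, BINARY_SED, outer_k=5, inner_k=3, seed=0,
            grids=REDUCED_GRIDS,
        )
        assert result.metric_means["f1"] >= 0.95

    def test_shuffled_labels_chance_auc(self, small_cohort_table, rng):
        table = small_cohort_table.copy()
        table["type_category"] = rng.permutation(
            table["type_category"].to_numpy()
        )
        design = md.build_design(table, BINARY_SED)
        result = md.nested_cv(
            design, BINARY_SED, outer_k=5, inner_k=3, seed=0,
            grids=REDUCED_GRIDS,
        )
        assert abs(result.metric_means["auc"] - 0.5) <= 0.1

    def test_too_few_subjects(self, rng):
        table = toy_table(rng, n_subjects=3, informative=["mvm"])
        design = md.build_design(table, BINARY_SED)
        with pytest.raises(ValueError, match="subjects"):
            md.nested_cv(design, BINARY_SED, outer_k=5, grids=REDUCED_GRIDS)


class TestBoostedTrees:
    def test_noise_features_chance_auc(self, rng):
        table = toy_table(rng, n_subjects=20, windows_per_subject=10)
        labels = rng.integers(0, 2, size=len(table))
        table["type_category"] = np.where(labels == 1, "Sedentary", "Locomotion")
        design = md.build_design(table, BINARY_SED)
        result = md.nested_cv(
            design, BINARY_SED, outer_k=5, inner_k=3, seed=1,
            grids=REDUCED_GRIDS,
        )
        assert abs(result.metric_means["auc"] - 0.5) <= 0.15

    def test_planted_feature_ranks_first(self, rng):
        table = toy_table(rng, informative=["sdvm"])
        design = md.build_design(table, BINARY_SED)
        model = md.fit_boosted_trees(
            design, {"max_depth": 3, "n_estimators": 50}, seed=0
        )
        ranking = md.rank_importance(model, FEATURE_NAMES)
        assert ranking[0][0] == "sdvm"

    def test_deterministic_given_seed(self, rng):
        table = toy_table(rng, informative=["mvm", "sdvm"])
        design = md.build_design(table, BINARY_SED)
        preds = []
        for _ in range(2):
            model = md.fit_boosted_trees(
                design, {"max_depth": 3, "n_estimators": 30}, seed=7
            )
            preds.append(model.predict_proba(design.X)[:, 1])
        np.testing.assert_array_equal(preds[0], preds[1])


class TestL1Linear:
    def test_full_shrinkage_kills_coefficients(self, rng):
        table = toy_table(rng, informative=["mvm"])
        design = md.build_design(table, BINARY_SED)
        model = md.fit_l1_linear(design, {"penalty_lambda": 1e6})
        coef = model.named_steps["model"].coef_
        assert np.allclose(coef, 0.0)

    def test_zero_penalty_matches_ols(self, rng):
        table = toy_table(rng, n_subjects=30, windows_per_subject=4)
        spec = TaskSpec("regression_ee", None, "l1_linear", "ALL")
        # make the target a clean linear function of a few features
        table["mets"] = (
            2.0
            + 1.5 * table["mvm"]
            - 0.7 * table["p625"]
            + 0.05 * rng.standard_normal(len(table))
        )
        design = md.build_design(table, spec)
        model = md.fit_l1_linear(design, {"penalty_lambda": 1e-10})
        ols = LinearRegression().fit(design.X, design.y)
        pred = model.predict(design.X)
        np.testing.assert_allclose(pred, ols.predict(design.X), atol=1e-2)

    def test_sparse_support_recovery(self, rng):
        table = toy_table(rng, n_subjects=30, windows_per_subject=6)
        spec = TaskSpec("regression_ee", None, "l1_linear", "ALL")
        informative = ["mvm", "sdvm", "p625"]
        table["mets"] = sum(3.0 * table[c] for c in informative)
        table["mets"] += 0.01 * rng.standard_normal(len(table))
        design = md.build_design(table, spec)
        model = md.fit_l1_linear(design, {"penalty_lambda": 0.05})
        coef = model.named_steps["model"].coef_.ravel()
        kept = model.named_steps["drop_constant"].get_support(indices=True)
        names = [FEATURE_NAMES[i] for i in kept]
        selected = {n for n, c in zip(names, coef) if abs(c) > 1e-6}
        assert set(informative) <= selected

    def test_constant_columns_dropped_with_warning(self, rng, caplog):
        table = toy_table(rng, informative=["mvm"])
        table["fpdf"] = 1.0
        design = md.build_design(table, BINARY_SED)
        with caplog.at_level("WARNING"):
            model = md.fit_l1_linear(design, {"penalty_lambda": 0.1})
        assert "constant" in caplog.text
        kept = model.named_steps["drop_constant"].get_support()
        assert kept.sum() == 48


class TestTransfer:
    def test_loo_same_group_rejected(self, small_cohort_table):
        with pytest.raises(ValueError):
            md.run_loo(small_cohort_table, BINARY_SED, "LPP", "LPP")

    def test_loo_runs_both_directions(self, small_cohort_table):
        for train, test in (("LPP", "HPP"), ("HPP", "LPP")):
            result = md.run_loo(
                small_cohort_table, BINARY_SED, train, test,
                grids=REDUCED_GRIDS,
            )
            assert result.repeats == 1
            assert 0.0 <= result.scores[0] <= 1.0

    def test_loo_empty_test_group(self, small_cohort_table):
        lpp_only = small_cohort_table[small_cohort_table.group == "LPP"]
        with pytest.raises(ValueError):
            md.run_loo(lpp_only, BINARY_SED, "LPP", "HPP",
                       grids=REDUCED_GRIDS)

    def test_lpo_retains_ten_scores(self, small_cohort_table):
        result = md.run_lpo(
            small_cohort_table, BINARY_SED, "LPP", "HPP",
            repeats=10, seed=0, grids=REDUCED_GRIDS,
        )
        assert result.repeats == 10
        assert len(result.scores) == 10
        assert result.mean == pytest.approx(np.mean(result.scores))

    def test_lpo_deterministic_splits(self, small_cohort_table):
        a = md.run_lpo(small_cohort_table, BINARY_SED, "LPP", "HPP",
                       repeats=3, seed=5, grids=REDUCED_GRIDS)
        b = md.run_lpo(small_cohort_table, BINARY_SED, "LPP", "HPP",
                       repeats=3, seed=5, grids=REDUCED_GRIDS)
        assert a.scores == b.scores

    def test_lpo_invalid_frac(self, small_cohort_table):
        with pytest.raises(ValueError):
            md.run_lpo(small_cohort_table, BINARY_SED, "LPP", "HPP",
                       frac=1.5)


class TestRankImportance:
    def test_normalized_and_clipped(self, rng):
        table = toy_table(rng, informative=["mvm"])
        design = md.build_design(table, BINARY_SED)
        model = md.fit_boosted_trees(
            design, {"max_depth": 3, "n_estimators": 30}, seed=0
        )
        full = md.rank_importance(model, FEATURE_NAMES, top_k=100)
        assert len(full) == 49
        assert sum(v for _, v in full) == pytest.approx(1.0)
        top = md.rank_importance(model, FEATURE_NAMES, top_k=15)
        assert len(top) == 15
        assert [v for _, v in top] == sorted(
            [v for _, v in top], reverse=True
        )

    def test_linear_fallback_flagged(self, rng, caplog):
        table = toy_table(rng, informative=["mvm"])
        design = md.build_design(table, BINARY_SED)
        model = md.fit_l1_linear(design, {"penalty_lambda": 0.01})
        with caplog.at_level("WARNING"):
            ranking = md.rank_importance(model, FEATURE_NAMES, top_k=5)
        assert "coefficients" in caplog.text
        assert len(ranking) == 5
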