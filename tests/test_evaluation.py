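import numpy as np
import pytest

from radcombat import FeatureTable, SimulationConfig, simulate_features
from radcombat.evaluation import (
    ModelSpec, default_model_specs, make_split, train_eval, cross_validate,
    evaluate_arm, compare_arms, ci95, _confusion_metrics, _auc_trapezoid,
    feature_importances, MODEL_NAMES,
)

from conftest import make_informative_table


def separable_table(n_per_class=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n_per_class, dtype=int),
              np.ones(n_per_class, dtype=int)]
    X = rng.normal(0, 0.2, (2 * n_per_class, 5))
    X[:, 0] += 10 * y  # two distant clusters
    return FeatureTable(X, [f"f{g}" for g in range(5)],
                        np.tile(["a", "b"], n_per_class), y)


class TestModelSpec:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gradient_boosting")

    def test_missing_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            ModelSpec("random_forest", {"n_estimators": 100})

    def test_study_settings_introspectable(self):
        spec = ModelSpec("random_forest", seed=0)
        model = spec.build()
        assert model.n_estimators == 100
        assert model.max_depth == 8
        svm = ModelSpec("svm", seed=0).build()
        assert svm.C == 2.0 and svm.kernel == "rbf" and svm.gamma == "scale"
        nn = ModelSpec("neural_net", seed=0).build()
        assert len(nn.hidden_layer_sizes) == 5


class TestSplit:
    def test_study_ratio_counts(self):
        # 135 per class at 8:2 -> 108 train / 27 test per class
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 135)
        X = rng.normal(0, 1, (270, 3))
        t = FeatureTable(X, list("abc"), np.repeat(["p", "q"], 135), y)
        plan = make_split(t, ratio=0.8, seed=0)
        for cls in (0, 1):
            assert (y[plan.train_indices] == cls).sum() == 108
            assert (y[plan.test_indices] == cls).sum() == 27

    def test_small_split(self):
        rng = np.random.default_rng(1)
        y = np.tile([0, 1], 5)
        t = FeatureTable(rng.normal(0, 1, (10, 2)), ["a", "b"],
                         np.repeat(["p", "q"], 5), y)
        plan = make_split(t, ratio=0.8, seed=3)
        assert len(plan.train_indices) == 8
        assert len(plan.test_indices) == 2

    def test_determinism_and_partition(self):
        t = separable_table()
        a = make_split(t, seed=11)
        b = make_split(t, seed=11)
        assert np.array_equal(a.train_indices, b.train_indices)
        union = np.union1d(a.train_indices, a.test_indices)
        assert np.array_equal(union, np.arange(t.n_samples))
        assert np.intersect1d(a.train_indices, a.test_indices).size == 0


class TestMetrics:
    def test_hand_computed_confusion(self):
        # predictions (1,0,1,0) vs truth (1,1,0,0): tp=1 fp=1 fn=1 tn=1
        m = _confusion_metrics(np.array([1, 1, 0, 0]),
                               np.array([1, 0, 1, 0]))
        assert m["accuracy"] == 0.5
        assert m["precision"] == 0.5
        assert m["recall"] == 0.5

    def test_constant_prediction_on_balanced_data(self):
        m = _confusion_metrics(np.array([0, 1, 0, 1]),
                               np.zeros(4, dtype=int))
        assert m["accuracy"] == 0.5
        assert m["recall"] == 0.0

    def test_auc_trapezoid_simple(self):
        assert _auc_trapezoid(np.array([0.0, 0.0, 1.0]),
                              np.array([0.0, 1.0, 1.0])) == 1.0
        assert _auc_trapezoid(np.array([0.0, 1.0]),
                              np.array([0.0, 1.0])) == 0.5

    def test_ci_convention_and_monotonicity(self):
        mean, ci = ci95(np.array([0.8, 0.8, 0.8, 0.8, 0.8]))
        assert mean == pytest.approx(0.8)
        assert ci == [pytest.approx(0.8), pytest.approx(0.8)]
        _, wide = ci95(np.array([0.6, 0.7, 0.8, 0.9, 1.0]))
        _, narrow = ci95(np.array([0.78, 0.79, 0.8, 0.81, 0.82]))
        assert wide[1] - wide[0] > narrow[1] - narrow[0]
        # bounds clipped into [0, 1]
        _, edge = ci95(np.array([0.0, 0.0, 0.1, 0.0, 0.0]))
        assert edge[0] >= 0.0


class TestTrainEval:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_separable_data_auc_one(self, name):
        t = separable_table()
        plan = make_split(t, seed=0)
        res = train_eval(
            ModelSpec(name, seed=0),
            t.values[plan.train_indices], t.class_labels[plan.train_indices],
            t.values[plan.test_indices], t.class_labels[plan.test_indices],
        )
        assert res["metrics"]["auc"] == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self):
        # permutation null: mean AUC over 20 label shuffles ~ 0.5
        t = make_informative_table(n_per_class=40, n_features=10,
                                   n_informative=3, seed=0)
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(20):
            y = rng.permutation(t.class_labels)
            shuffled = FeatureTable(t.values, t.feature_names,
                                    t.batch_labels, y)
            plan = make_split(shuffled, seed=int(rng.integers(1 << 16)))
            res = train_eval(
                ModelSpec("logistic", seed=0),
                shuffled.values[plan.train_indices], y[plan.train_indices],
                shuffled.values[plan.test_indices], y[plan.test_indices],
            )
            aucs.append(res["metrics"]["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_training_rejected(self):
        t = separable_table()
        with pytest.raises(ValueError):
            train_eval(ModelSpec("logistic"), t.values[:5], np.zeros(5),
                       t.values[:5], np.zeros(5))

    def test_no_leakage_from_test_labels(self):
        # corrupting the held-out labels must not change anything fitted
        t = make_informative_table(seed=4)
        plan = make_split(t, seed=0)
        Xtr = t.values[plan.train_indices]
        ytr = t.class_labels[plan.train_indices]
        Xte = t.values[plan.test_indices]
        yte = t.class_labels[plan.test_indices]
        res_a = train_eval(ModelSpec("logistic", seed=0), Xtr, ytr, Xte, yte)
        res_b = train_eval(ModelSpec("logistic", seed=0), Xtr, ytr, Xte,
                           1 - yte)
        assert np.array_equal(res_a["model"].coef_, res_b["model"].coef_)
        assert np.array_equal(res_a["scaler"][0], res_b["scaler"][0])
        assert np.array_equal(res_a["scaler"][1], res_b["scaler"][1])


class TestCrossValidate:
    def test_fold_partition(self):
        t = separable_table(n_per_class=25)
        out = cross_validate(ModelSpec("logistic", seed=0), t, k=5, seed=0)
        assert len(out["folds"]) == 5
        # every metric summary is a mean with a CI inside [0,1]
        for metric, s in out["summary"].items():
            assert 0.0 <= s["ci95"][0] <= s["mean"] <= s["ci95"][1] <= 1.0

    def test_k_exceeding_minority_class_rejected(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(20, dtype=int), np.ones(3, dtype=int)]
        t = FeatureTable(rng.normal(0, 1, (23, 2)), ["a", "b"],
                         np.tile(["p", "q"], 12)[:23], y)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("logistic"), t, k=5)


class TestCompareArms:
    def test_identical_arms_zero_deltas(self):
        t = separable_table()
        rep = evaluate_arm(t, "without_combat", k=3, seed=0)
        out = compare_arms(rep, rep)
        for model, deltas in out["deltas"].items():
            assert all(v == 0.0 for v in deltas.values())
        for model, imp in out["importance"].items():
            assert imp["spearman_rho"] == pytest.approx(1.0)
            assert all(v == 0 for v in imp["rank_change"].values())

    def test_reversed_arms_negate_deltas(self):
        a = evaluate_arm(separable_table(seed=1), "a", k=3, seed=0)
        b = evaluate_arm(make_informative_table(n_per_class=40,
                                                n_features=5, seed=2),
                         "b", k=3, seed=0)
        fwd = compare_arms(a, b)
        rev = compare_arms(b, a)
        for model in fwd["deltas"]:
            for metric, v in fwd["deltas"][model].items():
                assert rev["deltas"][model][metric] == pytest.approx(-v)

    def test_mismatched_model_lists_rejected(self):
        t = separable_table()
        full = evaluate_arm(t, "a", k=3, seed=0)
        partial = evaluate_arm(t, "b", [ModelSpec("logistic", seed=0)],
                               k=3, seed=0)
        with pytest.raises(ValueError):
            compare_arms(full, partial)

    def test_importance_sources(self):
        t = separable_table()
        rep = evaluate_arm(t, "a", k=3, seed=0)
        assert set(rep.importances) == {"lasso", "logistic", "random_forest"}
        for imp in rep.importances.values():
            assert set(imp) == set(t.feature_names)
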