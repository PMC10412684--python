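import math

import numpy as np
import pytest

import ecgnoise as e
from ecgnoise.dataset import DatasetMatrix
from ecgnoise.models import (
    SLP_NEURON_PRESETS,
    ConfusionCounts,
    ModelConfig,
    build_classifier,
    compute_metrics,
    confusion_from_predictions,
    make_split_plan,
    permutation_feature_importance,
    retrain_with_top_features,
    run_patient_rotation,
    tune_hyperparameters,
)
from ecgnoise.study import SLP_TEST_CONFUSIONS


class TestMetrics:
    def test_reference_patient_rows_at_two_decimals(self):
        m2 = compute_metrics(SLP_TEST_CONFUSIONS["2"]).rounded()
        assert (m2.acc, m2.re, m2.pr, m2.f1) == (0.81, 0.72, 0.77, 0.75)
        m4 = compute_metrics(SLP_TEST_CONFUSIONS["4"]).rounded()
        assert (m4.acc, m4.re, m4.pr, m4.f1) == (0.97, 0.97, 0.93, 0.95)

    def test_reference_aggregate_means(self):
        accs = [compute_metrics(c).acc for c in SLP_TEST_CONFUSIONS.values()]
        res = [compute_metrics(c).re for c in SLP_TEST_CONFUSIONS.values()]
        assert round(float(np.mean(accs)), 2) == 0.75
        assert round(float(np.mean(res)), 2) == 0.78

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=10))
        assert (m.acc, m.re, m.pr, m.f1, m.mcc, m.nmcc) == (1, 1, 1, 1, 1, 1)

    def test_zero_denominator_conventions(self):
        m = compute_metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=5))
        assert (m.re, m.pr, m.f1, m.mcc) == (0.0, 0.0, 0.0, 0.0)
        assert m.acc == 1.0 and m.nmcc == 0.5

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_identities_on_random_confusions(self, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 50, 4)
            if tp + fn + fp + tn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(fn), int(fp), int(tn)))
            assert 0.0 <= m.acc <= 1.0
            assert -1.0 <= m.mcc <= 1.0
            assert m.nmcc == pytest.approx((m.mcc + 1) / 2, abs=1e-12)
            if m.re + m.pr > 0:
                assert m.f1 == pytest.approx(
                    2 * m.re * m.pr / (m.re + m.pr), abs=1e-12
                )

    def test_confusion_matches_per_instance_tally(self, rng):
        y_true = rng.integers(0, 2, 100)
        y_pred = rng.integers(0, 2, 100)
        c = confusion_from_predictions(y_true, y_pred)
        assert c.tp == sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        assert c.fn == sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert c.fp == sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        assert c.tn == sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        assert c.total == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_predictions(np.zeros(3), np.zeros(4))


class TestBuildClassifier:
    def test_knn_k_one_memorizes_training_set(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        model = build_classifier(ModelConfig("knn", {"k": 1}))
        model.fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_hyperparameters_reach_the_estimators(self):
        assert build_classifier(ModelConfig("knn", {"k": 7})).n_neighbors == 7
        assert (
            build_classifier(ModelConfig("dtree", {"msl": 9})).min_samples_leaf == 9
        )
        svm = build_classifier(ModelConfig("linear_svm", {"s": 2.5, "c": 3.0}))
        assert svm.named_steps["scale"].s == 2.5
        assert svm.named_steps["svm"].C == 3.0
        slp = build_classifier(ModelConfig("slp", {"neurons": 40, "l2": 0.01}))
        assert slp.hidden_layer_sizes == (40,) and slp.alpha == 0.01
        rf = build_classifier(
            ModelConfig("rforest", {"ntrees": 60, "msl": 2, "nfeats": 5})
        )
        assert (rf.n_estimators, rf.min_samples_leaf, rf.max_features) == (60, 2, 5)

    def test_kernel_scale_divides(self):
        svm = build_classifier(ModelConfig("linear_svm", {"s": 4.0}))
        out = svm.named_steps["scale"].transform(np.array([[8.0, 2.0]]))
        assert np.allclose(out, [[2.0, 0.5]])

    def test_unknown_family_and_params_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelConfig("boosting", {})
        with pytest.raises(ValueError, match="k"):
            ModelConfig("dtree", {"k": 3})

    def test_neuron_presets_cover_retained_patients(self):
        assert set(SLP_NEURON_PRESETS) == {"2", "4", "6", "7", "9", "10"}
        assert all(5 <= v <= 100 for v in SLP_NEURON_PRESETS.values())


def _toy_dataset(n_patients=4, per_patient=40, n_feat=4, seed=0, informative=True):
    """Separable two-class dataset with patient identities."""
    rng = np.random.default_rng(seed)
    X, y, pids = [], [], []
    for p in range(n_patients):
        for _ in range(per_patient):
            label = int(rng.random() < 0.5)
            row = rng.standard_normal(n_feat)
            if informative:
                row[0] += 3.0 * label  # strong signal in feature 0
            X.append(row)
            y.append(label)
            pids.append(f"p{p}")
    return DatasetMatrix(
        np.array(X), np.array(y), np.array(pids),
        feature_names=tuple(f"x{j + 1}" for j in range(n_feat)),
    )


class TestSplitPlan:
    def test_partition_is_disjoint_and_exhaustive(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p1", seed=5)
        parts = np.concatenate([plan.test_idx, plan.train_idx, plan.val_idx])
        assert sorted(parts) == list(range(ds.n_instances))
        assert set(ds.patient_ids[plan.test_idx]) == {"p1"}
        assert "p1" not in set(ds.patient_ids[plan.train_idx])
        assert "p1" not in set(ds.patient_ids[plan.val_idx])

    def test_eighty_twenty_sizes(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p0", seed=1)
        n_other = ds.n_instances - plan.test_idx.size
        assert plan.train_idx.size == round(0.8 * n_other)
        assert plan.val_idx.size == n_other - plan.train_idx.size

    def test_cv_folds_partition_the_train_set(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p2", seed=3)
        assert len(plan.cv_folds) == 5
        held_out = np.concatenate([va for _, va in plan.cv_folds])
        assert sorted(held_out) == sorted(plan.train_idx)
        for tr, va in plan.cv_folds:
            assert not set(tr) & set(va)

    def test_deterministic_given_seed(self):
        ds = _toy_dataset()
        a = make_split_plan(ds, "p1", seed=9)
        b = make_split_plan(ds, "p1", seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.val_idx, b.val_idx)
        c = make_split_plan(ds, "p1", seed=10)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_unknown_patient_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(_toy_dataset(), "nobody", seed=0)


class TestTuning:
    def test_single_candidate_grid_is_returned(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p0", seed=2)
        cfg = tune_hyperparameters(
            ds, plan, "slp", search_space={"neurons": ("grid", (10,))}, seed=2
        )
        assert cfg.params == {"neurons": 10}

    def test_result_stays_inside_the_search_space(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p0", seed=2)
        cfg = tune_hyperparameters(
            ds, plan, "knn", search_space={"k": ("int", 1, 15)}, budget=6, seed=2
        )
        assert cfg.family == "knn"
        assert 1 <= cfg.params["k"] <= 15

    def test_deterministic_given_seed(self):
        ds = _toy_dataset()
        plan = make_split_plan(ds, "p1", seed=4)
        kw = dict(search_space={"k": ("int", 1, 15)}, budget=6, seed=4)
        a = tune_hyperparameters(ds, plan, "knn", **kw)
        b = tune_hyperparameters(ds, plan, "knn", **kw)
        assert a.params == b.params

    def test_tuned_tree_beats_degenerate_leaf_size(self):
        ds = _toy_dataset(per_patient=60)
        plan = make_split_plan(ds, "p0", seed=7)
        cfg = tune_hyperparameters(
            ds, plan, "dtree", search_space={"msl": ("int", 1, 100)}, budget=10, seed=7
        )
        # with one informative feature and ~190 fit rows, a tuned leaf size
        # should stay far from forcing a single leaf over the whole train set
        assert cfg.params["msl"] < 100


@pytest.fixture(scope="module")
def toy_rotation():
    ds = _toy_dataset(n_patients=4, per_patient=40, seed=3)
    reports = run_patient_rotation(ds, families=("knn",), seed=11, tuning_budget=4)
    return ds, reports["knn"]


class TestRotation:
    def test_one_result_per_patient(self, toy_rotation):
        ds, rep = toy_rotation
        assert sorted(rep.per_patient) == ["p0", "p1", "p2", "p3"]
        for pid, res in rep.per_patient.items():
            assert res.confusion.total == int(np.sum(ds.patient_ids == pid))

    def test_aggregate_is_mean_and_population_sd(self, toy_rotation):
        _, rep = toy_rotation
        agg = rep.aggregate()
        f1s = [r.metrics.f1 for r in rep.per_patient.values()]
        assert agg["f1"][0] == pytest.approx(np.mean(f1s), abs=1e-12)
        assert agg["f1"][1] == pytest.approx(np.std(f1s), abs=1e-12)

    def test_separable_data_learned_well(self, toy_rotation):
        _, rep = toy_rotation
        assert rep.aggregate()["acc"][0] >= 0.85

    def test_bit_reproducible(self, toy_rotation):
        ds, rep = toy_rotation
        again = run_patient_rotation(ds, families=("knn",), seed=11, tuning_budget=4)[
            "knn"
        ]
        for pid in rep.per_patient:
            assert rep.per_patient[pid].confusion == again.per_patient[pid].confusion
            assert rep.per_patient[pid].config.params == again.per_patient[pid].config.params

    def test_test_patient_rows_cannot_leak_into_tuning_or_scaling(self, toy_rotation):
        ds, rep = toy_rotation
        # corrupt the held-out patient's features beyond recognition
        mangled = ds.X.copy()
        test_rows = ds.patient_ids == "p1"
        mangled[test_rows] = 1e6 * np.random.default_rng(0).standard_normal(
            (test_rows.sum(), ds.X.shape[1])
        )
        ds2 = DatasetMatrix(mangled, ds.y, ds.patient_ids, ds.feature_names)
        plan = make_split_plan(ds2, "p1", rep.per_patient["p1"].plan.seed)
        cfg = tune_hyperparameters(
            ds2, plan, "knn", budget=rep.tuning_budget, seed=plan.seed
        )
        assert cfg.params == rep.per_patient["p1"].config.params
        scaler = e.fit_feature_scaler(
            ds2.X[np.concatenate([plan.train_idx, plan.val_idx])]
        )
        assert np.array_equal(scaler.mu, rep.per_patient["p1"].scaler.mu)
        assert np.array_equal(scaler.sigma, rep.per_patient["p1"].scaler.sigma)

    def test_too_few_patients_rejected(self):
        ds = _toy_dataset(n_patients=2)
        with pytest.raises(ValueError):
            run_patient_rotation(ds, families=("knn",), seed=0)


class TestPermutationImportance:
    def test_ignored_feature_has_zero_importance(self, rng):
        # feature 1 never influences this stump
        X = np.column_stack([rng.standard_normal(200), rng.standard_normal(200)])
        y = (X[:, 0] > 0).astype(int)
        from sklearn.tree import DecisionTreeClassifier

        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        ranked = permutation_feature_importance(model, X, y, metric="accuracy", seed=1)
        by_name = {d["feature"]: d for d in ranked}
        assert by_name["x2"]["mean"] == pytest.approx(0.0, abs=1e-12)
        assert by_name["x1"]["mean"] > 0.3

    def test_label_copy_feature_ranks_first(self, rng):
        X = np.column_stack(
            [rng.standard_normal(150), rng.integers(0, 2, 150).astype(float)]
        )
        y = X[:, 1].astype(int)
        model = build_classifier(ModelConfig("knn", {"k": 1}))
        model.fit(X, y)
        ranked = permutation_feature_importance(model, X, y, metric="f1", seed=2)
        assert ranked[0]["feature"] == "x2"

    def test_output_sorted_descending(self, rng):
        X = rng.standard_normal((100, 5))
        y = (X[:, 2] > 0).astype(int)
        model = build_classifier(ModelConfig("rforest", {"ntrees": 30}, seed=0))
        model.fit(X, y)
        ranked = permutation_feature_importance(model, X, y, seed=3)
        means = [d["mean"] for d in ranked]
        assert means == sorted(means, reverse=True)
        assert {d["index"] for d in ranked} == set(range(5))

    def test_bad_arguments_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.repeat([0, 1], 5)
        model = build_classifier(ModelConfig("knn", {"k": 1})).fit(X, y)
        with pytest.raises(ValueError):
            permutation_feature_importance(model, X, y, metric="auroc")
        with pytest.raises(ValueError):
            permutation_feature_importance(model, X, y, n_repeats=0)


class TestRetrainTopFeatures:
    def test_all_features_reproduces_full_rotation(self, toy_rotation):
        ds, rep = toy_rotation
        sub = retrain_with_top_features(ds, rep, k=ds.X.shape[1], n_repeats=3)
        assert sub.feature_subset == tuple(range(ds.X.shape[1]))
        for pid in rep.per_patient:
            assert sub.per_patient[pid].confusion == rep.per_patient[pid].confusion

    def test_single_feature_run(self, toy_rotation):
        ds, rep = toy_rotation
        sub = retrain_with_top_features(ds, rep, k=1, n_repeats=3)
        assert len(sub.feature_subset) == 1
        # the informative feature should be the one kept
        assert sub.feature_subset == (0,)

    def test_out_of_range_k_rejected(self, toy_rotation):
        ds, rep = toy_rotation
        with pytest.raises(ValueError):
            retrain_with_top_features(ds, rep, k=0)
        with pytest.raises(ValueError):
            retrain_with_top_features(ds, rep, k=ds.X.shape[1] + 1)
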