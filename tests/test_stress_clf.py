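"""Label assignment, feature assembly and the classification harness."""

import numpy as np
import pandas as pd
import pytest

from stressphen import stress_clf as sc
from stressphen.synthscene import TreatmentSpec
from stressphen.traits import FEATURE_COLUMNS


def _treat(**kw):
    d = dict(box_id="box01", treatment="t", water="Sufficient",
             nitrogen="High", weeds="None")
    d.update(kw)
    return TreatmentSpec(**d)


def _trait_frame(rng, n_boxes=10, n_dates=6, signal=None):
    rows = []
    for b in range(n_boxes):
        for d in range(n_dates):
            row = {"box_id": f"box{b:02d}", "das": 5 + 5 * d}
            for c in FEATURE_COLUMNS:
                row[c] = rng.normal()
            if signal:
                row[signal[0]] = signal[1](b, d)
            rows.append(row)
    return pd.DataFrame(rows)


class TestLabels:
    def test_water_label_boundary(self):
        dry = _treat(water="Limited")
        assert sc.assign_labels(dry, 20).water == "Sufficient"
        assert sc.assign_labels(dry, 28).water == "Sufficient"   # inclusive at 28
        assert sc.assign_labels(dry, 36).water == "Drying"

    def test_well_watered_never_drying(self):
        assert sc.assign_labels(_treat(), 70).water == "Sufficient"

    def test_nitrogen_and_weeds_copied(self):
        lab = sc.assign_labels(_treat(nitrogen="Low", weeds="Medium"), 40)
        assert (lab.water, lab.nitrogen, lab.weeds) == ("Sufficient", "Low", "Medium")

    def test_unknown_treatment_level_rejected(self):
        with pytest.raises(ValueError):
            _treat(water="Damp")


class TestFeatureAssembly:
    def test_vector_is_55_dimensional(self, rng):
        df = _trait_frame(rng)
        asm = sc.FeatureAssembler().fit(df)
        X = asm.transform(df)
        assert X.shape == (len(df), 55)
        assert sc.FEATURE_DIM == 55

    def test_training_matrix_standardized(self, rng):
        df = _trait_frame(rng)
        X = sc.FeatureAssembler().fit(df).transform(df)
        np.testing.assert_allclose(X[:, :54].mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X[:, :54].std(axis=0), 1, atol=1e-9)
        np.testing.assert_array_equal(X[:, 54], df["das"])       # DAS unscaled

    def test_absent_values_impute_to_zero(self, rng):
        df = _trait_frame(rng)
        asm = sc.FeatureAssembler().fit(df)
        empty = df.iloc[[0]].copy()
        empty[list(FEATURE_COLUMNS)] = np.nan
        x = asm.transform(empty)[0]
        np.testing.assert_allclose(x[:54], 0, atol=1e-12)
        assert x[54] == empty["das"].iloc[0]

    def test_missing_columns_raise(self, rng):
        df = _trait_frame(rng).drop(columns=["HS05_var"])
        with pytest.raises(ValueError, match="HS05_var"):
            sc.FeatureAssembler().fit(df)


class TestSplit:
    def test_holds_out_20_percent_of_boxes(self):
        boxes = [f"box{i:02d}" for i in range(30)]
        train, test = sc.split_boxes(boxes, 0.2, seed=0)
        assert len(test) == 6 and len(train) == 24
        assert set(train).isdisjoint(test)

    def test_deterministic_under_seed(self):
        boxes = [f"b{i}" for i in range(20)]
        assert sc.split_boxes(boxes, 0.2, 3) == sc.split_boxes(boxes, 0.2, 3)

    def test_too_few_boxes_raise(self):
        with pytest.raises(ValueError):
            sc.split_boxes(["only"], 0.2, 0)


class TestKFold:
    def test_folds_partition_rows(self, rng):
        y = np.array(["a", "b", "c"] * 20)
        X = rng.normal(size=(60, 5))
        res = sc.kfold_cv(X, y, k=5, seed=0)
        assign = res["fold_assignments"]
        assert sorted(np.unique(assign)) == [0, 1, 2, 3, 4]
        assert len(assign) == 60
        assert len(res["fold_accuracies"]) == 5

    def test_separable_data_is_perfect(self, rng):
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = rng.normal(size=(60, 3)) + np.where(y == "a", 0, 10)[:, None]
        res = sc.kfold_cv(X, y, k=5, seed=0)
        assert res["mean_accuracy"] == 1.0

    def test_permuted_labels_score_at_chance(self, rng):
        y = rng.permutation(np.array(["a", "b", "c"] * 40))
        X = rng.normal(size=(120, 5))
        res = sc.kfold_cv(X, y, k=5, seed=0)
        assert abs(res["mean_accuracy"] - 1 / 3) < 0.15

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="class"):
            sc.kfold_cv(rng.normal(size=(20, 3)), np.array(["a"] * 20), k=5)


class TestCost:
    def test_diagonal_confusion_costs_nothing(self):
        CM = np.diag([5, 8, 2])
        assert sc.misclassification_cost(CM, sc.DEFAULT_COST_MATRIX) == 0.0

    def test_two_level_errors_cost_double(self):
        CM = np.zeros((3, 3)); CM[0, 2] = 10     # 10 Low -> High errors
        assert sc.misclassification_cost(CM, sc.DEFAULT_COST_MATRIX, 10) == 2.0

    def test_hand_summed_mixed_matrix(self):
        CM = np.array([[5, 3, 0], [0, 5, 0], [0, 0, 5]])
        assert sc.misclassification_cost(CM, sc.DEFAULT_COST_MATRIX, 18) == \
            pytest.approx(3 / 18)

    def test_invariant_to_simultaneous_permutation(self, rng):
        CM = rng.integers(0, 10, (3, 3)).astype(float)
        W = sc.DEFAULT_COST_MATRIX
        p = rng.permutation(3)
        assert sc.misclassification_cost(CM[np.ix_(p, p)], W[np.ix_(p, p)]) == \
            pytest.approx(sc.misclassification_cost(CM, W))

    def test_zero_n_raises(self):
        with pytest.raises(ValueError):
            sc.misclassification_cost(np.zeros((2, 2)), np.ones((2, 2)))

    def test_default_cost_matrix_is_tabled(self):
        np.testing.assert_array_equal(sc.DEFAULT_COST_MATRIX,
                                      [[0, 1, 2], [1, 0, 1], [2, 1, 0]])


class TestEvaluate:
    class _Const:
        def __init__(self, label):
            self.label = label

        def predict(self, X):
            return np.array([self.label] * len(X))

    def test_perfect_predictions(self):
        y = np.array(["High"] * 7)
        rep = sc.evaluate(self._Const("High"), np.zeros((7, 2)), y,
                          ("Low", "Medium", "High"), sc.DEFAULT_COST_MATRIX)
        assert rep.accuracy == 1.0 and rep.cost == 0.0
        assert rep.n == 7 and np.trace(rep.confusion) == 7

    def test_accuracy_equals_trace_over_n(self, rng):
        y = rng.choice(["Low", "Medium", "High"], 40)
        rep = sc.evaluate(self._Const("Medium"), np.zeros((40, 2)), y,
                          ("Low", "Medium", "High"), sc.DEFAULT_COST_MATRIX)
        assert rep.confusion.sum() == 40
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 40)
        off = rep.confusion.sum() - np.trace(rep.confusion)
        assert rep.accuracy + off / 40 == pytest.approx(1.0)


class TestProtocol:
    def test_run_classification_report_shape(self, rng):
        df = _trait_frame(rng, n_boxes=12, n_dates=5,
                          signal=("CanCov_mean", lambda b, d: 10.0 * (b % 2) + d))
        labels = pd.DataFrame([
            {"box_id": f"box{b:02d}", "das": 5 + 5 * d,
             "water": "Sufficient" if b % 2 else "Drying",
             "nitrogen": ["Low", "Medium", "High"][b % 3],
             "weeds": ["None", "Medium", "High"][b % 3]}
            for b in range(12) for d in range(5)])
        rep = sc.run_classification(df, labels, k=3, seed=0, drop_first_date=False)
        assert set(rep["factors"]) == {"water", "nitrogen", "weeds"}
        for f in rep["factors"].values():
            assert 0 <= f["cv_mean_accuracy"] <= 1
            assert np.sum(f["confusion_matrix"]) == rep["n_test"]
        assert set(rep["train_boxes"]).isdisjoint(rep["test_boxes"])

    def test_ablation_table_structure(self, rng):
        df = _trait_frame(rng, n_boxes=10, n_dates=5)
        labels = pd.DataFrame([
            {"box_id": f"box{b:02d}", "das": 5 + 5 * d,
             "water": "Sufficient" if b % 2 else "Drying",
             "nitrogen": ["Low", "Medium", "High"][b % 3],
             "weeds": ["None", "Medium", "High"][b % 3]}
            for b in range(10) for d in range(5)])
        table = sc.modality_ablation(df, labels, k=3, seed=0, drop_first_date=False)
        assert set(table) == {"rgb", "rgb_3d", "hs", "rgb_3d_hs", "rgb_3d_hs_time"}
        for subset in table.values():
            assert set(subset) == {"water", "nitrogen", "weeds"}

    def test_subset_definitions_are_fixed(self):
        assert sc.MODALITY_SUBSETS["rgb"][0] == ("CanCov_mean",)
        assert len(sc.MODALITY_SUBSETS["hs"][0]) == 50
        assert sc.MODALITY_SUBSETS["rgb_3d_hs_time"][1] is True
        with pytest.raises(ValueError, match="empty"):
            sc.modality_ablation(pd.DataFrame(), pd.DataFrame(),
                                 subsets={"bad": ((), False)})

    def test_unknown_method_raises(self, rng):
        df = _trait_frame(rng, 4, 3)
        labels = pd.DataFrame([{"box_id": f"box{b:02d}", "das": 5 + 5 * d,
                                "water": "Sufficient", "nitrogen": "High",
                                "weeds": "None"} for b in range(4) for d in range(3)])
        with pytest.raises(ValueError, match="unknown method"):
            sc.run_classification(df, labels, method="magic")
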