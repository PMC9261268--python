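"""Splitting, grid tuning, training, prediction and evaluation."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastccs.descriptors import DescriptorMatrix, autoscale_apply, autoscale_fit
from plastccs.modeling import (
    EvalReport,
    SplitSpec,
    SVMGrid,
    TrainedCCSModel,
    XGBGrid,
    _cv_folds,
    ablate_subset,
    evaluate,
    predict_ccs,
    relative_error,
    split_train_test,
    train_final,
    tune_svm,
    tune_xgb,
)


def toy_matrix(n=120, p=3, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    keys = [f"K{i:04d}" for i in range(n)]
    frame = pd.DataFrame(X, index=keys, columns=[f"d{j}" for j in range(p)])
    m = DescriptorMatrix(frame)
    if informative:
        y = 200.0 + 30.0 * X[:, 0] - 15.0 * X[:, 1] + rng.normal(scale=2.0, size=n)
    else:
        y = rng.normal(200.0, 30.0, size=n)
    return m, y


class TestSplit:
    def test_seven_three_split_of_ten(self):
        train, test = split_train_test([f"k{i}" for i in range(10)], SplitSpec(seed=1))
        assert len(train) == 7 and len(test) == 3

    def test_round_half_up(self):
        # 0.7 * 15 = 10.5 rounds up to 11
        train, test = split_train_test([f"k{i}" for i in range(15)], SplitSpec(seed=1))
        assert len(train) == 11 and len(test) == 4

    def test_deterministic_and_disjoint_exhaustive(self):
        keys = [f"k{i}" for i in range(57)]
        a = split_train_test(keys, SplitSpec(seed=9))
        b = split_train_test(keys, SplitSpec(seed=9))
        assert a == b
        train, test = a
        assert set(train) | set(test) == set(keys)
        assert set(train) & set(test) == set()

    def test_too_few_keys_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(["a"] * 9, SplitSpec())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.2)


class TestGrids:
    def test_svm_grid_has_72_combinations(self):
        combos = SVMGrid().combinations(n_descriptors=84)
        assert len(combos) == 72
        assert len({(c["C"], c["gamma"]) for c in combos}) == 72

    def test_svm_cost_divided_by_descriptor_count(self):
        combos = SVMGrid().combinations(n_descriptors=10)
        assert min(c["C"] for c in combos) == pytest.approx(0.001 / 10)
        assert max(c["C"] for c in combos) == pytest.approx(0.5 / 10)
        assert sorted({c["gamma"] for c in combos}) == [float(2**k) for k in range(9)]

    def test_xgb_grid_has_576_combinations(self):
        combos = XGBGrid().combinations()
        assert len(combos) == 576
        assert len({tuple(sorted(c.items())) for c in combos}) == 576


class TestCvFolds:
    def test_folds_partition_rows(self):
        folds = list(_cv_folds(97, 10, seed=1).split(np.zeros((97, 1))))
        seen = np.concatenate([va for _, va in folds])
        assert sorted(seen) == list(range(97))
        assert len(seen) == 97  # each row in exactly one validation fold

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            _cv_folds(5, 10, seed=1)


class TestTuneSvm:
    def test_single_combo_grid_passthrough(self):
        m, y = toy_matrix()
        grid = SVMGrid(c_base=(0.5,), gamma=(1.0,))
        best, table = tune_svm(m, y, grid, seed=1)
        assert len(table) == 1
        assert best["gamma"] == 1.0 and best["c_base"] == 0.5

    def test_full_grid_table_has_72_rows_each_touched_once(self):
        m, y = toy_matrix(n=60)
        _, table = tune_svm(m, y, k=5, seed=1)
        assert len(table) == 72
        assert table.duplicated(subset=["C", "gamma"]).sum() == 0

    def test_best_model_beats_mean_only_baseline(self):
        m, y = toy_matrix(n=300, seed=4)
        best, table = tune_svm(m, y, seed=4)
        assert table["rmsecv"].min() < statistics.stdev(y)

    def test_tie_break_is_listed_grid_order(self):
        m, y = toy_matrix(n=50)
        grid = SVMGrid(c_base=(0.1, 0.1), gamma=(2.0,))
        best, table = tune_svm(m, y, grid, k=5, seed=1)
        # identical combos tie exactly; argmin must take the first row
        assert table.iloc[0]["rmsecv"] == table.iloc[1]["rmsecv"]
        assert best["c_base"] == 0.1


class TestTuneXgb:
    def test_single_combo_passthrough_with_nrounds(self):
        m, y = toy_matrix(n=80)
        grid = XGBGrid(eta=(0.3,), max_depth=(3,), min_child_weight=(1,),
                       subsample=(0.8,), colsample_bytree=(0.8,), max_rounds=60)
        best, table = tune_xgb(m, y, grid, k=5, seed=1)
        assert len(table) == 1
        assert 1 <= best["nrounds"] <= 60

    def test_selected_model_beats_intercept_only(self):
        m, y = toy_matrix(n=200, seed=8)
        grid = XGBGrid(eta=(0.1, 0.3), max_depth=(3,), min_child_weight=(1,),
                       subsample=(0.8,), colsample_bytree=(0.8,), max_rounds=120)
        best, _ = tune_xgb(m, y, grid, k=5, seed=8)
        model = train_final(m, y, best, "xgb", seed=8)
        rmse = float(np.sqrt(np.mean((predict_ccs(model, m) - y) ** 2)))
        assert rmse < np.std(y)


class TestTrainPredict:
    def test_retrain_same_seed_identical_predictions(self):
        m, y = toy_matrix()
        params = {"C": 0.1, "gamma": 1.0, "epsilon": 0.1}
        p1 = predict_ccs(train_final(m, y, params, "svm", seed=2), m)
        p2 = predict_ccs(train_final(m, y, params, "svm", seed=2), m)
        assert np.array_equal(p1, p2)
        assert len(p1) == m.shape[0]

    @pytest.mark.parametrize("algorithm,params", [
        ("svm", {"C": 0.1, "gamma": 1.0, "epsilon": 0.1}),
        ("xgb", {"nrounds": 30, "eta": 0.3, "max_depth": 3,
                 "min_child_weight": 1, "subsample": 0.8, "colsample_bytree": 0.8}),
    ])
    def test_serialization_round_trip_preserves_predictions(
            self, tmp_path, algorithm, params):
        m, y = toy_matrix()
        model = train_final(m, y, params, algorithm, seed=1)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedCCSModel.load(path)
        assert np.array_equal(predict_ccs(model, m), predict_ccs(loaded, m))
        assert loaded.descriptor_names == model.descriptor_names

    def test_schema_version_mismatch_refused(self, tmp_path):
        import joblib

        m, y = toy_matrix()
        model = train_final(m, y, {"C": 0.1, "gamma": 1.0}, "svm")
        path = tmp_path / "model.joblib"
        model.save(path)
        payload = joblib.load(path)
        payload["schema_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="schema version"):
            TrainedCCSModel.load(path)

    def test_permuted_rows_give_permuted_predictions(self):
        m, y = toy_matrix()
        model = train_final(m, y, {"C": 0.1, "gamma": 1.0}, "svm")
        perm = list(reversed(m.row_keys))
        direct = predict_ccs(model, m.select_rows(perm))
        reordered = predict_ccs(model, m)[::-1]
        assert np.allclose(direct, reordered)

    def test_missing_descriptor_column_named_in_error(self):
        m, y = toy_matrix()
        model = train_final(m, y, {"C": 0.1, "gamma": 1.0}, "svm")
        partial = m.select_columns(m.col_names[:-1])
        with pytest.raises(KeyError, match=m.col_names[-1]):
            predict_ccs(model, partial)

    def test_unknown_algorithm_rejected(self):
        m, y = toy_matrix()
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_final(m, y, {}, "neural-net")


class TestRelativeError:
    def test_zero_when_equal(self):
        assert relative_error(200.0, 200.0) == 0.0

    def test_literature_vs_experimental_worked_example(self):
        # 211.4 vs 215.2 A^2: -1.77% which rounds to -1.8%
        err = relative_error(211.4, 215.2)
        assert err == pytest.approx(-1.766, abs=1e-3)
        assert round(err, 1) == -1.8

    def test_predicted_vs_experimental_example(self):
        assert relative_error(207.9, 215.2) == pytest.approx(-3.392, abs=1e-3)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(200.0, 0.0)


class TestEvaluate:
    def test_perfect_prediction(self):
        exp = np.array([150.0, 200.0, 250.0])
        rep = evaluate(exp, exp)
        assert rep.r2p == 1.0 and rep.rmsep == 0.0 and rep.mre_pct == 0.0
        assert rep.pct_within_2 == rep.pct_within_5 == 100.0

    def test_worked_example(self):
        exp = np.array([150.0, 200.0, 250.0])
        pred = np.array([153.0, 198.0, 245.0])
        rep = evaluate(pred, exp)
        assert rep.mre_pct == pytest.approx(2.0, abs=1e-12)
        assert rep.rmsep == pytest.approx(math.sqrt((9 + 4 + 25) / 3), abs=1e-9)
        assert rep.pct_within_2 == pytest.approx(100 / 3, abs=1e-9)
        assert rep.pct_within_3 == pytest.approx(100.0)

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))

    def test_matches_spreadsheet_style_recomputation(self, rng):
        """evaluate() agrees with a plain-Python reimplementation to 1e-10."""
        for _ in range(20):
            n = int(rng.integers(3, 40))
            exp = rng.uniform(120, 330, size=n)
            pred = exp * (1 + rng.normal(scale=0.03, size=n))
            rep = evaluate(pred, exp)
            rel = [(p - e) / e * 100.0 for p, e in zip(pred, exp)]
            abs_rel = sorted(abs(r) for r in rel)
            mid = len(abs_rel) // 2
            mre = (abs_rel[mid] if n % 2 else (abs_rel[mid - 1] + abs_rel[mid]) / 2)
            ss_res = sum((p - e) ** 2 for p, e in zip(pred, exp))
            mean_exp = sum(exp) / n
            ss_tot = sum((e - mean_exp) ** 2 for e in exp)
            assert abs(rep.rmsep - math.sqrt(ss_res / n)) < 1e-10
            assert abs(rep.r2p - (1 - ss_res / ss_tot)) < 1e-10
            assert abs(rep.mre_pct - mre) < 1e-10
            assert abs(rep.pct_within_5
                       - 100 * sum(a < 5 for a in abs_rel) / n) < 1e-10

    @given(st.lists(st.floats(min_value=-0.2, max_value=0.2),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_error_band_monotonicity(self, rel_errors):
        exp = np.full(len(rel_errors), 200.0)
        pred = exp * (1 + np.array(rel_errors))
        rep = evaluate(pred, exp)
        assert 0 <= rep.pct_within_2 <= rep.pct_within_3 <= rep.pct_within_5 <= 100


class TestAblation:
    def test_empty_predicate_gives_identical_reports(self):
        m, y = toy_matrix(n=80)
        scal = autoscale_fit(m)
        ms = autoscale_apply(m, scal)
        mtest, ytest = toy_matrix(n=40, seed=5)
        mtest = autoscale_apply(mtest, scal)
        out = ablate_subset(ms, y, mtest, ytest, lambda k: False,
                            {"C": 0.1, "gamma": 1.0}, "svm")
        assert out[("full", "all")].to_dict() == out[("filtered", "all")].to_dict()

    def test_tiny_filtered_training_rejected(self):
        m, y = toy_matrix(n=20)
        with pytest.raises(ValueError, match="too small"):
            ablate_subset(m, y, m, y, lambda k: True, {"C": 0.1, "gamma": 1.0})
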