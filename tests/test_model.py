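"""Cost-sensitive forest, OOB importance, LOOCV and forward selection."""

import numpy as np
import pandas as pd
import pytest

from icualarms.config import ModelConfig
from icualarms.model import (
    CostSensitiveForest,
    build_final_model,
    forward_selection,
    loocv_score,
    oob_importance,
    predict,
    train_rf,
    tune_fn_cost,
)
from icualarms.records import Arrhythmia, FeatureTable, Label


def make_table(n=100, informative=1, noise=4, sep=1.0, seed=0,
               arrhythmia=Arrhythmia.ASYSTOLE, ecg_pair=False):
    """Synthetic table: `informative` shifted features + pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    cols = {}
    for i in range(informative):
        cols[f"ecg1_f{i}"] = sep * y + 0.15 * rng.standard_normal(n)
        if ecg_pair:
            cols[f"ecg2_f{i}"] = sep * y + 0.15 * rng.standard_normal(n)
    for i in range(noise):
        cols[f"ppg_n{i}"] = rng.standard_normal(n)
    return FeatureTable(
        arrhythmia, pd.DataFrame(cols),
        [Label.TRUE_ALARM if v else Label.FALSE_ALARM for v in y],
        [f"r{i}" for i in range(n)], [284.0] * n,
    )


class TestForest:
    def test_separable_table_perfect_training_accuracy(self):
        tbl = make_table()
        clf = train_rf(tbl, seed=1)
        assert (clf.predict(tbl.features) == tbl.y).mean() == 1.0

    def test_deterministic_given_seed(self):
        tbl = make_table()
        p1 = train_rf(tbl, seed=5).predict_proba(tbl.features)
        p2 = train_rf(tbl, seed=5).predict_proba(tbl.features)
        assert np.array_equal(p1, p2)

    def test_stable_across_seeds_on_separable_data(self):
        tbl = make_table()
        a = train_rf(tbl, seed=1).predict(tbl.features)
        b = train_rf(tbl, seed=2).predict(tbl.features)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        tbl = make_table(n=20)
        one = tbl.subset_rows(np.flatnonzero(tbl.y == 1))
        with pytest.raises(ValueError, match="single class"):
            train_rf(one)

    def test_sklearn_estimator_protocol(self):
        clf = CostSensitiveForest(n_trees=11, cost_fn=1.3, random_state=2)
        params = clf.get_params()
        assert params["cost_fn"] == 1.3
        clf.set_params(n_trees=7)
        tbl = make_table(n=40)
        clf.fit(tbl.features, tbl.y)
        assert len(clf.estimators_) == 7
        assert clf.predict_proba(tbl.features).shape == (40, 2)

    def test_nan_features_imputed_with_training_medians(self):
        tbl = make_table(n=60)
        tbl.features.iloc[0, 0] = np.nan
        clf = train_rf(tbl, seed=3)
        lab, vote = predict(clf, {c: np.nan for c in tbl.feature_names})
        assert lab in (Label.TRUE_ALARM, Label.FALSE_ALARM)
        assert 0.0 <= vote <= 1.0

    def test_unknown_feature_rejected_at_predict(self):
        tbl = make_table(n=40)
        clf = train_rf(tbl, seed=1)
        bad = {c: 0.0 for c in tbl.feature_names}
        bad["surprise"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            predict(clf, bad)

    def test_equal_costs_match_unweighted_forest(self):
        tbl = make_table(n=80, sep=0.8)
        a = CostSensitiveForest(n_trees=51, cost_fp=1.0, cost_fn=1.0,
                                random_state=9).fit(tbl.features, tbl.y)
        b = CostSensitiveForest(n_trees=51, cost_fp=2.0, cost_fn=2.0,
                                random_state=9).fit(tbl.features, tbl.y)
        pa = a.predict_proba(tbl.features)[:, 1]
        pb = b.predict_proba(tbl.features)[:, 1]
        assert np.max(np.abs(pa - pb)) < 1e-12  # weights only set the ratio


class TestOobImportance:
    def test_label_feature_ranks_first(self):
        tbl = make_table(n=200, informative=1, noise=5, seed=4)
        imp = oob_importance(tbl, seed=4, n_trees=51)
        assert imp.idxmax() == "ecg1_f0"

    def test_noise_importance_near_zero(self):
        scores = []
        for seed in range(5):
            tbl = make_table(n=200, informative=1, noise=5, seed=seed)
            imp = oob_importance(tbl, seed=seed, n_trees=51)
            scores.append(imp.drop("ecg1_f0").abs().mean() / imp["ecg1_f0"])
        assert np.mean(scores) < 0.3

    def test_constant_feature_exactly_zero(self):
        tbl = make_table(n=60)
        tbl.features["const"] = 1.0
        tbl2 = FeatureTable(tbl.arrhythmia, tbl.features, tbl.labels,
                            tbl.record_ids, tbl.window_starts)
        imp = oob_importance(tbl2, seed=1, n_trees=31)
        assert imp["const"] == 0.0


class TestLoocv:
    def test_separable_scores_100(self):
        res = loocv_score(make_table(n=40), seed=2)
        assert res["score"] == 100.0

    def test_shuffled_labels_score_below_separable(self):
        tbl = make_table(n=60, seed=3)
        rng = np.random.default_rng(3)
        shuffled = FeatureTable(
            tbl.arrhythmia, tbl.features,
            [tbl.labels[i] for i in rng.permutation(len(tbl))],
            tbl.record_ids, tbl.window_starts)
        good = loocv_score(tbl, seed=3)["score"]
        bad = loocv_score(shuffled, seed=3)["score"]
        assert bad < good - 20

    def test_two_row_smoke(self):
        tbl = make_table(n=2)
        res = loocv_score(tbl, seed=1)
        assert 0.0 <= res["score"] <= 100.0

    def test_augmented_rows_held_out_together(self):
        """A record's duplicated rows must never straddle train/test."""
        tbl = make_table(n=40)
        # duplicate rows with identical record ids (window augmentation)
        feats = pd.concat([tbl.features, tbl.features.iloc[:8]],
                          ignore_index=True)
        labels = tbl.labels + tbl.labels[:8]
        rids = tbl.record_ids + tbl.record_ids[:8]
        starts = tbl.window_starts + [294.0] * 8
        aug = FeatureTable(tbl.arrhythmia, feats, labels, rids, starts)
        res = loocv_score(aug, seed=1)
        # 40 unique records counted once each
        assert res["tp"] + res["tn"] + res["fp"] + res["fn"] == 40

    def test_full_set_beats_random_subset(self):
        tbl = make_table(n=60, informative=2, noise=6, seed=7, ecg_pair=False)
        full = loocv_score(tbl, feature_subset=["ecg1_f0", "ecg1_f1"],
                           seed=7)["score"]
        noise_only = loocv_score(tbl, feature_subset=["ppg_n0", "ppg_n1"],
                                 seed=7)["score"]
        assert full >= noise_only


class TestForwardSelection:
    def test_informative_pair_found_and_x_small(self):
        tbl = make_table(n=80, informative=2, noise=8, seed=5)
        sel = forward_selection(tbl, seed=5)
        assert sel["chosen_x"] <= 4
        assert {"ecg1_f0", "ecg1_f1"} <= set(sel["final_features"])

    def test_expansion_rule_arithmetic(self):
        import math
        cfg = ModelConfig()
        assert math.ceil(cfg.expansion * 5) == 6

    def test_ecg_twin_symmetrization(self):
        tbl = make_table(n=80, informative=1, noise=6, seed=6, ecg_pair=True)
        sel = forward_selection(tbl, seed=6)
        final = set(sel["final_features"])
        assert ("ecg1_f0" in final) == ("ecg2_f0" in final)
        assert "ecg1_f0" in final


class TestCostTuning:
    def test_single_value_grid(self):
        tbl = make_table(n=40)
        out = tune_fn_cost(tbl, grid=(1.3,), seed=1)
        assert out["best_cost_fn"] == 1.3

    def test_tie_broken_to_smallest_cost(self):
        tbl = make_table(n=40)  # separable: all costs score 100
        out = tune_fn_cost(tbl, grid=(1.0, 1.1, 1.2), seed=1)
        assert out["best_cost_fn"] == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tune_fn_cost(make_table(n=40), grid=())

    def test_higher_fn_cost_does_not_reduce_tpr(self):
        """Harder positives: raising the FN cost shifts votes toward true."""
        rng = np.random.default_rng(11)
        n = 60
        y = np.repeat([0, 1], n // 2)
        x = np.where(y == 1, 0.55, 0.0) + rng.standard_normal(n)
        tbl = FeatureTable(
            Arrhythmia.TACHYCARDIA, pd.DataFrame({"ecg1_x": x}),
            [Label.TRUE_ALARM if v else Label.FALSE_ALARM for v in y],
            [f"r{i}" for i in range(n)], [280.0] * n)
        lo = loocv_score(tbl, cost_fn=1.0, seed=11, n_trees=51)
        hi = loocv_score(tbl, cost_fn=2.0, seed=11, n_trees=51)
        assert hi["tp"] >= lo["tp"]


class TestFinalModel:
    def test_bundle_selects_informative_pair_and_round_trips(self, tmp_path):
        tbl = make_table(n=60, informative=1, noise=4, seed=8, ecg_pair=True)
        model = build_final_model(tbl, seed=8)
        assert {"ecg1_f0", "ecg2_f0"} <= set(model.selected_features)
        assert 1.0 <= model.cost_fn <= 2.0
        meta = model.save(tmp_path)
        from icualarms.model import TrainedAlarmModel
        back = TrainedAlarmModel.load(meta)
        row = tbl.features.iloc[0].to_dict()
        assert back.predict_record([row]) == model.predict_record([row])

    def test_deterministic_given_seed(self):
        tbl = make_table(n=60, informative=1, noise=4, seed=8)
        m1 = build_final_model(tbl, seed=8)
        m2 = build_final_model(tbl, seed=8)
        assert m1.selected_features == m2.selected_features
        assert m1.cost_fn == m2.cost_fn

    def test_empty_table_rejected(self):
        tbl = make_table(n=40)
        empty = tbl.subset_rows(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            build_final_model(empty)
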