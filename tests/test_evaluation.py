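import numpy as np
import pandas as pd
import pytest

from eegtda import (chance_level, classify_loso, loso_folds, metric_suite,
                    regress_loso)
from eegtda.tda import FEATURE_NAMES


def indicator_table(rng, n_subjects=6, n_mci=3, n_epochs=10, noise=0.0):
    """Feature table where one feature encodes the class label exactly."""
    rows = []
    for s in range(n_subjects):
        group = "mci" if s < n_mci else "healthy"
        moca = 20 if group == "mci" else 28
        for i in range(n_epochs):
            feats = {name: rng.normal() for name in FEATURE_NAMES}
            feats["total_cycles"] = (1.0 if group == "mci" else 0.0) \
                + noise * rng.normal()
            rows.append({"subject_id": f"s{s}", "group": group,
                         "moca": moca + rng.integers(-1, 2),
                         "condition": "TGT" if i % 2 else "IGN",
                         "session": 0, **feats})
    return pd.DataFrame(rows)


class TestLosoFolds:
    def test_partition_and_leakage(self, rng):
        table = indicator_table(rng)
        folds = loso_folds(table)
        assert len(folds) == 6
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(len(table)))
        subjects = table["subject_id"].to_numpy()
        for train, test in folds:
            assert set(subjects[train]).isdisjoint(set(subjects[test]))

    def test_single_subject_rejected(self, rng):
        table = indicator_table(rng, n_subjects=1, n_mci=0)
        with pytest.raises(ValueError):
            loso_folds(table)


class TestChanceLevel:
    @pytest.mark.parametrize("labels,expected", [
        (["mci"] * 16 + ["healthy"] * 7, 70),
        (["a"] * 10 + ["b"] * 10, 50),
        (["a"] * 3 + ["b"], 75),
    ])
    def test_majority_percent(self, labels, expected):
        assert chance_level(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            chance_level([])


class TestMetricSuite:
    def test_confusion_matrix_arithmetic(self):
        y_true = np.array(["mci", "mci", "healthy", "healthy"])
        y_pred = np.array(["mci", "healthy", "healthy", "healthy"])
        m = metric_suite(y_true, y_pred)
        assert m["accuracy"] == 75.0
        # MCI as positive class, by hand: precision 1.0, recall 0.5
        prec, rec = 1.0, 0.5
        assert m["f1_mci"] == pytest.approx(2 * prec * rec / (prec + rec))

    def test_all_correct(self):
        y = np.array(["mci", "healthy", "mci"])
        m = metric_suite(y, y, scores=np.array([0.9, 0.1, 0.8]))
        for k in ("f1", "recall", "precision", "auc"):
            assert m[k] == 1.0
        assert m["accuracy"] == 100.0

    def test_degenerate_auc_is_nan_with_warning(self):
        y = np.array(["mci", "mci"])
        with pytest.warns(UserWarning):
            m = metric_suite(y, y, scores=np.array([0.7, 0.9]))
        assert m["accuracy"] == 100.0
        assert np.isnan(m["auc"])

    def test_regression_examples(self):
        perfect = metric_suite([20, 25, 30], [20, 25, 30], task="regression")
        assert perfect["r2"] == 1.0
        assert perfect["mse"] == perfect["mae"] == perfect["mape"] == 0.0
        y = np.array([20.0, 25.0, 30.0])
        const = metric_suite(y, np.full(3, y.mean()), task="regression")
        assert const["r2"] == pytest.approx(0.0)
        m = metric_suite([20, 25, 30], [22, 24, 33], task="regression")
        assert m["mae"] == pytest.approx(2.0)
        assert m["mape"] == pytest.approx((2 / 20 + 1 / 25 + 3 / 30) * 100 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metric_suite([1, 2], [1], task="regression")


class TestClassifyLoso:
    def test_perfect_indicator_feature_gives_ceiling(self, rng):
        panel, folds = classify_loso(indicator_table(rng), seed=0)
        assert panel.pooled["accuracy"] == 100.0
        assert panel.pooled["f1"] == 1.0
        assert panel.median["accuracy"] == 100.0
        assert len(folds) == 6

    def test_seeded_determinism(self, rng):
        table = indicator_table(rng, noise=2.0)
        p1, _ = classify_loso(table, seed=5)
        p2, _ = classify_loso(table, seed=5)
        assert p1.median == p2.median
        assert p1.pooled == p2.pooled

    def test_single_class_training_fold_rejected(self, rng):
        table = indicator_table(rng, n_subjects=3, n_mci=2)
        all_mci = table[table["group"] == "mci"]  # single-class study
        with pytest.raises(ValueError, match="single class"):
            classify_loso(all_mci)

    def test_per_subject_vote_uniform_predictions(self, rng):
        _, folds = classify_loso(indicator_table(rng, noise=2.0),
                                 per_subject_vote=True, seed=0)
        for f in folds:
            assert len(set(f.predicted_labels)) == 1


class TestRegressLoso:
    def test_moca_recovered_from_indicator(self, rng):
        table = indicator_table(rng, n_epochs=12)
        panel, folds = regress_loso(table, seed=0)
        assert panel.pooled["mae"] < 3.0
        assert len(folds) == 6
        for f in folds:
            assert f.metrics["mae"] <= np.sqrt(f.metrics["mse"]) + 1e-12

    def test_condition_filtering_changes_n(self, rng):
        table = indicator_table(rng)
        _, folds_tgt = regress_loso(table, condition="TGT", seed=0)
        n_tgt = sum(len(f.predicted_moca) for f in folds_tgt)
        assert n_tgt == (table["condition"] == "TGT").sum()


class TestRecovery:
    def test_classification_beats_chance_at_full_effect(self, recovery_study):
        profiles, features = recovery_study
        chance = chance_level(profiles["group"])
        assert chance == 57  # 13 of 23 impaired
        panel, _ = classify_loso(features, condition="ALL", seed=0)
        assert panel.pooled["accuracy"] > chance
        assert panel.median["accuracy"] > chance

    def test_moca_mae_below_cohort_sd(self, recovery_study):
        profiles, features = recovery_study
        sd = float(np.std(profiles["moca"]))
        panel, _ = regress_loso(features, condition="ALL", seed=0)
        assert panel.pooled["mae"] < sd
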