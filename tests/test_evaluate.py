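import numpy as np
import pandas as pd
import pytest

from eegattn.evaluate import (
    ABLATION_SUBSETS,
    ConfusionCounts,
    ablation,
    attention_rate,
    confusion,
    evaluate,
    grouped_evaluate,
    inattention_rate,
    stratified_kfold,
    weighted_accuracy,
)
from eegattn.features import FEATURE_COLUMNS
from eegattn.io import ATTENTIVE, INATTENTIVE
from eegattn.kernels import KernelSpec


def _balanced_frame(n_per_class, rng=None):
    rng = rng or np.random.default_rng(0)
    n = 2 * n_per_class
    df = pd.DataFrame(rng.normal(size=(n, 5)), columns=FEATURE_COLUMNS)
    df["label"] = [ATTENTIVE] * n_per_class + [INATTENTIVE] * n_per_class
    df["group"] = ["M", "F"] * n_per_class
    return df


class TestStratifiedKfold:
    def test_balanced_2400_rows_split_five_ways(self):
        df = _balanced_frame(1200)
        folds = stratified_kfold(df, k=5, seed=0)
        assert len(folds) == 5
        y = df["label"].to_numpy()
        for test_idx in folds:
            assert len(test_idx) == 480
            assert (y[test_idx] == ATTENTIVE).sum() == 240
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(2400))

    def test_two_folds_of_four_rows(self):
        df = _balanced_frame(2)
        folds = stratified_kfold(df, k=2, seed=1)
        y = df["label"].to_numpy()
        for test_idx in folds:
            assert len(test_idx) == 2
            assert (y[test_idx] == ATTENTIVE).sum() == 1

    def test_same_seed_same_partition(self):
        df = _balanced_frame(50)
        a = stratified_kfold(df, k=5, seed=9)
        b = stratified_kfold(df, k=5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(_balanced_frame(3), k=4, seed=0)


class TestConfusionAndRates:
    def test_perfect_prediction(self):
        truth = [ATTENTIVE] * 10 + [INATTENTIVE] * 10
        c = confusion(truth, truth)
        assert (c.TA, c.TI, c.CA, c.CI) == (10, 10, 10, 10)
        assert c.accuracy == 100.0

    def test_all_attentive_prediction(self):
        truth = np.array([ATTENTIVE] * 10 + [INATTENTIVE] * 10)
        c = confusion(np.full(20, ATTENTIVE), truth)
        assert (c.CA, c.CI) == (10, 0)

    def test_empty_input_all_zero(self):
        c = confusion([], [])
        assert (c.TA, c.TI, c.CA, c.CI) == (0, 0, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([ATTENTIVE], [])

    def test_rate_arithmetic(self):
        assert attention_rate(ConfusionCounts(TA=2400, TI=0, CA=1800, CI=0)) == 75.0
        assert inattention_rate(ConfusionCounts(TA=0, TI=2400, CA=0, CI=1200)) == 50.0
        assert attention_rate(ConfusionCounts(TA=5, TI=0, CA=5, CI=0)) == 100.0

    def test_undefined_rates_raise(self):
        empty = ConfusionCounts()
        with pytest.raises(ZeroDivisionError):
            attention_rate(empty)
        with pytest.raises(ZeroDivisionError):
            inattention_rate(empty)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TA=5, TI=5, CA=6, CI=0)


class TestWeightedAccuracy:
    def test_prevalence_formula(self):
        assert weighted_accuracy(90.0, 50.0, 0.1) == pytest.approx(86.0)
        assert weighted_accuracy(100.0, 100.0, 0.37) == 100.0
        assert weighted_accuracy(80.0, 40.0, 0.0) == 80.0

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_prevalence_rejected(self, p):
        with pytest.raises(ValueError):
            weighted_accuracy(90.0, 50.0, p)


class TestEvaluate:
    def test_fold_accounting_and_report_consistency(self, small_effect_dataset):
        rep = evaluate(small_effect_dataset, C=1, k=5, seed=3)
        total = sum(c.TA + c.TI for c in rep.per_fold_counts)
        assert total == len(small_effect_dataset)
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.per_fold_accuracy), abs=1e-9)
        assert rep.best_accuracy == max(rep.per_fold_accuracy)
        pooled = rep.pooled
        assert pooled.TA == sum(c.TA for c in rep.per_fold_counts)
        assert rep.AR == pytest.approx(100.0 * pooled.CA / pooled.TA)

    def test_balanced_pooled_accuracy_is_rate_mean(self, small_effect_dataset):
        """With TA = TI the pooled accuracy equals (AR + IR)/2 exactly."""
        rep = evaluate(small_effect_dataset, C=1, k=5, seed=3)
        assert rep.pooled.TA == rep.pooled.TI
        assert rep.pooled.accuracy == pytest.approx((rep.AR + rep.IR) / 2, abs=1e-9)

    def test_deterministic_given_seed(self, small_effect_dataset):
        a = evaluate(small_effect_dataset, C=1, k=5, seed=7)
        b = evaluate(small_effect_dataset, C=1, k=5, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_excluding_informative_bands_hurts(self, small_effect_dataset):
        """Features blind to the simulated band shifts sit near chance."""
        full = evaluate(small_effect_dataset, C=1, k=5, seed=3)
        delta_only = evaluate(
            small_effect_dataset, C=1, k=5, seed=3, features=("E_delta",)
        )
        assert delta_only.mean_accuracy < full.mean_accuracy
        assert delta_only.mean_accuracy < 62.0

    def test_empty_feature_subset_rejected(self, small_effect_dataset):
        with pytest.raises(ValueError):
            evaluate(small_effect_dataset, features=())
        with pytest.raises(ValueError):
            evaluate(small_effect_dataset, features=("E_gamma",))


class TestAblationGrid:
    def test_grid_structure(self, small_effect_dataset):
        grid = ablation(small_effect_dataset, C=1, k=3, seed=1)
        assert len(grid) == 6 * 2
        assert len(ABLATION_SUBSETS) == 6
        assert set(grid["kernel"]) == {"polykernel", "normalized_polykernel"}
        for col in (
            "mean_train_accuracy",
            "mean_kfold_accuracy",
            "best_train_accuracy",
            "best_kfold_accuracy",
        ):
            assert grid[col].between(0, 100).all()


class TestGroupedEvaluate:
    def test_groups_partition_rows(self, small_effect_dataset):
        reports = grouped_evaluate(small_effect_dataset, C=1, k=3, seed=2)
        assert set(reports) == {"M", "F"}
        n = sum(r.pooled.TA + r.pooled.TI for r in reports.values())
        assert n == len(small_effect_dataset)

    def test_single_class_group_skipped_with_warning(self, small_effect_dataset, caplog):
        df = small_effect_dataset.copy()
        df.loc[df["group"] == "F", "label"] = ATTENTIVE
        with caplog.at_level("WARNING"):
            reports = grouped_evaluate(df, C=1, k=3, seed=2)
        assert set(reports) == {"M"}
        assert "skipped" in caplog.text

    def test_identical_generator_groups_statistically_close(self, small_effect_dataset):
        """M and F rows come from the same process → similar accuracies."""
        reports = grouped_evaluate(small_effect_dataset, C=1, k=5, seed=2)
        accs = [r.mean_accuracy for r in reports.values()]
        n = min(r.pooled.TA + r.pooled.TI for r in reports.values())
        se = 100 * np.sqrt(0.25 / n)
        assert abs(accs[0] - accs[1]) < 4 * se
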