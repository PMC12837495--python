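"""Evaluation framework: fold assignment, ROC/AUC vs pairwise oracle,
Youden cut-off scan, confusion-rate arithmetic, comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctacollat import evalstats as ev


def pairwise_auc_oracle(labels, probs):
    """Mann-Whitney formulation: (#{pos>neg} + 0.5*#{ties}) / (n_pos*n_neg)."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_scan_oracle(labels, probs):
    """Exhaustive threshold scan for the maximal Youden index."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    best = (-2.0, -1.0, None)
    for c in np.unique(probs):
        pred = probs >= c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if (j, sens) > best[:2]:
            best = (j, sens, c)
    return best


class TestAssignFolds:
    def test_157_patients_give_balanced_folds(self):
        patients = [(f"p{i}", 1 if i < 117 else 0) for i in range(157)]
        fa = ev.assign_folds(patients, k=5, seed=0)
        sizes = sorted(
            (np.array(list(fa.folds.values())) == f).sum() for f in range(5)
        )
        assert sizes == [31, 31, 31, 32, 32]

    def test_every_patient_in_exactly_one_fold(self):
        patients = [(f"p{i}", i % 2) for i in range(23)]
        fa = ev.assign_folds(patients, k=5, seed=1)
        assert set(fa.folds) == {f"p{i}" for i in range(23)}
        assert set(fa.folds.values()) <= set(range(5))

    def test_deterministic_under_seed(self):
        patients = [(f"p{i}", i % 2) for i in range(40)]
        assert (
            ev.assign_folds(patients, seed=7).folds
            == ev.assign_folds(patients, seed=7).folds
        )

    def test_stratification_keeps_minority_in_every_fold(self):
        patients = [(f"p{i}", 1 if i < 117 else 0) for i in range(157)]
        fa = ev.assign_folds(patients, k=5, seed=3)
        for f in range(5):
            labels = [lab for (pid, lab) in patients if fa.folds[pid] == f]
            assert 0 in labels and 1 in labels

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            ev.assign_folds([("a", 1), ("b", 0)], k=5)


class TestSplitTrainVal:
    def test_124_patients_split_93_31(self):
        patients = [(f"p{i}", 1 if i < 90 else 0) for i in range(124)]
        train, val = ev.split_train_val(patients, seed=0)
        assert len(train) == 93 and len(val) == 31

    def test_disjoint_and_complete(self):
        patients = [(f"p{i}", i % 2) for i in range(40)]
        train, val = ev.split_train_val(patients, seed=2)
        ids = {p for p, _ in train} | {p for p, _ in val}
        assert len(ids) == 40
        assert not ({p for p, _ in train} & {p for p, _ in val})

    def test_both_classes_in_val_when_both_present(self):
        patients = [(f"p{i}", 1 if i < 30 else 0) for i in range(36)]
        for seed in range(5):
            _, val = ev.split_train_val(patients, seed=seed)
            labs = {lab for _, lab in val}
            assert labs == {0, 1}

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            ev.split_train_val([("a", 1), ("b", 0)])


class TestRocAndAuc:
    def test_perfectly_separated(self):
        labels = [0, 0, 1, 1]
        assert ev.roc_and_auc(labels, [0.1, 0.2, 0.8, 0.9]).auc == pytest.approx(1.0)

    def test_identical_probabilities(self):
        assert ev.roc_and_auc([0, 1, 0, 1], [0.5] * 4).auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(10, 31))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            probs = np.round(rng.random(n), 2)  # coarse grid forces ties
            roc = ev.roc_and_auc(labels, probs)
            assert roc.auc == pytest.approx(pairwise_auc_oracle(labels, probs))

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        roc = ev.roc_and_auc(labels, rng.random(30))
        assert (np.diff(roc.sensitivity) >= -1e-12).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ev.roc_and_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestYoudenAndOverall:
    def test_table_arithmetic_sensitivity_oriented(self):
        # 102/117 correct positives, 26/40 correct negatives
        assert ev.youden(102 / 117, 26 / 40) == pytest.approx(0.522, abs=5e-4)

    def test_table_arithmetic_balanced(self):
        assert ev.youden(85 / 117, 31 / 40) == pytest.approx(0.501, abs=5e-4)

    def test_degenerate_values(self):
        assert ev.youden(1.0, 1.0) == pytest.approx(1.0)
        assert ev.youden(0.5, 0.5) == pytest.approx(0.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ev.youden(1.2, 0.5)

    @pytest.mark.parametrize(
        "j,auc,expected",
        [(0.521795, 0.773, 0.647), (0.482479, 0.753, 0.618), (0.0, 0.5, 0.25)],
    )
    def test_overall_performance(self, j, auc, expected):
        assert ev.overall_performance(j, auc) == pytest.approx(expected, abs=5e-4)

    def test_overall_performance_monotone(self):
        base = ev.overall_performance(0.4, 0.7)
        assert ev.overall_performance(0.5, 0.7) > base
        assert ev.overall_performance(0.4, 0.8) > base


class TestOptimalCutoff:
    def test_separable_reaches_youden_one(self):
        labels = [0, 0, 0, 1, 1, 1]
        probs = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        cutoff, s = ev.optimal_cutoff(labels, probs)
        assert s.optimal_youden == pytest.approx(1.0)
        assert 0.3 < cutoff <= 0.7

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            labels = rng.integers(0, 2, 20)
            labels[:2] = [0, 1]
            probs = np.round(rng.random(20), 2)
            cutoff, s = ev.optimal_cutoff(labels, probs)
            j_star, sens_star, _ = youden_scan_oracle(labels, probs)
            assert s.optimal_youden == pytest.approx(j_star)
            assert s.sensitivity == pytest.approx(sens_star)

    def test_argmax_property(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        probs = rng.random(25)
        cutoff, s = ev.optimal_cutoff(labels, probs)
        for c in np.unique(probs):
            pred = probs >= c
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            assert s.optimal_youden >= sens + spec - 1 - 1e-12

    def test_summary_invariants(self):
        labels = [0, 1, 0, 1, 1, 0, 1]
        probs = [0.2, 0.6, 0.4, 0.8, 0.5, 0.3, 0.9]
        _, s = ev.optimal_cutoff(labels, probs)
        assert s.optimal_youden == pytest.approx(s.sensitivity + s.specificity - 1)
        assert s.overall_performance == pytest.approx((s.optimal_youden + s.auc) / 2)
        assert 0 <= s.accuracy <= 1


class TestRatesToCounts:
    @pytest.mark.parametrize(
        "sens,spec,n_pos,n_neg,tp,tn,acc",
        [
            (87.18, 65.00, 117, 40, 102, 26, 0.8153),
            (63.25, 85.00, 117, 40, 74, 34, 0.6879),
            (72.65, 77.50, 117, 40, 85, 31, 0.7389),
            (100.0, 100.0, 10, 10, 10, 10, 1.0),
        ],
    )
    def test_confusion_recovery(self, sens, spec, n_pos, n_neg, tp, tn, acc):
        TP, FN, TN, FP, accuracy = ev.rates_to_counts(sens, spec, n_pos, n_neg)
        assert (TP, TN) == (tp, tn)
        assert TP + FN == n_pos and TN + FP == n_neg
        assert accuracy == pytest.approx(acc, abs=5e-5)

    def test_inconsistent_rate_warns(self):
        with pytest.warns(UserWarning):
            ev.rates_to_counts(50.0, 93.0, 3, 40)  # 50% of 3 is not near an integer

    def test_bad_cohort_raises(self):
        with pytest.raises(ValueError):
            ev.rates_to_counts(50, 50, 0, 10)


class TestOrientation:
    def test_signed_difference(self):
        s = ev.PerformanceSummary(
            auc=0.773, cutoff=0.5, sensitivity=0.8718, specificity=0.65,
            accuracy=0.8153, optimal_youden=0.5218, overall_performance=0.647,
        )
        assert ev.orientation(s) == pytest.approx(0.2218, abs=1e-4)

    def test_balanced_is_zero(self):
        s = ev.PerformanceSummary(0.7, 0.5, 0.75, 0.75, 0.75, 0.5, 0.6)
        assert ev.orientation(s) == 0.0


def _grid_results(effect=0.0, seed=0, n_per_cell=1):
    """Synthetic full-grid results table with an optional kernel effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in (3, 5, 7):
        for f in (8, 16):
            for n in (2, 3, 4, 5):
                for fc in (64, 128):
                    for b in (8, 16, 32, 64):
                        rows.append(
                            {
                                "kernel_size": k,
                                "first_filters": f,
                                "n_conv": n,
                                "fc_nodes": fc,
                                "batch_size": b,
                                "overall_performance": rng.normal(
                                    0.6 + effect * (k == 7), 0.05
                                ),
                            }
                        )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_paired_samples_give_t0_p1(self):
        df = _grid_results(effect=0.0, seed=1)
        # duplicate one kernel level onto another: identical pairs
        base = df[df.kernel_size == 3].copy()
        for k in (5, 7):
            dup = base.copy()
            dup["kernel_size"] = k
            df = pd.concat([df[df.kernel_size != k], dup], ignore_index=True)
        report = ev.compare_groups(df, "kernel_size", paired=True)
        row = report[(report.level_a == 5) & (report.level_b == 7)].iloc[0]
        assert row.statistic == 0.0 and row.p_value == 1.0

    def test_paired_detects_planted_effect(self):
        df = _grid_results(effect=0.08, seed=2)
        report = ev.compare_groups(df, "kernel_size", paired=True)
        row = report[(report.level_a == 3) & (report.level_b == 7)].iloc[0]
        assert row.test == "paired t" and row.p_value < 0.05

    def test_unpaired_shifted_normals_significant(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "n_conv": [2] * 40 + [4] * 40,
                "overall_performance": np.concatenate(
                    [rng.normal(0.5, 0.05, 40), rng.normal(0.55, 0.05, 40)]
                ),
            }
        )
        report = ev.compare_groups(df, "n_conv", paired=False)
        row = report.iloc[0]
        assert row.test == "independent t"  # n >= 30: central-limit rule
        assert row.p_value < 0.05

    def test_small_nonnormal_groups_use_mann_whitney(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "n_conv": [2] * 12 + [4] * 12,
                "overall_performance": np.concatenate(
                    [rng.exponential(1.0, 12), rng.exponential(1.5, 12)]
                ),
            }
        )
        report = ev.compare_groups(df, "n_conv", paired=False)
        assert report.iloc[0]["test"] == "Mann-Whitney U"
        # the rule actually consulted Shapiro-Wilk
        assert report.iloc[0]["shapiro_min_p"] < 0.05

    def test_unmatched_pairs_raise(self):
        df = _grid_results(seed=7)
        df = df.drop(df[(df.kernel_size == 7)].index[:3])
        with pytest.raises(ValueError, match="unmatched"):
            ev.compare_groups(df, "kernel_size", paired=True)

    def test_unknown_column_raises(self):
        with pytest.raises(ValueError):
            ev.compare_groups(_grid_results(), "dropout", paired=True)
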