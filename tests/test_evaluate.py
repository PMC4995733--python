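import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.dummy import DummyClassifier

from redoxcys.evaluate import (
    ConfusionCounts,
    confusion,
    cross_validate,
    evaluate_by_group,
    metrics,
    roc_and_auc,
    sample_balanced_negatives,
)
from redoxcys.model import ScalingParams, SVMParams, TrainedModel, train_svm
from redoxcys.seqio import CysteineSite, SiteTable


def mann_whitney_auc(scores, y):
    """Independent AUC oracle: normalised rank-sum of the positive scores."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    ranks = rankdata(scores)
    n_pos, n_neg = np.sum(y == 1), np.sum(y == -1)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusion:
    def test_simple_counts(self):
        c = confusion([1, -1], [1, -1])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_flipping_predictions_swaps_counts(self, rng):
        y = rng.choice([1, -1], size=50)
        p = rng.choice([1, -1], size=50)
        a, b = confusion(y, p), confusion(y, -p)
        assert (a.TP, a.TN, a.FP, a.FN) == (b.FN, b.FP, b.TN, b.TP)

    def test_matches_brute_force_count(self, rng):
        for _ in range(20):
            y = rng.choice([1, -1], size=30)
            p = rng.choice([1, -1], size=30)
            c = confusion(y, p)
            oracle = {
                "TP": sum(1 for a, b in zip(y, p) if a == 1 and b == 1),
                "TN": sum(1 for a, b in zip(y, p) if a == -1 and b == -1),
                "FP": sum(1 for a, b in zip(y, p) if a == -1 and b == 1),
                "FN": sum(1 for a, b in zip(y, p) if a == 1 and b == -1),
            }
            assert (c.TP, c.TN, c.FP, c.FN) == tuple(oracle.values())

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([1, 0], [1, -1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(50, 50, 0, 0))
        assert (m.SN, m.SP, m.ACC, m.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_chance_level(self):
        m = metrics(ConfusionCounts(25, 25, 25, 25))
        assert m.ACC == 0.5 and m.MCC == 0.0

    def test_hand_computed_case(self):
        m = metrics(ConfusionCounts(TP=60, TN=40, FP=10, FN=20))
        assert m.SN == pytest.approx(0.75)
        assert m.SP == pytest.approx(0.8)
        assert m.ACC == pytest.approx(100 / 130)
        assert m.MCC == pytest.approx(2200 / np.sqrt(70 * 80 * 50 * 60))

    def test_zero_denominator_mcc_is_zero(self):
        assert metrics(ConfusionCounts(5, 0, 0, 5)).MCC == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_formula_oracle_on_random_tables(self, rng):
        """Definitions re-evaluated independently agree to 1e-12."""
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            sn = tp / (tp + fn) if tp + fn else 0.0
            sp = tn / (tn + fp) if tn + fp else 0.0
            acc = (tp + tn) / (tp + tn + fp + fn)
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
            assert abs(m.SN - sn) < 1e-12 and abs(m.SP - sp) < 1e-12
            assert abs(m.ACC - acc) < 1e-12 and abs(m.MCC - mcc) < 1e-12


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_and_auc([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert curve.auc == 1.0

    def test_identical_scores_give_diagonal(self):
        curve = roc_and_auc([0.5] * 6, [1, -1, 1, -1, 1, -1])
        assert curve.auc == pytest.approx(0.5)
        assert len(curve.fpr) == 2  # a single tied step plus the origin

    def test_curve_endpoints(self, rng):
        scores = rng.normal(size=40)
        y = rng.choice([1, -1], size=40)
        if len(set(y)) < 2:
            y[0], y[1] = 1, -1
        curve = roc_and_auc(scores, y)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_matches_mann_whitney_statistic(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = np.r_[np.ones(n // 2, int), -np.ones(n - n // 2, int)]
            scores = np.round(rng.normal(size=n), 1)  # coarse: force ties
            assert roc_and_auc(scores, y).auc == pytest.approx(
                mann_whitney_auc(scores, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.choice([1, -1], size=50)
        y[:2] = [1, -1]
        scores = rng.normal(size=50)
        a = roc_and_auc(scores, y).auc
        b = roc_and_auc(np.exp(scores) * 3 + 1, y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_auc([1.0, 2.0], [1, 1])


def _majority_model(n_features):
    """A chance-level trainer: uniform class prior, constant scores."""
    est = DummyClassifier(strategy="prior")
    return est


def separable_design(n=100, p=4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    X = rng.normal(size=(n, p)) + 3.0 * y[:, None]
    return X, y


class TestCrossValidate:
    def test_stratification_balances_every_fold(self):
        X, y = separable_design(n=100)
        trainer = lambda Xt, yt, s: train_svm(Xt, yt, SVMParams(C=1, gamma=0.1), seed=s)
        report = cross_validate(X, y, trainer, k=10, seed=0)
        for fold in range(10):
            mask = report.fold_assignment == fold
            assert np.sum(y[mask] == 1) == 5 and np.sum(y[mask] == -1) == 5

    def test_chance_trainer_scores_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = np.array([1, -1] * 50)

        def trainer(Xt, yt, s):
            est = DummyClassifier(strategy="prior").fit(Xt, yt)
            from redoxcys.model import scale_fit

            return TrainedModel(kind="naive_bayes", estimator=est, scaling=scale_fit(Xt))

        report = cross_validate(X, y, trainer, k=10, seed=0)
        assert abs(report.aggregate.ACC - 0.5) <= 0.1
        assert abs(report.aggregate.AUC - 0.5) <= 0.05

    def test_separable_signal_recovers_high_auc(self):
        aucs = []
        for seed in range(5):
            X, y = separable_design(seed=seed)
            trainer = lambda Xt, yt, s: train_svm(Xt, yt, SVMParams(C=1, gamma=0.1), seed=s)
            aucs.append(cross_validate(X, y, trainer, k=10, seed=seed).aggregate.AUC)
        assert np.median(aucs) > 0.95

    def test_aggregate_acc_between_fold_extremes(self):
        X, y = separable_design(n=60, seed=3)
        X += np.random.default_rng(0).normal(size=X.shape) * 2
        trainer = lambda Xt, yt, s: train_svm(Xt, yt, SVMParams(C=1, gamma=0.1), seed=s)
        report = cross_validate(X, y, trainer, k=5, seed=0)
        accs = [m.ACC for m in report.fold_metrics]
        assert min(accs) <= report.aggregate.ACC <= max(accs)

    def test_k_larger_than_class_count_rejected(self):
        X, y = separable_design(n=10)
        trainer = lambda Xt, yt, s: train_svm(Xt, yt, seed=s)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(X, y, trainer, k=8, seed=0)

    def test_deterministic_under_seed(self):
        X, y = separable_design(n=60, seed=2)
        trainer = lambda Xt, yt, s: train_svm(Xt, yt, SVMParams(C=1, gamma=0.1), seed=s)
        a = cross_validate(X, y, trainer, k=5, seed=9)
        b = cross_validate(X, y, trainer, k=5, seed=9)
        assert a.aggregate == b.aggregate
        np.testing.assert_array_equal(a.scores, b.scores)


class TestByGroup:
    def test_single_group_equals_overall(self, rng):
        y = rng.choice([1, -1], size=60)
        p = rng.choice([1, -1], size=60)
        if np.sum(y == 1) < 10:
            y[:10] = 1
        table = evaluate_by_group(y, p, ["fam"] * 60, min_positives=1)
        fam = table[table.group == "fam"].iloc[0]
        total = table[table.group == "Total"].iloc[0]
        assert fam.ACC == total.ACC and fam.MCC == total.MCC

    def test_group_counts_partition_total(self, rng):
        y = rng.choice([1, -1], size=80)
        p = rng.choice([1, -1], size=80)
        groups = rng.choice(["a", "b", "c"], size=80).tolist()
        table = evaluate_by_group(y, p, groups, min_positives=0)
        assert table[table.group != "Total"].n_cys.sum() == 80

    def test_filter_then_metrics_oracle(self, rng):
        y = rng.choice([1, -1], size=100)
        p = rng.choice([1, -1], size=100)
        groups = rng.choice(["a", "b"], size=100)
        table = evaluate_by_group(y, p, groups.tolist(), min_positives=0)
        for g in ("a", "b"):
            mask = groups == g
            expected = metrics(confusion(y[mask], p[mask]))
            row = table[table.group == g].iloc[0]
            assert row.ACC == pytest.approx(expected.ACC)
            assert row.MCC == pytest.approx(expected.MCC)

    def test_small_groups_suppressed(self):
        y = [1] * 12 + [-1] * 12
        p = y
        groups = ["big"] * 20 + ["tiny"] * 4
        table = evaluate_by_group(y, p, groups, min_positives=10)
        assert set(table.group) == {"big", "Total"}


class TestBalancedSampling:
    def _table(self, n_pos=5, n_neg=20):
        sites = [CysteineSite("p", i * 3 + 1, 1) for i in range(n_pos)]
        sites += [CysteineSite("q", i * 3 + 1, -1) for i in range(n_neg)]
        return SiteTable(sites)

    def test_balanced_output(self):
        out = sample_balanced_negatives(self._table(), seed=0)
        assert len(out.positives()) == 5 and len(out.negatives()) == 5

    def test_same_seed_same_sample(self):
        a = sample_balanced_negatives(self._table(), seed=3)
        b = sample_balanced_negatives(self._table(), seed=3)
        assert [(s.protein_id, s.position) for s in a] == [
            (s.protein_id, s.position) for s in b
        ]

    def test_sampled_negatives_are_subset(self, rng):
        table = self._table(n_pos=7, n_neg=30)
        original = {(s.protein_id, s.position) for s in table.negatives()}
        for seed in range(5):
            out = sample_balanced_negatives(table, seed=seed)
            assert {(s.protein_id, s.position) for s in out.negatives()} <= original

    def test_insufficient_negatives_rejected(self):
        with pytest.raises(ValueError, match="negatives"):
            sample_balanced_negatives(self._table(n_pos=5, n_neg=3), seed=0)
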