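"""Double cross-validation machinery: fold bookkeeping, screening, SFS
against exhaustive search, fold evaluation, summaries, comparator
selectors/classifiers, and cross-session transfer."""

import warnings

import numpy as np
import pytest

from netmark import (
    ClassifierSpec,
    adaboost_classify,
    correlate_scores,
    cross_session_eval,
    dprime,
    estimate_chance,
    evaluate_fold,
    make_cv_plan,
    misclassification_rate,
    run_double_cv,
    screen_single_features,
    select_independent,
    select_lda,
    sfs_select,
)
from netmark.classify import _cv_accuracy, _inner_folds


def gaussian_cohort(n, p, effect, n_informative=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.standard_normal((n, p))
    x[:, :n_informative] += effect * np.outer(y, np.ones(n_informative))
    return x, y


class TestPlan:
    def test_equal_fold_sizes_170_subjects(self):
        ids = [f"s{i}" for i in range(170)]
        labels = np.repeat([0, 1], 85)
        plan = make_cv_plan(ids, labels, n_outer=5, n_partitions=10, seed=1)
        for p in range(10):
            counts = np.bincount(plan.assignments[p], minlength=5)
            np.testing.assert_array_equal(counts, 34)

    def test_each_subject_tested_once_per_partition(self):
        ids = [f"s{i}" for i in range(30)]
        labels = np.tile([0, 1], 15)
        plan = make_cv_plan(ids, labels, n_partitions=10, seed=2)
        assert plan.assignments.shape == (10, 30)
        # a subject is in exactly one test fold per partition, so across
        # 10 partitions it is tested exactly 10 times
        for s in range(30):
            assert len(plan.assignments[:, s]) == 10

    def test_remainder_round_robin_and_determinism(self):
        ids = [f"s{i}" for i in range(13)]
        labels = np.tile([0, 1], 7)[:13]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = make_cv_plan(ids, labels, n_outer=5, n_partitions=2, seed=3)
            again = make_cv_plan(ids, labels, n_outer=5, n_partitions=2, seed=3)
        counts = sorted(np.bincount(plan.assignments[0], minlength=5))
        assert counts == [2, 2, 3, 3, 3]
        np.testing.assert_array_equal(plan.assignments, again.assignments)

    def test_single_class_fold_warns(self):
        ids = [f"s{i}" for i in range(10)]
        labels = np.array([0] * 9 + [1])
        with pytest.warns(UserWarning, match="single class"):
            make_cv_plan(ids, labels, n_outer=5, n_partitions=1, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_cv_plan(["a", "b"], np.array([0, 1]), n_outer=5)


class TestScreenAndSFS:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        self.spec = ClassifierSpec()

    def _folds(self, n):
        return _inner_folds(np.arange(n), 4, self.rng)

    def test_label_feature_kept_with_perfect_accuracy(self):
        n = 40
        y = np.tile([0, 1], n // 2)
        x = np.column_stack([2.0 * y - 1.0, self.rng.standard_normal(n)])
        accs, screened = screen_single_features(x, y, self._folds(n), self.spec)
        assert accs[0] == 1.0
        assert 0 in screened

    def test_random_features_rarely_retained(self):
        n, p = 48, 60
        y = np.tile([0, 1], n // 2)
        x = self.rng.standard_normal((n, p))
        _, screened = screen_single_features(x, y, self._folds(n), self.spec)
        # null features pass a >60% mean-validation screen only rarely
        assert len(screened) <= 0.15 * p

    def test_sfs_starts_with_perfect_feature(self):
        n = 24
        y = np.tile([0, 1], n // 2)
        x = np.column_stack([self.rng.standard_normal(n),
                             2.0 * y - 1.0,
                             self.rng.standard_normal(n)])
        folds = self._folds(n)
        accs, screened = screen_single_features(x, y, folds, self.spec)
        order, curve = sfs_select(x, y, screened, accs, folds, self.spec,
                                  max_features=2)
        assert order[0] == 1
        assert curve[0] == 1.0

    def test_sfs_step2_matches_exhaustive_pair_search(self):
        n, p = 32, 5
        x, y = gaussian_cohort(n, p, effect=0.8, n_informative=3, seed=9)
        folds = self._folds(n)
        accs = np.array([_cv_accuracy(x, y, [j], folds, self.spec)
                         for j in range(p)])
        order, _ = sfs_select(x, y, np.arange(p), accs, folds, self.spec,
                              max_features=2)
        first = int(np.argmax(accs))
        pair_accs = {j: _cv_accuracy(x, y, [first, j], folds, self.spec)
                     for j in range(p) if j != first}
        best_partner = min((j for j in pair_accs
                            if pair_accs[j] == max(pair_accs.values())))
        assert order == [first, best_partner]

    def test_sfs_stops_at_available_features(self):
        n = 24
        x, y = gaussian_cohort(n, 3, effect=1.0, seed=4)
        folds = self._folds(n)
        accs, _ = screen_single_features(x, y, folds, self.spec)
        order, curve = sfs_select(x, y, np.arange(3), accs, folds, self.spec,
                                  max_features=40)
        assert len(order) == 3 and len(set(order)) == 3
        assert all(0 <= a <= 1 for a in curve)


class TestEvaluation:
    def test_confusion_counts_on_toy(self):
        # 6 train + 6 test, feature = label + small noise: all correct
        rng = np.random.default_rng(0)
        y = np.array([0, 0, 0, 1, 1, 1] * 2)
        x = (2.0 * y - 1.0 + 0.1 * rng.standard_normal(12)).reshape(-1, 1)
        accs, preds = evaluate_fold(x, y, [0], np.arange(6), np.arange(6, 12),
                                    ClassifierSpec())
        assert accs == [1.0]
        np.testing.assert_array_equal(preds[0], y[6:])

    def test_overlapping_train_test_rejected(self):
        x = np.zeros((4, 1))
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="overlap"):
            evaluate_fold(x, y, [0], np.arange(3), np.arange(2, 4),
                          ClassifierSpec())

    def test_metrics_from_hand_counted_confusion(self):
        # 6-subject test fold with a known decision rule: threshold at 0
        # puts subjects {0.5, 1.5} -> patient, {-0.5, -1.5, -0.2, 0.2} mixed;
        # confusion counts must match hand tallies
        x_tr = np.array([-2.0, -1.0, -0.9, 0.9, 1.0, 2.0]).reshape(-1, 1)
        y_tr = np.array([0, 0, 0, 1, 1, 1])
        x_te = np.array([-1.5, -0.5, -0.2, 0.2, 0.5, 1.5]).reshape(-1, 1)
        y_te = np.array([0, 1, 0, 1, 0, 1])
        x = np.vstack([x_tr, x_te])
        y = np.concatenate([y_tr, y_te])
        accs, preds = evaluate_fold(x, y, [0], np.arange(6), np.arange(6, 12),
                                    ClassifierSpec())
        pred = preds[0]
        expected_pred = (x_te[:, 0] > 0).astype(int)
        np.testing.assert_array_equal(pred, expected_pred)
        # hand tally: predictions [0,0,0,1,1,1] vs truth [0,1,0,1,0,1]
        tp = np.sum((pred == 1) & (y_te == 1))
        tn = np.sum((pred == 0) & (y_te == 0))
        assert (tp, tn) == (2, 2)
        assert accs[0] == pytest.approx(4.0 / 6.0)


class TestDoubleCV:
    def test_trace_counts_and_mr_range(self):
        x, y = gaussian_cohort(30, 10, effect=1.2, seed=5)
        ids = [f"s{i}" for i in range(30)]
        plan = make_cv_plan(ids, y, n_outer=5, n_partitions=2, seed=5)
        res = run_double_cv(x, y, [f"f{j}" for j in range(10)], plan,
                            max_features=4)
        assert len(res.traces) == 10  # 2 partitions x 5 folds
        mr = misclassification_rate(res)
        assert set(mr) == set(ids)
        assert all(0 <= v <= 1 for v in mr.values())
        # strong effect: well above chance
        assert res.accuracy > 0.7

    def test_no_leakage_canary(self):
        # a feature matching the labels only on each fold's test subjects
        # must not be preferentially selected: selection sees only rows
        # where the canary is pure noise
        rng = np.random.default_rng(12)
        n, p = 40, 12
        x, y = gaussian_cohort(n, p, effect=0.6, seed=12)
        ids = [f"s{i}" for i in range(n)]
        selected_canary = 0
        total = 0
        for rep in range(3):
            plan = make_cv_plan(ids, y, n_outer=5, n_partitions=1, seed=rep)
            fold_of = plan.assignments[0]
            # build one canary per run: labels on the subjects of fold 0,
            # noise elsewhere (fold 0's test unit is the leakage target)
            canary = rng.standard_normal(n)
            mask = fold_of == 0
            canary[mask] = 4.0 * (2 * y[mask] - 1)
            xa = np.column_stack([x, canary])
            res = run_double_cv(xa, y, [f"f{j}" for j in range(p)] + ["canary"],
                                plan, max_features=4)
            trace = [t for t in res.traces if t.fold == 0][0]
            total += 1
            if "canary" in trace.sfs_order:
                selected_canary += 1
        assert selected_canary == 0

    def test_shuffled_labels_near_chance(self):
        x, y = gaussian_cohort(40, 20, effect=0.5, seed=3)
        accs = estimate_chance(x, y, [f"f{j}" for j in range(20)],
                               n_shuffles=4, n_partitions=1, max_features=4,
                               seed=3)
        assert 0.3 < np.mean(accs) < 0.7


class TestSummaries:
    def test_misclassification_rate_values(self):
        x, y = gaussian_cohort(20, 4, effect=2.0, seed=8)
        ids = [f"s{i}" for i in range(20)]
        plan = make_cv_plan(ids, y, n_outer=5, n_partitions=3, seed=8)
        res = run_double_cv(x, y, list("abcd"), plan, max_features=2)
        mr = misclassification_rate(res)
        for sid in ids:
            assert mr[sid] == res.misclassification_counts[sid] / 3

    def test_correlate_scores(self):
        mr = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        r, p = correlate_scores(mr, mr)
        assert r == pytest.approx(1.0)
        r, _ = correlate_scores(mr, -mr)
        assert r == pytest.approx(-1.0)
        other = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        r, _ = correlate_scores(mr, other)
        a, b = mr - mr.mean(), other - other.mean()
        assert r == pytest.approx(np.sum(a * b) /
                                  np.sqrt(np.sum(a ** 2) * np.sum(b ** 2)))
        with pytest.raises(ValueError, match="zero variance"):
            correlate_scores(mr, np.ones(5))

    def test_dprime_values(self):
        vals = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="pooled"):
            dprime(vals, labels)
        rng = np.random.default_rng(1)
        con = rng.normal(0, 1, 200)
        pat = rng.normal(1, 1, 200)
        d, p = dprime(np.concatenate([con, pat]),
                      np.array([0] * 200 + [1] * 200))
        assert d == pytest.approx(1.0, abs=0.15)
        assert p < 1e-6
        # equal means -> 0
        d, _ = dprime(np.concatenate([con, con]),
                      np.array([0] * 200 + [1] * 200))
        assert abs(d) < 0.01
        # hand-computed toy
        vals = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        expect = (6.0 - 2.0) / np.sqrt((1.0 + 1.0) / 2)
        d, _ = dprime(vals, labels)
        assert d == pytest.approx(expect)


class TestComparators:
    def test_independent_selection_ranking(self):
        accs = np.array([0.55, 0.80, 0.80, 0.95, 0.60])
        assert select_independent(accs, k=3) == [3, 1, 2]
        assert select_independent(accs, k=10) == [3, 1, 2, 4, 0]

    def test_lda_two_feature_closed_form(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.repeat([0, 1], n // 2)
        x = rng.standard_normal((n, 2))
        x[:, 0] += 2.0 * y  # informative; feature 1 is noise
        order = select_lda(x, y, k=2)
        assert order[0] == 0
        # closed form: w = Sw^-1 (m1 - m0)
        m0, m1 = x[y == 0].mean(0), x[y == 1].mean(0)
        sw = sum((x[y == c] - m).T @ (x[y == c] - m)
                 for c, m in ((0, m0), (1, m1)))
        w = np.linalg.solve(sw, m1 - m0)
        expected = sorted(range(2), key=lambda j: -abs(w[j]))
        assert order == expected

    def test_lda_singular_scatter_ok(self):
        # more features than subjects: pseudo-inverse must not fail
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 30))
        y = np.tile([0, 1], 5)
        order = select_lda(x, y, k=5)
        assert len(order) == 5

    def test_adaboost_separable_and_reference_agreement(self):
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.svm import SVC
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 3))
        y = (x[:, 0] + 0.8 * rng.standard_normal(40) > 0).astype(int)
        xt = rng.standard_normal((20, 3))
        mine = adaboost_classify(x, y, xt, n_weak=10)
        ref = AdaBoostClassifier(estimator=SVC(kernel="linear", C=1),
                                 n_estimators=10).fit(x, y).predict(xt)
        np.testing.assert_array_equal(mine, ref)
        # linearly separable toy: perfect training accuracy
        ysep = (x[:, 0] > 0).astype(int)
        pred = adaboost_classify(x, ysep, x, n_weak=10)
        assert np.mean(pred == ysep) == 1.0


class TestCrossSession:
    def test_identical_sessions_reproduce_training_accuracy(self):
        x, y = gaussian_cohort(24, 6, effect=1.5, seed=6)
        acc2, cols = cross_session_eval(x, y, x, y, seed=6)
        # session 2 identical to session 1: accuracy equals the training
        # accuracy of the frozen model
        from netmark.classify import _standardizer
        scale = _standardizer(x)
        clf = ClassifierSpec().make()
        clf.fit(scale(x)[:, cols], y)
        train_acc = np.mean(clf.predict(scale(x)[:, cols]) == y)
        assert acc2 == pytest.approx(train_acc)

    def test_shuffled_second_session_near_chance(self):
        x, y = gaussian_cohort(40, 8, effect=1.5, seed=2)
        rng = np.random.default_rng(2)
        accs = [cross_session_eval(x, y, x, rng.permutation(y), seed=s)[0]
                for s in range(5)]
        assert 0.3 < np.mean(accs) < 0.7

    def test_state_variability_lowers_transfer(self):
        # session-2 features = attenuated session-1 signal + state noise;
        # more state noise, lower transfer accuracy (averaged over draws)
        def transfer(noise_sd, seed):
            rng = np.random.default_rng(seed)
            x1, y = gaussian_cohort(40, 8, effect=1.2, seed=seed)
            x2 = x1 + noise_sd * rng.standard_normal(x1.shape)
            return cross_session_eval(x1, y, x2, y, seed=seed)[0]

        low = np.mean([transfer(0.2, s) for s in range(6)])
        high = np.mean([transfer(3.0, s) for s in range(6)])
        assert high < low

    def test_mismatched_sessions_rejected(self):
        x, y = gaussian_cohort(10, 3, effect=1.0, seed=1)
        with pytest.raises(ValueError, match="same subjects"):
            cross_session_eval(x, y, x[:5], y[:5])
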