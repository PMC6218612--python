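"""Double cross-validated feature selection and classification.

The subject set is split into 5 outer folds (each serving once as the test
set), repeated over N_perm random partitions. Within each outer fold the
remaining subjects are rotated through a 4-fold train/validation scheme
used for feature selection: a single-feature screen keeps features whose
mean validation accuracy exceeds 60%, then sequential forward selection
(SFS) greedily grows a feature set up to 40 features by mean validation
accuracy. The selected set is finally trained on all non-test subjects and
evaluated on the held-out test fold, giving the double cross-validation
(generalization) estimate; the inner validation accuracies give the
single cross-validation (optimistic) curve.

No test-fold subject ever influences screening, selection, training, or
the feature standardization statistics for that fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "CVPlan",
    "SelectionTrace",
    "RunResults",
    "make_cv_plan",
    "screen_single_features",
    "sfs_select",
    "evaluate_fold",
    "run_double_cv",
    "estimate_chance",
    "misclassification_rate",
    "correlate_scores",
    "dprime",
    "select_independent",
    "select_lda",
    "adaboost_classify",
    "cross_session_eval",
]

SCREEN_THRESHOLD = 0.60
MAX_SFS_FEATURES = 40


@dataclass
class ClassifierSpec:
    """Support-vector classifier configuration (default: linear, C = 1)."""

    kernel: str = "linear"
    box_constraint: float = 1.0
    rbf_sigma: float = 1.0
    poly_degree: int = 3

    def make(self) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.box_constraint)
        if self.kernel == "rbf":
            gamma = 1.0 / (2.0 * self.rbf_sigma ** 2)
            return SVC(kernel="rbf", C=self.box_constraint, gamma=gamma)
        if self.kernel == "quadratic":
            return SVC(kernel="poly", degree=2, C=self.box_constraint,
                       gamma="scale", coef0=1.0)
        if self.kernel == "polynomial":
            return SVC(kernel="poly", degree=self.poly_degree,
                       C=self.box_constraint, gamma="scale", coef0=1.0)
        raise ValueError(f"unknown kernel '{self.kernel}'")


@dataclass
class CVPlan:
    """Nested fold structure over subjects.

    ``assignments[p, s]`` is the outer test fold of subject s in partition
    p; every subject appears in exactly one test fold per partition.
    """

    subject_ids: list[str]
    labels: np.ndarray  # 1 = patient (positive), 0 = control
    n_outer_folds: int
    n_inner_shuffles: int
    n_partitions: int
    seed: int
    assignments: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class SelectionTrace:
    """One (partition, outer fold) unit of the double CV."""

    partition: int
    fold: int
    screened_features: list[str]
    sfs_order: list[str]
    inner_accuracy_by_step: list[float]
    test_accuracy_by_step: list[float]
    best_step: int  # 1-based prefix length maximizing inner accuracy
    tp: int
    tn: int
    fp: int
    fn: int
    test_subjects: list[str] = field(default_factory=list)
    test_correct: list[bool] = field(default_factory=list)


@dataclass
class RunResults:
    """Aggregated double-CV output across all partitions and folds."""

    traces: list[SelectionTrace]
    plan: CVPlan
    misclassification_counts: dict[str, int]
    accuracy: float
    sensitivity: float
    specificity: float
    single_cv_curve: np.ndarray  # mean inner-validation accuracy per step
    double_cv_curve: np.ndarray  # mean test accuracy per step
    mean_screened_count: float
    chance_accuracies: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fold construction


def make_cv_plan(subject_ids: list[str], labels: np.ndarray, n_outer: int = 5,
                 n_inner: int = 4, n_partitions: int = 10,
                 seed: int = 0) -> CVPlan:
    """Random equal-size outer folds, repeated over partitions.

    Remainder subjects (when n is not divisible by n_outer) are spread
    round-robin over the first folds. A warning is raised if any test fold
    lacks one of the classes (degenerate metrics downstream).
    """
    labels = np.asarray(labels, dtype=int)
    n = len(subject_ids)
    if n_outer < 2:
        raise ValueError("n_outer must be >= 2")
    if n < n_outer:
        raise ValueError(f"{n} subjects cannot fill {n_outer} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 17]))
    assignments = np.empty((n_partitions, n), dtype=int)
    sizes = np.full(n_outer, n // n_outer)
    sizes[: n % n_outer] += 1
    for p in range(n_partitions):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        start = 0
        for f, sz in enumerate(sizes):
            fold_of[perm[start:start + sz]] = f
            start += sz
        assignments[p] = fold_of
        for f in range(n_outer):
            fold_labels = labels[fold_of == f]
            if len(np.unique(fold_labels)) < 2:
                warnings.warn(
                    f"partition {p} fold {f} contains a single class; "
                    "sensitivity/specificity will be undefined there",
                    stacklevel=2)
    return CVPlan(list(subject_ids), labels, n_outer, n_inner, n_partitions,
                  seed, assignments)


def _inner_folds(indices: np.ndarray, n_inner: int,
                 rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotation scheme: one shuffle, then each of n_inner contiguous chunks
    serves once as the validation set."""
    perm = rng.permutation(indices)
    chunks = np.array_split(perm, n_inner)
    folds = []
    for v in range(n_inner):
        val = chunks[v]
        train = np.concatenate([chunks[u] for u in range(n_inner) if u != v])
        folds.append((train, val))
    return folds


def _standardizer(x_train: np.ndarray):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return lambda x: (x - mu) / sd


def _cv_accuracy(x: np.ndarray, y: np.ndarray, cols: list[int],
                 folds, spec: ClassifierSpec) -> float:
    """Mean validation accuracy over the inner folds for a feature subset."""
    accs = []
    for train, val in folds:
        xt = x[np.ix_(train, cols)]
        xv = x[np.ix_(val, cols)]
        clf = spec.make()
        clf.fit(xt, y[train])
        accs.append(float(np.mean(clf.predict(xv) == y[val])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# screening and sequential forward selection


def screen_single_features(x: np.ndarray, y: np.ndarray, folds,
                           spec: ClassifierSpec,
                           threshold: float = SCREEN_THRESHOLD
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Mean single-feature validation accuracy for every feature; the
    screen keeps accuracies strictly above the threshold."""
    n_feat = x.shape[1]
    accs = np.empty(n_feat)
    for j in range(n_feat):
        accs[j] = _cv_accuracy(x, y, [j], folds, spec)
    return accs, np.nonzero(accs > threshold)[0]


def sfs_select(x: np.ndarray, y: np.ndarray, candidates: np.ndarray,
               screen_accs: np.ndarray, folds, spec: ClassifierSpec,
               max_features: int = MAX_SFS_FEATURES
               ) -> tuple[list[int], list[float]]:
    """Greedy forward selection among screened candidates.

    Step 1 reuses the screen accuracies (identical definition, same folds);
    each later step adds the candidate maximizing mean validation accuracy
    of the combined set. Ties resolve to the earliest candidate in catalog
    order. Returns (selected column indices, accuracy by step).
    """
    if len(candidates) == 0:
        raise ValueError("no screened features to select from")
    candidates = list(candidates)
    best0 = candidates[int(np.argmax(screen_accs[candidates]))]
    selected = [best0]
    curve = [float(screen_accs[best0])]
    remaining = [c for c in candidates if c != best0]
    while remaining and len(selected) < max_features:
        step_accs = np.array([
            _cv_accuracy(x, y, selected + [c], folds, spec) for c in remaining])
        pick = int(np.argmax(step_accs))  # first max = catalog order
        selected.append(remaining.pop(pick))
        curve.append(float(step_accs[pick]))
    return selected, curve


def evaluate_fold(x: np.ndarray, y: np.ndarray, selected: list[int],
                  train_idx: np.ndarray, test_idx: np.ndarray,
                  spec: ClassifierSpec):
    """Train on the non-test subjects and score every SFS prefix on the
    test fold. Returns (accuracy by step, predictions by step)."""
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test subject sets overlap")
    accs, preds = [], []
    for step in range(1, len(selected) + 1):
        cols = selected[:step]
        clf = spec.make()
        clf.fit(x[np.ix_(train_idx, cols)], y[train_idx])
        p = clf.predict(x[np.ix_(test_idx, cols)])
        preds.append(p)
        accs.append(float(np.mean(p == y[test_idx])))
    return accs, preds


# ---------------------------------------------------------------------------
# the double loop


def run_double_cv(x: np.ndarray, y: np.ndarray, feature_ids: list[str],
                  plan: CVPlan, spec: ClassifierSpec | None = None,
                  screen_threshold: float = SCREEN_THRESHOLD,
                  max_features: int = MAX_SFS_FEATURES) -> RunResults:
    """Full screen -> SFS -> test evaluation over every (partition, fold).

    Feature standardization uses non-test-subject statistics only. If the
    screen retains nothing (common under shuffled labels), the single best
    feature by screen accuracy is used so every fold still predicts.
    The per-fold prediction used for misclassification counting comes from
    the prefix maximizing mean inner-validation accuracy (earliest on ties).
    """
    spec = spec or ClassifierSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    traces: list[SelectionTrace] = []
    mis = {s: 0 for s in plan.subject_ids}
    screened_counts = []
    for p in range(plan.n_partitions):
        for f in range(plan.n_outer_folds):
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed & 0x7FFFFFFF, 101, p, f]))
            test_idx = np.nonzero(plan.assignments[p] == f)[0]
            dev_idx = np.nonzero(plan.assignments[p] != f)[0]
            scale = _standardizer(x[dev_idx])
            xs = scale(x)
            folds = _inner_folds(dev_idx, plan.n_inner_shuffles, rng)
            accs, screened = screen_single_features(xs, y, folds, spec,
                                                    screen_threshold)
            screened_counts.append(len(screened))
            candidates = screened if len(screened) else \
                np.array([int(np.argmax(accs))])
            selected, inner_curve = sfs_select(xs, y, candidates, accs, folds,
                                               spec, max_features)
            test_curve, preds = evaluate_fold(xs, y, selected, dev_idx,
                                              test_idx, spec)
            best_step = int(np.argmax(inner_curve)) + 1
            p_best = preds[best_step - 1]
            correct = p_best == y[test_idx]
            tp = int(np.sum((p_best == 1) & (y[test_idx] == 1)))
            tn = int(np.sum((p_best == 0) & (y[test_idx] == 0)))
            fp = int(np.sum((p_best == 1) & (y[test_idx] == 0)))
            fn = int(np.sum((p_best == 0) & (y[test_idx] == 1)))
            for t, ok in zip(test_idx, correct):
                if not ok:
                    mis[plan.subject_ids[t]] += 1
            traces.append(SelectionTrace(
                partition=p, fold=f,
                screened_features=[feature_ids[j] for j in screened],
                sfs_order=[feature_ids[j] for j in selected],
                inner_accuracy_by_step=inner_curve,
                test_accuracy_by_step=test_curve,
                best_step=best_step, tp=tp, tn=tn, fp=fp, fn=fn,
                test_subjects=[plan.subject_ids[t] for t in test_idx],
                test_correct=correct.tolist()))
    max_steps = max(len(t.inner_accuracy_by_step) for t in traces)

    def _curve(key):
        m = np.full((len(traces), max_steps), np.nan)
        for i, t in enumerate(traces):
            vals = getattr(t, key)
            m[i, : len(vals)] = vals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(m, axis=0)

    tp = sum(t.tp for t in traces)
    tn = sum(t.tn for t in traces)
    fp = sum(t.fp for t in traces)
    fn = sum(t.fn for t in traces)
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec_ = tn / (tn + fp) if tn + fp else np.nan
    return RunResults(traces, plan, mis, acc, sens, spec_,
                      _curve("inner_accuracy_by_step"),
                      _curve("test_accuracy_by_step"),
                      float(np.mean(screened_counts)))


def estimate_chance(x: np.ndarray, y: np.ndarray, feature_ids: list[str],
                    spec: ClassifierSpec | None = None, n_shuffles: int = 10,
                    n_outer: int = 5, n_inner: int = 4, n_partitions: int = 1,
                    screen_threshold: float = SCREEN_THRESHOLD,
                    max_features: int = MAX_SFS_FEATURES,
                    seed: int = 0) -> list[float]:
    """Chance-level accuracy: the full double-CV process repeated with
    randomly shuffled labels."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 202]))
    out = []
    subject_ids = [f"s{i}" for i in range(len(y))]
    for r in range(n_shuffles):
        y_sh = rng.permutation(np.asarray(y, dtype=int))
        plan = make_cv_plan(subject_ids, y_sh, n_outer, n_inner, n_partitions,
                            seed=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_double_cv(x, y_sh, feature_ids, plan, spec,
                                screen_threshold, max_features)
        out.append(res.accuracy)
    return out


# ---------------------------------------------------------------------------
# summaries, effect sizes, comparators


def misclassification_rate(results: RunResults) -> dict[str, float]:
    """Per-subject MR = misclassifications / N_perm (each subject is tested
    once per partition)."""
    n_perm = results.plan.n_partitions
    return {s: m / n_perm for s, m in results.misclassification_counts.items()}


def correlate_scores(mr: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between misclassification
    rate and a symptom score."""
    mr = np.asarray(mr, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if mr.size < 3 or mr.size != scores.size:
        raise ValueError("need >= 3 paired values")
    if mr.std() == 0 or scores.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(mr, scores)
    return float(r), float(p)


def dprime(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Effect size d' = (mean_patient - mean_control) / rms within-group sd,
    with the two-sample t-test p-value."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pat, con = values[labels == 1], values[labels == 0]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("both groups need >= 2 subjects")
    pooled = np.sqrt((pat.var(ddof=1) + con.var(ddof=1)) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    d = (pat.mean() - con.mean()) / pooled
    _, p = stats.ttest_ind(pat, con)
    return float(d), float(p)


def select_independent(screen_accs: np.ndarray, k: int = 40) -> list[int]:
    """Top-k features by single-feature validation accuracy (ties by
    catalog order)."""
    order = sorted(range(len(screen_accs)), key=lambda j: (-screen_accs[j], j))
    return order[: min(k, len(order))]


def select_lda(x: np.ndarray, y: np.ndarray, k: int = 40) -> list[int]:
    """Top-k features by absolute weight in the Fisher discriminant
    direction, computed with the Moore-Penrose pseudo-inverse of the
    within-class scatter (defined even when the scatter is singular)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("LDA selection needs two classes")
    m0 = x[y == 0].mean(axis=0)
    m1 = x[y == 1].mean(axis=0)
    sw = np.zeros((x.shape[1], x.shape[1]))
    for c, mc in ((0, m0), (1, m1)):
        xc = x[y == c] - mc
        sw += xc.T @ xc
    w = np.linalg.pinv(sw) @ (m1 - m0)
    order = sorted(range(len(w)), key=lambda j: (-abs(w[j]), j))
    return order[: min(k, len(order))]


def adaboost_classify(x_train: np.ndarray, y_train: np.ndarray,
                      x_test: np.ndarray, spec: ClassifierSpec | None = None,
                      n_weak: int = 10) -> np.ndarray:
    """Adaboost over linear-SVM weak learners (discrete boosting with
    weighted-vote prediction). Degenerate rounds (error 0 or >= 1/2) end
    the boosting with a logged notice."""
    spec = spec or ClassifierSpec()
    x_train = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    n = len(y)
    w = np.full(n, 1.0 / n)
    learners: list[tuple[float, SVC]] = []
    for t in range(n_weak):
        clf = spec.make()
        clf.fit(x_train, y, sample_weight=w)
        pred = clf.predict(x_train)
        err = float(np.sum(w[pred != y]))
        if err <= 0:
            learners.append((1.0, clf))
            logger.info("adaboost round %d: perfect weak learner, stopping", t)
            break
        if err >= 0.5:
            logger.warning("adaboost round %d: weak learner no better than "
                           "chance (err=%.3f), stopping", t, err)
            break
        alpha = 0.5 * np.log((1 - err) / err)
        learners.append((alpha, clf))
        w *= np.exp(alpha * np.where(pred != y, 1.0, -1.0))
        w /= w.sum()
    if not learners:
        clf = spec.make()
        clf.fit(x_train, y)
        learners = [(1.0, clf)]
    votes = np.zeros(len(x_test))
    for alpha, clf in learners:
        votes += alpha * (2 * clf.predict(np.asarray(x_test, dtype=float)) - 1)
    return (votes > 0).astype(int)


def cross_session_eval(x1: np.ndarray, y1: np.ndarray, x2: np.ndarray,
                       y2: np.ndarray, spec: ClassifierSpec | None = None,
                       n_inner: int = 4,
                       screen_threshold: float = SCREEN_THRESHOLD,
                       max_features: int = MAX_SFS_FEATURES,
                       seed: int = 0) -> tuple[float, list[int]]:
    """Select features and train on session 1 only; apply the frozen model
    and feature set to session 2. Returns (session-2 accuracy, columns)."""
    spec = spec or ClassifierSpec()
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y1 = np.asarray(y1, dtype=int)
    if x1.shape != x2.shape:
        raise ValueError("sessions must contain the same subjects and features")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 303]))
    scale = _standardizer(x1)
    xs1, xs2 = scale(x1), scale(x2)
    folds = _inner_folds(np.arange(len(y1)), n_inner, rng)
    accs, screened = screen_single_features(xs1, y1, folds, spec,
                                            screen_threshold)
    candidates = screened if len(screened) else np.array([int(np.argmax(accs))])
    selected, curve = sfs_select(xs1, y1, candidates, accs, folds, spec,
                                 max_features)
    best_step = int(np.argmax(curve)) + 1
    cols = selected[:best_step]
    clf = spec.make()
    clf.fit(xs1[:, cols], y1)
    acc = float(np.mean(clf.predict(xs2[:, cols]) == np.asarray(y2, dtype=int)))
    return acc, cols
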