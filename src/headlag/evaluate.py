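"""Cross-validated evaluation of the fuzzy head-lag classifier.

The protocol is repeated stratified cross-validation (default 30 repeats
of 5 folds) over labeled canonical sequences. Because the pull-to-sit
levels are ordinal, headline metrics are computed on two binarizations:

* ``level0_vs_rest`` — level 0 (positive) against levels {1, 3}: can the
  model discriminate absent head control from any head control?
* ``level3_vs_rest`` — level 3 (positive) against levels {0, 1}: can it
  single out full head control?

From each pooled 2×2 confusion matrix we report accuracy, sensitivity
(TP / (TP + FN)), specificity (TN / (FP + TN)), per-class recall under
both positive-class orientations, their average, and Cohen's kappa. The
two keypoint subsets (thirteen vs five) are compared with a classical
paired two-tailed t-test on per-run accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HeadlagError
from .fuzzy import classify_batch, fit_level_model
from .skeleton import PTS_LEVELS, CanonicalSequence

#: The two ordinal binarization tasks: task -> (positive levels, name of positive class).
BINARIZATION_TASKS: dict[str, tuple[frozenset[int], str]] = {
    "level0_vs_rest": (frozenset({0}), "level 0"),
    "level3_vs_rest": (frozenset({3}), "level 3"),
}


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Pooled binary counts; ``positive_class`` documents the orientation."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise HeadlagError(f"confusion count {name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix2x2":
        """The same table with the positive/negative orientation flipped."""
        return ConfusionMatrix2x2(
            tp=self.tn,
            fn=self.fp,
            fp=self.fn,
            tn=self.tp,
            positive_class=f"not {self.positive_class}",
        )


def binarize(
    true: Sequence[int], predicted: Sequence[int], task: str
) -> ConfusionMatrix2x2:
    """Collapse ordinal (true, predicted) pairs into a binary confusion matrix."""
    positive, pos_name = _task(task)
    t = np.isin(np.asarray(true), list(positive))
    p = np.isin(np.asarray(predicted), list(positive))
    return ConfusionMatrix2x2(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        positive_class=pos_name,
    )


def _task(task: str) -> tuple[frozenset[int], str]:
    try:
        return BINARIZATION_TASKS[task]
    except KeyError:
        raise HeadlagError(
            f"unknown binarization task {task!r}: expected one of "
            f"{sorted(BINARIZATION_TASKS)}"
        ) from None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def accuracy(cm: ConfusionMatrix2x2) -> float:
    """(TP + TN) / total, as a percentage."""
    if cm.total == 0:
        raise HeadlagError("accuracy undefined for an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def sensitivity_specificity(cm: ConfusionMatrix2x2) -> tuple[float, float]:
    """(sensitivity, specificity) as percentages.

    sensitivity = TP / (TP + FN); specificity = TN / (FP + TN).
    """
    if cm.tp + cm.fn == 0:
        raise HeadlagError("sensitivity undefined: TP + FN = 0")
    if cm.fp + cm.tn == 0:
        raise HeadlagError("specificity undefined: FP + TN = 0")
    return (
        100.0 * cm.tp / (cm.tp + cm.fn),
        100.0 * cm.tn / (cm.fp + cm.tn),
    )


def per_class_recall(cm: ConfusionMatrix2x2) -> dict[str, float]:
    """Recall of each binarized class as percentages.

    Identical numbers to :func:`sensitivity_specificity` but keyed by
    class name, so results are unambiguous regardless of which class a
    report treats as positive.
    """
    sens, spec = sensitivity_specificity(cm)
    return {cm.positive_class: sens, f"not {cm.positive_class}": spec}


def average_sensitivity_specificity(cm: ConfusionMatrix2x2) -> float:
    """Arithmetic mean of the two per-class recalls (balanced accuracy), %."""
    sens, spec = sensitivity_specificity(cm)
    return (sens + spec) / 2.0


def cohen_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    p_o is observed agreement; p_e the agreement expected from the row and
    column marginals. If all mass sits in one cell (p_e = 1), κ is
    reported as 0 with a warning.
    """
    n = cm.total
    if n == 0:
        raise HeadlagError("kappa undefined for an empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    true_pos, true_neg = cm.tp + cm.fn, cm.fp + cm.tn
    pred_pos, pred_neg = cm.tp + cm.fp, cm.fn + cm.tn
    p_e = (true_pos * pred_pos + true_neg * pred_neg) / (n * n)
    if p_e >= 1.0:
        warnings.warn("kappa degenerate: all mass in one cell; reporting 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for repeated stratified cross-validation.

    ``assignments`` has shape (repeats, n): the fold id of each instance
    in each repeat. Within each repeat the folds partition the dataset and
    per-fold label counts are within ±1 of exact proportionality.
    """

    folds: int
    repeats: int
    seed: int
    assignments: np.ndarray

    @property
    def n(self) -> int:
        return self.assignments.shape[1]


def make_cv_plan(
    labels: Sequence[int], folds: int = 5, repeats: int = 30, seed: int = 0
) -> CVPlan:
    """Build a deterministic repeated stratified fold plan.

    Repeat ``r`` draws from an independent stream derived from
    ``(seed, r)``, so plans are reproducible and repeats independent.
    Every label must have at least ``folds`` instances.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if folds < 2:
        raise HeadlagError("need at least 2 folds")
    uniq, counts = np.unique(labels, return_counts=True)
    for lvl, cnt in zip(uniq, counts):
        if cnt < folds:
            raise HeadlagError(
                f"label {lvl} has only {cnt} instances; need >= {folds} for "
                f"{folds}-fold stratification"
            )
    assignments = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        fold_of = np.empty(n, dtype=int)
        offset = 0  # rotate fold order between labels to balance remainders
        for lvl in uniq:
            idx = np.flatnonzero(labels == lvl)
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                fold_of[i] = (pos + offset) % folds
            offset += len(idx) % folds
        assignments[r] = fold_of
    return CVPlan(folds=folds, repeats=repeats, seed=int(seed), assignments=assignments)


@dataclass(frozen=True)
class CVRecords:
    """Flat per-test-instance results of :func:`run_cv` (aligned arrays)."""

    repeat: np.ndarray
    fold: np.ndarray
    index: np.ndarray
    true: np.ndarray
    predicted: np.ndarray

    def __len__(self) -> int:
        return len(self.repeat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": self.repeat,
                "fold": self.fold,
                "index": self.index,
                "true": self.true,
                "predicted": self.predicted,
            }
        )


def run_cv(dataset: Iterable[CanonicalSequence], plan: CVPlan) -> CVRecords:
    """Execute the cross-validation: fit per-level models, classify test folds.

    For every repeat and fold, the three level models are fitted on the
    training folds and the held-out fold is classified, so each instance
    is tested exactly once per repeat. A training fold missing a level
    entirely is an error (that level's model cannot be fitted).
    """
    seqs = list(dataset)
    if len(seqs) != plan.n:
        raise HeadlagError(
            f"dataset size {len(seqs)} does not match plan size {plan.n}"
        )
    labels = np.array([_require_label(s) for s in seqs])
    coords = np.stack([s.coords for s in seqs])

    rec_repeat, rec_fold, rec_index, rec_true, rec_pred = [], [], [], [], []
    for r in range(plan.repeats):
        fold_of = plan.assignments[r]
        for f in range(plan.folds):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            models = {}
            for lvl in PTS_LEVELS:
                members = train[labels[train] == lvl]
                if len(members) == 0:
                    raise HeadlagError(
                        f"repeat {r} fold {f}: no level-{lvl} training "
                        "instances; cannot fit that level's model"
                    )
                models[lvl] = fit_level_model(
                    [seqs[i] for i in members], level=lvl
                )
            predicted, _ = classify_batch(coords[test], models)
            rec_repeat.append(np.full(len(test), r))
            rec_fold.append(np.full(len(test), f))
            rec_index.append(test)
            rec_true.append(labels[test])
            rec_pred.append(predicted)
    return CVRecords(
        repeat=np.concatenate(rec_repeat),
        fold=np.concatenate(rec_fold),
        index=np.concatenate(rec_index),
        true=np.concatenate(rec_true),
        predicted=np.concatenate(rec_pred),
    )


def _require_label(seq: CanonicalSequence) -> int:
    if seq.label is None:
        raise HeadlagError(f"sequence {seq.sequence_id!r} has no label")
    return seq.label


# ---------------------------------------------------------------------------
# summaries and the paired t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSummary:
    """Pooled and per-run metrics of one binarization task."""

    task: str
    pooled: ConfusionMatrix2x2
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    recalls: dict[str, float]
    average_recall: float
    per_repeat_accuracy: np.ndarray
    per_fold_accuracy: np.ndarray
    accuracy_mean: float
    accuracy_sd: float  # over repeats (ddof=1); 0 flagged for single repeat
    accuracy_sd_folds: float


@dataclass(frozen=True)
class EvaluationSummary:
    tasks: dict[str, TaskSummary]
    n_results: int

    def accuracy_table(self) -> pd.DataFrame:
        """Flat (task, repeat, accuracy) table for external plotting."""
        rows = []
        for name, summary in self.tasks.items():
            for r, acc in enumerate(summary.per_repeat_accuracy):
                rows.append({"task": name, "repeat": r, "accuracy": acc})
        return pd.DataFrame(rows)


def summarize(records: CVRecords) -> EvaluationSummary:
    """Pool CV records into per-task metrics.

    Pooled confusion matrices aggregate all repeats; per-repeat and
    per-fold accuracies support both flavors of spread (their standard
    deviations differ — both are reported).
    """
    tasks: dict[str, TaskSummary] = {}
    repeats = np.unique(records.repeat)
    for task in BINARIZATION_TASKS:
        pooled = binarize(records.true, records.predicted, task)
        per_repeat = np.array(
            [
                accuracy(binarize(records.true[records.repeat == r],
                                  records.predicted[records.repeat == r], task))
                for r in repeats
            ]
        )
        per_fold = []
        for r in repeats:
            in_r = records.repeat == r
            for f in np.unique(records.fold[in_r]):
                sel = in_r & (records.fold == f)
                per_fold.append(
                    accuracy(binarize(records.true[sel], records.predicted[sel], task))
                )
        per_fold = np.asarray(per_fold)
        sens, spec = sensitivity_specificity(pooled)
        tasks[task] = TaskSummary(
            task=task,
            pooled=pooled,
            accuracy=accuracy(pooled),
            kappa=cohen_kappa(pooled),
            sensitivity=sens,
            specificity=spec,
            recalls=per_class_recall(pooled),
            average_recall=average_sensitivity_specificity(pooled),
            per_repeat_accuracy=per_repeat,
            per_fold_accuracy=per_fold,
            accuracy_mean=float(per_repeat.mean()),
            accuracy_sd=float(per_repeat.std(ddof=1)) if len(per_repeat) > 1 else 0.0,
            accuracy_sd_folds=float(per_fold.std(ddof=1)) if len(per_fold) > 1 else 0.0,
        )
    return EvaluationSummary(tasks=tasks, n_results=len(records))


@dataclass(frozen=True)
class PairedTTestResult:
    """Classical paired two-tailed t-test on per-run accuracy deviations."""

    d: np.ndarray
    mu_d: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def paired_t_test(
    acc_a: Sequence[float], acc_b: Sequence[float]
) -> PairedTTestResult:
    """Paired two-tailed t-test on d_j = a_j − b_j.

    Zero-variance deviations are handled explicitly: all-zero d gives
    t = 0, p = 1 (with a warning); constant nonzero d gives the limiting
    p = 0 (with a warning).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise HeadlagError("paired t-test needs two equal-length runs (>= 2)")
    d = a - b
    n = len(d)
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mu == 0.0:
            warnings.warn("paired t-test: all deviations zero; t=0, p=1")
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn(
                "paired t-test: zero-variance nonzero deviations; limiting p=0"
            )
            t_stat, p = float(np.sign(mu)) * np.inf, 0.0
    else:
        t_stat = mu / (sd / np.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), n - 1))
    return PairedTTestResult(
        d=d, mu_d=mu, t_statistic=float(t_stat), degrees_of_freedom=n - 1, p_value=p
    )
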