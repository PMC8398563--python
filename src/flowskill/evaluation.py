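"""Leave-one-super-trial-out evaluation protocol and result accounting.

A "super-trial" is the i-th repetition of the task across all subjects.
Fold i trains on every other repetition and tests on repetition i, so every
subject appears on both sides of every fold and the classifier must
generalise across attempts, not across people.  The full protocol repeats
the cross-validation ``n_runs`` times with different training seeds and
summarises accuracies as Mean (average of per-run means), Standard
Deviation (over the run means), Best run and Best trial, in percent.

Expert recall — expert true positives over the number of expert samples in
the test fold — guards against the failure mode where a method scores well
by recognising only the majority (novice) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion

from .windows import WindowedDataset


@dataclass(frozen=True)
class FoldPlan:
    """LOSO partition: fold i holds out trial index i for every subject."""

    n_super_trials: int
    folds: tuple[tuple[int, tuple[int, ...]], ...]  # (test trial, train trials)


def loso_split(dataset: WindowedDataset) -> FoldPlan:
    """Build the leave-one-super-trial-out fold plan for a windowed dataset.

    Requires every subject to have samples from the same set of trial
    indices; ragged cohorts must be padded or dropped by the caller.
    """
    trials_by_subject = {
        s: tuple(sorted(np.unique(dataset.trial[dataset.subject == s])))
        for s in np.unique(dataset.subject)
    }
    trial_sets = set(trials_by_subject.values())
    if len(trial_sets) != 1:
        raise ValueError(f"ragged trial counts per subject: {trials_by_subject}")
    trials = trial_sets.pop()
    folds = tuple(
        (t, tuple(tr for tr in trials if tr != t)) for t in trials
    )
    return FoldPlan(n_super_trials=len(trials), folds=folds)


@dataclass
class ConfusionCounts:
    """Per-class confusion bookkeeping for one (run, fold) evaluation."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # rows = true class, cols = predicted class
    run: int = 0
    fold: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes, run: int = 0,
                         fold: int = 0) -> "ConfusionCounts":
        m = _sk_confusion(y_true, y_pred, labels=list(classes))
        return cls(classes=tuple(classes), matrix=m, run=run, fold=fold)

    def _idx(self, cls_name: str) -> int:
        return self.classes.index(cls_name)

    def true_positives(self, cls_name: str) -> int:
        i = self._idx(cls_name)
        return int(self.matrix[i, i])

    def false_positives(self, cls_name: str) -> int:
        i = self._idx(cls_name)
        return int(self.matrix[:, i].sum() - self.matrix[i, i])

    def n_true(self, cls_name: str) -> int:
        return int(self.matrix[self._idx(cls_name)].sum())

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix)) / self.total


def expert_recall(cm: ConfusionCounts) -> float | None:
    """ExpertTruePositive / NumOfExpertsInTrial, in [0, 1].

    Returns None (missing, not zero) when the test fold contains no expert
    samples.
    """
    if "expert" not in cm.classes:
        return None
    n_experts = cm.n_true("expert")
    if n_experts == 0:
        return None
    return cm.true_positives("expert") / n_experts


def zero_tp_census(matrices: list[ConfusionCounts]) -> dict[str, dict[str, int]]:
    """Count matrices with zero true / false positives per class.

    Mirrors the reliability analysis of per-fold confusion matrices: a high
    zero-true-positive count for experts flags a method that never finds an
    expert even when its raw accuracy looks acceptable.
    """
    if not matrices:
        raise ValueError("no confusion matrices given")
    classes = matrices[0].classes
    census = {c: {"zero_tp": 0, "zero_fp": 0} for c in classes}
    for m in matrices:
        for c in classes:
            if m.true_positives(c) == 0:
                census[c]["zero_tp"] += 1
            if m.false_positives(c) == 0:
                census[c]["zero_fp"] += 1
    return census


@dataclass
class ProtocolResult:
    """All accuracies and confusion matrices from n_runs × n_folds."""

    method: str
    head: str
    window_tag: str
    accuracies: np.ndarray  # (n_runs, n_folds), fractions in [0, 1]
    matrices: list[ConfusionCounts] = field(default_factory=list)

    @property
    def run_means(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    def summary(self) -> dict[str, float]:
        """Mean / SD / Best run / Best trial, in percent."""
        rm = self.run_means
        return {
            "Parameters": self.window_tag,
            "Evaluation": "Model" if self.head == "model" else "SVM",
            "Mean": 100.0 * float(rm.mean()),
            "StandardDeviation": 100.0 * float(rm.std(ddof=0)),
            "BestRun": 100.0 * float(rm.max()),
            "BestTrial": 100.0 * float(self.accuracies.max()),
        }

    def result_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary()])

    def mean_expert_recall(self) -> float | None:
        vals = [expert_recall(m) for m in self.matrices]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None


def run_protocol(
    dataset: WindowedDataset,
    estimator,
    head: str = "model",
    n_runs: int = 5,
    base_seed: int = 0,
    normalize: bool = True,
    window_tag: str = "",
) -> ProtocolResult:
    """n_runs repetitions of LOSO cross-validation with per-fold retraining.

    Run r re-seeds the estimator with ``base_seed + r`` so runs are
    independent but reproducible.  When ``normalize`` is set, each feature
    column is z-scored with statistics computed on the training folds only.
    Accuracy is per-window: every W×240 sample votes independently.
    """
    plan = loso_split(dataset)
    classes = tuple(np.unique(dataset.skill))
    accs = np.zeros((n_runs, plan.n_super_trials))
    matrices: list[ConfusionCounts] = []
    for r in range(n_runs):
        for k, (test_trial, _train_trials) in enumerate(plan.folds):
            test_mask = dataset.trial == test_trial
            X_tr, y_tr = dataset.X[~test_mask], dataset.skill[~test_mask]
            X_te, y_te = dataset.X[test_mask], dataset.skill[test_mask]
            if normalize:
                mu = X_tr.reshape(-1, X_tr.shape[-1]).mean(axis=0)
                sd = X_tr.reshape(-1, X_tr.shape[-1]).std(axis=0)
                sd = np.where(sd < 1e-8, 1.0, sd)
                X_tr = (X_tr - mu) / sd
                X_te = (X_te - mu) / sd
            est = clone(estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=base_seed + r)
            try:
                est.fit(X_tr, y_tr)
            except Exception as exc:  # noqa: BLE001 - protocol contract
                raise RuntimeError(
                    f"training failed in run {r}, fold {k} (trial {test_trial}): {exc}"
                ) from exc
            y_pred = est.predict(X_te, head=head)
            cm = ConfusionCounts.from_predictions(y_te, y_pred, classes, run=r, fold=k)
            accs[r, k] = cm.accuracy
            matrices.append(cm)
    method = getattr(estimator, "arch_id", type(estimator).__name__)
    return ProtocolResult(method=method, head=head, window_tag=window_tag,
                          accuracies=accs, matrices=matrices)
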