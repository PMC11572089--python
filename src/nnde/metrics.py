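"""Test-set performance metrics, decision-error criteria, and exclusion rules.

A "decision error" (DE) is recorded when a model fitted to null data reaches a
nominally acceptable test-set performance: R^2 >= .10 for continuous outcomes,
or AUC / balanced accuracy at thresholds .6, .65, .7 for binary outcomes.  Two
kinds of replication are excluded from DE estimation because a practitioner
would recognize the fit as failed: the model predicted a single class for
every test row, or the test rows happened to contain a single true class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Exclusion",
    "MetricsReport",
    "DECriterion",
    "CONTINUOUS_CRITERIA",
    "BINARY_CRITERIA",
    "r_squared",
    "auc_rank",
    "balanced_accuracy",
    "exclusion_status",
    "evaluate_test_set",
    "evaluate_criteria",
]

_CONSTANT_TOL = 1e-12


class Exclusion(str, enum.Enum):
    INCLUDED = "INCLUDED"
    CONSTANT_PREDICTION = "CONSTANT_PREDICTION"
    DEGENERATE_TEST_TRUTH = "DEGENERATE_TEST_TRUTH"


@dataclass(frozen=True)
class DECriterion:
    """One acceptability rule: metric in {R2, AUC, BA} and an inclusive threshold."""

    metric: str
    threshold: float

    def __post_init__(self) -> None:
        if self.metric not in ("R2", "AUC", "BA"):
            raise ValueError(f"metric must be one of R2/AUC/BA, got {self.metric!r}")

    @property
    def label(self) -> str:
        return f"{self.metric}>={self.threshold:g}"

    @property
    def task(self) -> str:
        return "regression" if self.metric == "R2" else "classification"


#: The criterion used for continuous outcomes.
CONTINUOUS_CRITERIA = (DECriterion("R2", 0.1),)

#: The six criteria used for binary outcomes.
BINARY_CRITERIA = tuple(
    DECriterion(metric, thr) for metric in ("AUC", "BA") for thr in (0.6, 0.65, 0.7)
)


@dataclass
class MetricsReport:
    """Test-set metrics for one replication plus its exclusion status.

    Metric fields are populated only for the relevant task and only when the
    replication is INCLUDED; excluded replications carry no metric values.
    """

    task: str
    exclusion: Exclusion
    r2: float | None = None
    auc: float | None = None
    balanced_accuracy: float | None = None
    predicted_class_counts: tuple[int, int] | None = None

    def metric_value(self, metric: str) -> float | None:
        return {"R2": self.r2, "AUC": self.auc, "BA": self.balanced_accuracy}[metric]

    def to_record(self) -> dict:
        return {
            "task": self.task,
            "exclusion": self.exclusion.value,
            "r2": self.r2,
            "auc": self.auc,
            "balanced_accuracy": self.balanced_accuracy,
            "predicted_class_counts": (
                list(self.predicted_class_counts)
                if self.predicted_class_counts is not None
                else None
            ),
        }


def r_squared(y_true, y_pred) -> float:
    """Out-of-sample R^2: 1 − SS_res/SS_tot around the *test-set* mean.

    Can be negative (the model predicts worse than the test mean).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2:
        raise ValueError("r_squared needs at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= _CONSTANT_TOL:
        raise ValueError("y_true is constant; R^2 is undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def auc_rank(y_true, scores) -> float:
    """ROC AUC in Mann–Whitney form via average ranks; ties count 1/2.

    Equals the probability that a random positive outranks a random negative.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_rank needs both a positive and a negative example")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = float(ranks[pos].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def balanced_accuracy(y_true, scores, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2, classifying score >= threshold as positive."""
    y_true = np.asarray(y_true)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    pos = y_true == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("balanced_accuracy needs both classes in y_true")
    sensitivity = float((pred[pos] == 1).mean())
    specificity = float((pred[neg] == 0).mean())
    return 0.5 * (sensitivity + specificity)


def exclusion_status(y_true_test, scores, task: str, threshold: float = 0.5) -> Exclusion:
    """Classify one replication against the two exclusion rules.

    Degenerate test truth (all true test values identical) takes precedence
    over constant prediction.  Constant prediction means all thresholded
    classes agree (classification) or the prediction range is numerically
    zero (regression analog).
    """
    y_true_test = np.asarray(y_true_test)
    scores = np.asarray(scores, dtype=float)
    if len(y_true_test) == 0:
        raise ValueError("empty test set")
    if np.all(y_true_test == y_true_test[0]):
        return Exclusion.DEGENERATE_TEST_TRUTH
    if task == "classification":
        classes = scores >= threshold
        if classes.all() or not classes.any():
            return Exclusion.CONSTANT_PREDICTION
    else:
        if float(np.ptp(scores)) < _CONSTANT_TOL:
            return Exclusion.CONSTANT_PREDICTION
    return Exclusion.INCLUDED


def evaluate_test_set(
    y_true, scores, task: str, threshold: float = 0.5
) -> MetricsReport:
    """Build the per-replication report: exclusion status, then metrics if included."""
    status = exclusion_status(y_true, scores, task, threshold)
    report = MetricsReport(task=task, exclusion=status)
    if task == "classification":
        pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
        report.predicted_class_counts = (int((pred == 0).sum()), int((pred == 1).sum()))
    if status is not Exclusion.INCLUDED:
        return report
    if task == "regression":
        report.r2 = r_squared(y_true, scores)
    else:
        report.auc = auc_rank(y_true, scores)
        report.balanced_accuracy = balanced_accuracy(y_true, scores, threshold)
    return report


def evaluate_criteria(report: MetricsReport, criteria) -> dict:
    """Per-criterion DE flags: True iff metric value >= threshold (inclusive).

    Excluded replications get ``None`` for every flag.  Requesting a metric
    that does not belong to the report's task is a contract error.
    """
    flags: dict[str, bool | None] = {}
    for criterion in criteria:
        if criterion.task != report.task:
            raise ValueError(
                f"criterion {criterion.label} does not apply to task {report.task!r}"
            )
        if report.exclusion is not Exclusion.INCLUDED:
            flags[criterion.label] = None
        else:
            flags[criterion.label] = bool(report.metric_value(criterion.metric) >= criterion.threshold)
    return flags
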