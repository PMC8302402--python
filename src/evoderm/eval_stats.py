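"""Classifier evaluation statistics: confusion matrices, accuracies, paired t-test.

Implements the statistics used to compare a classifier's per-class accuracy
under two image conditions (motion-blurred vs GA-enhanced): confusion
matrices, per-class and overall accuracy, mean/SD summaries, and the paired
t-test of the matched per-class accuracy differences with hypotheses
H0: mu1 - mu2 = 0 against Ha: mu1 - mu2 > 0.

The module also bundles the seven-class dermoscopy case-study tables this
package ships as reference inputs: per-class test-image counts and the
per-class accuracies measured on blurred and on GA-enhanced images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .synthetic_data import DEFAULT_CLASS_ORDER

__all__ = [
    "CLASS_ORDER",
    "TEST_COUNTS",
    "ACCURACY_GA_ENHANCED",
    "ACCURACY_BLURRED",
    "InvalidInputError",
    "InsufficientDataError",
    "UndefinedClassError",
    "ClassificationTable",
    "ConfusionMatrix",
    "PairedTTestResult",
    "confusion_matrix",
    "per_class_accuracy",
    "overall_accuracy",
    "summarize",
    "paired_t_test",
    "case_study_table",
]


class InvalidInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class UndefinedClassError(ValueError):
    pass


#: fixed class order of every tabular output
CLASS_ORDER: tuple[str, ...] = DEFAULT_CLASS_ORDER

#: bundled case study: number of test images per class (total 589)
TEST_COUNTS: dict[str, int] = dict(zip(CLASS_ORDER, (130, 201, 128, 40, 54, 13, 23)))

#: bundled case study: per-class accuracy (%) on GA-enhanced images
ACCURACY_GA_ENHANCED: dict[str, float] = dict(
    zip(CLASS_ORDER, (94.62, 99.50, 99.22, 92.50, 98.15, 84.62, 86.96))
)

#: bundled case study: per-class accuracy (%) on motion-blurred images
ACCURACY_BLURRED: dict[str, float] = dict(
    zip(CLASS_ORDER, (91.54, 87.56, 96.88, 77.50, 85.19, 76.92, 60.87))
)


@dataclass(frozen=True)
class ClassificationTable:
    """Per-class test counts and correct counts (or accuracy percentages)."""

    class_names: tuple[str, ...]
    counts: tuple[int, ...]
    correct: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.class_names) == len(self.counts) == len(self.correct)):
            raise InvalidInputError("table columns must align")
        for c, k in zip(self.counts, self.correct):
            if not 0 <= k <= c:
                raise InvalidInputError(f"correct count {k} outside [0, {c}]")

    @property
    def accuracies_pct(self) -> np.ndarray:
        return 100.0 * np.asarray(self.correct) / np.asarray(self.counts)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predicted classes."""

    matrix: np.ndarray = field(repr=False)
    class_names: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        n = len(self.class_names)
        if m.shape != (n, n):
            raise InvalidInputError(f"matrix shape {m.shape} != ({n}, {n})")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            raise InvalidInputError("matrix must hold nonnegative integers")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.class_names, columns=self.class_names)


def confusion_matrix(
    true_labels, predicted_labels, class_order: tuple[str, ...] = CLASS_ORDER
) -> ConfusionMatrix:
    """Count matrix with cell (i, j) = samples of true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise InvalidInputError("label lists must have equal length")
    known = set(class_order)
    unknown = {l for l in true_labels + predicted_labels if l not in known}
    if unknown:
        raise InvalidInputError(f"unknown labels: {sorted(unknown)}")
    m = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    return ConfusionMatrix(m.astype(int), tuple(class_order))


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """100 * diagonal / row sum, per class (percent)."""
    row_sums = cm.matrix.sum(axis=1)
    empty = [name for name, s in zip(cm.class_names, row_sums) if s == 0]
    if empty:
        raise UndefinedClassError(f"no test samples for classes: {empty}")
    return 100.0 * np.diag(cm.matrix) / row_sums


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * trace / total: the fraction of correctly classified images."""
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.matrix)) / cm.total


def summarize(accuracies) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    a = np.asarray(accuracies, dtype=float)
    if a.size < 2:
        raise InsufficientDataError("need at least 2 values to summarize")
    return float(a.mean()), float(a.std(ddof=1))


@dataclass(frozen=True)
class PairedTTestResult:
    """Paired t-test of matched differences a - b.

    ``t = d / (s / sqrt(n))`` with ``d`` the mean and ``s`` the sample SD of
    the differences; ``p_one_sided`` is the upper-tail probability under the
    alternative mu_a - mu_b > 0; ``p_two_sided`` is also reported.
    ``degenerate`` flags zero-variance differences with nonzero mean
    (t reported as +/- infinity).
    """

    mean_diff: float
    sd_diff: float
    n: int
    df: int
    t: float
    p_one_sided: float
    p_two_sided: float
    reject_at_05: bool
    degenerate: bool = False


def paired_t_test(sample_a, sample_b, alternative: str = "greater") -> PairedTTestResult:
    """Paired t-test of ``sample_a - sample_b`` (default upper-tail alternative)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("samples must be 1-D and of equal length")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    if alternative not in ("greater", "less", "two-sided"):
        raise InvalidInputError(f"unknown alternative {alternative!r}")

    diff = a - b
    n = diff.size
    d = float(diff.mean())
    s = float(diff.std(ddof=1))
    df = n - 1
    degenerate = False
    if s == 0.0:
        if d == 0.0:
            t = 0.0
        else:
            t = math.copysign(math.inf, d)
            degenerate = True
    else:
        t = d / (s / math.sqrt(n))

    # one-sided upper-tail p; the t CDF is evaluated through the regularized
    # incomplete beta function
    p_upper = float(sp_stats.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    p_two = float(2 * sp_stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if alternative == "greater":
        p_primary = p_upper
    elif alternative == "less":
        p_primary = 1.0 - p_upper if math.isfinite(t) else (1.0 if t > 0 else 0.0)
    else:
        p_primary = p_two
    return PairedTTestResult(
        mean_diff=d,
        sd_diff=s,
        n=n,
        df=df,
        t=t,
        p_one_sided=p_upper,
        p_two_sided=p_two,
        reject_at_05=p_primary < 0.05,
        degenerate=degenerate,
    )


def case_study_table(condition: str = "blurred") -> ClassificationTable:
    """The bundled case study as a :class:`ClassificationTable`.

    ``condition`` selects the accuracy column ('blurred' or 'ga'); correct
    counts are ``round(accuracy * count)`` per class.
    """
    acc = {"blurred": ACCURACY_BLURRED, "ga": ACCURACY_GA_ENHANCED}[condition]
    counts = tuple(TEST_COUNTS[c] for c in CLASS_ORDER)
    correct = tuple(
        int(round(acc[c] / 100.0 * TEST_COUNTS[c])) for c in CLASS_ORDER
    )
    return ClassificationTable(CLASS_ORDER, counts, correct)
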