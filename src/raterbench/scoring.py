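"""Tie-tolerant decision rule, partial-credit scoring and categorical metrics.

The predicted diagnosis is the category with the highest assigned probability.
When k categories share the maximum the case credit is split 1/k among them:
a case is fully correct when the truth is the unique maximum, fractionally
correct (1/k) when the truth is among k tied maxima, and incorrect otherwise.
Tabulating the per-case credit vectors stratified by truth yields fractional
confusion matrices, from which accuracy / sensitivity / specificity (with
Wilson or Wald intervals on the fractional success counts), weighted F1 and a
tie-aware Cohen's kappa are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import AssessmentTable, CategorySet, UndefinedStatistic


def assign_credit(
    p: Sequence[float] | np.ndarray,
    tie_tolerance: float = 1e-9,
    decimals: int | None = None,
) -> np.ndarray:
    """Fractional label assignment under the tie-tolerant argmax rule.

    Categories whose value lies within ``tie_tolerance`` of the maximum form
    the tie set of size k; each receives credit 1/k, all others 0.  In
    reported-precision mode (``decimals`` set) values are rounded first, so
    probabilities recorded at e.g. one-decimal percent (``decimals=3``) tie
    exactly the way the observer recorded them.
    """
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be non-negative")
    arr = np.asarray(p, dtype=float)
    if decimals is not None:
        arr = np.round(arr, decimals)
    top = arr.max()
    mask = arr >= top - tie_tolerance
    return mask / mask.sum()


def score_case(credit: np.ndarray, truth_index: int) -> float:
    """Per-case correctness: the credit mass sitting on the true category."""
    return float(credit[truth_index])


@dataclass
class FractionalConfusionMatrix:
    """Truth-by-predicted tabulation with fractional tie-split entries.

    Rows cover the truth categories present in the data; columns cover the
    full category set.  Row sums equal the per-class subject counts.
    """

    truth_codes: tuple[str, ...]
    pred_codes: tuple[str, ...]
    counts: np.ndarray  # shape (len(truth_codes), len(pred_codes))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.truth_codes), len(self.pred_codes)):
            raise ValueError("confusion matrix shape mismatch")
        if np.any(self.counts < -1e-12):
            raise ValueError("negative confusion-matrix mass")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def row_total(self, code: str) -> float:
        return float(self.counts[self.truth_codes.index(code)].sum())

    def cell(self, truth: str, pred: str) -> float:
        return float(
            self.counts[self.truth_codes.index(truth), self.pred_codes.index(pred)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.truth_codes), columns=list(self.pred_codes)
        )


def confusion_matrix(
    table: AssessmentTable,
    rater: str,
    tie_tolerance: float = 1e-9,
    decimals: int | None = None,
) -> FractionalConfusionMatrix:
    """Fractional confusion matrix for one rater, rows ordered per category set."""
    cats = table.categories
    labels = table.truth_labels()
    truth_codes = tuple(c for c in cats.codes if c in set(labels))
    counts = np.zeros((len(truth_codes), cats.n))
    probs = table.rater_probs(rater)
    row_of = {c: i for i, c in enumerate(truth_codes)}
    for vec, label in zip(probs, labels):
        counts[row_of[label]] += assign_credit(vec, tie_tolerance, decimals)
    return FractionalConfusionMatrix(truth_codes, cats.codes, counts)


# ---------------------------------------------------------------------------
# Proportion intervals
# ---------------------------------------------------------------------------

def wilson_interval(
    successes: float, n: float, conf_level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval, accepting fractional success counts.

    Partial-credit proportions have fractional numerators (e.g. 1.5 correct
    out of 2); the fractional count is substituted directly into the Wilson
    closed form.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = norm.ppf(0.5 + conf_level / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    # the bounds are exactly 0 / 1 at the boundary counts; snap to avoid
    # floating-point residue breaking the lower <= estimate <= upper contract
    lower = 0.0 if successes == 0 else max(0.0, center - half)
    upper = 1.0 if successes == n else min(1.0, center + half)
    return (lower, upper)


def wald_interval(
    successes: float, n: float, conf_level: float = 0.95
) -> tuple[float, float]:
    """Classical Wald (normal-approximation) interval, clamped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + conf_level / 2)
    phat = successes / n
    half = z * np.sqrt(phat * (1 - phat) / n)
    return (max(0.0, phat - half), min(1.0, phat + half))


_INTERVALS = {"wilson": wilson_interval, "wald": wald_interval}


# ---------------------------------------------------------------------------
# Binary classification metrics from the fractional matrix
# ---------------------------------------------------------------------------

@dataclass
class ClassificationMetrics:
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    weighted_f1: float
    n_pos: float
    n_neg: float
    kappa_vs_truth: float | None = None

    def with_kappa(self, kappa: float | None) -> "ClassificationMetrics":
        return replace(self, kappa_vs_truth=kappa)


def classification_metrics(
    m: FractionalConfusionMatrix,
    categories: CategorySet | None = None,
    conf_level: float = 0.95,
    method: str = "wilson",
) -> ClassificationMetrics:
    """Accuracy / sensitivity / specificity with CIs, plus weighted F1.

    Credit mass landing on any of the five non-CN/AD categories counts as a
    misclassification for the binary outcome: only the diagonal CN and AD
    cells contribute successes.
    """
    cats = categories or CategorySet()
    pos, neg = cats.positive, cats.negative
    for code in (pos, neg):
        if code not in m.truth_codes:
            raise ValueError(f"confusion matrix has no row for class {code!r}")
    interval = _INTERVALS[method]
    n_pos, n_neg = m.row_total(pos), m.row_total(neg)
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both truth classes need at least one subject")
    n = m.total
    tp, tn = m.cell(pos, pos), m.cell(neg, neg)
    accuracy = (tp + tn) / n
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    return ClassificationMetrics(
        accuracy=accuracy,
        accuracy_ci=interval(tp + tn, n, conf_level),
        sensitivity=sensitivity,
        sensitivity_ci=interval(tp, n_pos, conf_level),
        specificity=specificity,
        specificity_ci=interval(tn, n_neg, conf_level),
        weighted_f1=weighted_f1(m, cats),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def weighted_f1(
    m: FractionalConfusionMatrix,
    categories: CategorySet | None = None,
    over: str = "truth",
) -> float:
    """Support-weighted F1 over the truth classes of the fractional matrix.

    Per class: precision = diagonal / column sum (0 when the column is
    empty), recall = diagonal / row sum, F1 their harmonic mean (0 when both
    vanish); classes are weighted by row support.  ``over="full"`` extends
    the average to every category in the set (absent truth rows contribute
    zero support and are no-ops).
    """
    if over not in ("truth", "full"):
        raise ValueError("over must be 'truth' or 'full'")
    classes = m.truth_codes if over == "truth" else m.pred_codes
    n = m.total
    score = 0.0
    col_sums = m.counts.sum(axis=0)
    for code in classes:
        if code not in m.truth_codes:
            continue
        row = m.truth_codes.index(code)
        col = m.pred_codes.index(code)
        support = m.counts[row].sum()
        diag = m.counts[row, col]
        col_sum = col_sums[col]
        precision = diag / col_sum if col_sum > 0 else 0.0
        recall = diag / support if support > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        score += (support / n) * f1
    return score


# ---------------------------------------------------------------------------
# Tie-aware Cohen's kappa
# ---------------------------------------------------------------------------

def labels_to_credit(labels: Sequence[str], categories: CategorySet) -> np.ndarray:
    """Encode hard labels as unit credit vectors (n × n_categories)."""
    out = np.zeros((len(labels), categories.n))
    for i, label in enumerate(labels):
        out[i, categories.index(label)] = 1.0
    return out


def credit_matrix(
    table: AssessmentTable,
    rater: str,
    tie_tolerance: float = 1e-9,
    decimals: int | None = None,
) -> np.ndarray:
    """Stack of per-case credit vectors for one rater (n × n_categories)."""
    return np.vstack(
        [assign_credit(v, tie_tolerance, decimals) for v in table.rater_probs(rater)]
    )


def tie_aware_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two stacks of credit vectors.

    Observed agreement is the mean per-case dot product of credit vectors
    (so a half tie overlapping a firm call contributes 0.5); expected
    agreement is the dot product of the two raters' mean credit profiles.
    With tie-free (unit) credit vectors this is exactly classical Cohen's
    kappa.  Truth labels may stand in for either rater via
    :func:`labels_to_credit`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need two equal-shape credit stacks with n >= 2")
    p_o = float(np.mean(np.sum(a * b, axis=1)))
    p_e = float(np.dot(a.mean(axis=0), b.mean(axis=0)))
    if p_e >= 1 - 1e-12:
        raise UndefinedStatistic(
            "expected agreement is 1 (both raters degenerate on one category)"
        )
    return (p_o - p_e) / (1 - p_e)
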