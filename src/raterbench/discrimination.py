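"""ROC analysis, DeLong's paired AUC test, and correlated-AUC power analysis.

Discrimination is always assessed on a continuous score channel (here the AD
probability) against the binary truth.  The positivity convention throughout
is "positive iff score >= threshold"; tied scores therefore produce diagonal
ROC segments and contribute half-credit to the Mann–Whitney AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .data_model import AssessmentTable, UndefinedStatistic


def _split_by_class(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


@dataclass
class ROCCurve:
    """Empirical ROC staircase: thresholds (descending, +inf sentinel first)
    and the matching (FPR, TPR) points starting at (0,0) and ending at (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_points(scores, labels) -> ROCCurve:
    """Empirical ROC curve for the rule "call positive iff score >= t"."""
    pos, neg = _split_by_class(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # block ends of distinct score values
    ends = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = np.cumsum(y)[ends]
    fp = np.cumsum(1 - y)[ends]
    thresholds = np.r_[np.inf, s[ends]]
    tpr = np.r_[0.0, tp / len(pos)]
    fpr = np.r_[0.0, fp / len(neg)]
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc_mann_whitney(scores_pos, scores_neg) -> float:
    """AUC as the Mann–Whitney probability, half-credit for exact ties.

    Computed from mid-ranks, which agrees exactly with exhaustive pair
    counting (rank sums of half-integers are exact in double precision).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg)))


def auc_from_labels(scores, labels) -> float:
    pos, neg = _split_by_class(scores, labels)
    return auc_mann_whitney(pos, neg)


@dataclass
class AUCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int


def bootstrap_auc_ci(
    table: AssessmentTable,
    rater: str,
    n_boot: int = 2000,
    conf_level: float = 0.95,
    seed: int = 0,
) -> AUCResult:
    """Percentile bootstrap CI for one rater's AUC (stratified resampling)."""
    return bootstrap_auc_ci_arrays(
        table.positive_scores(rater), table.binary_truth(), n_boot, conf_level, seed
    )


def bootstrap_auc_ci_arrays(
    scores, labels, n_boot: int = 2000, conf_level: float = 0.95, seed: int = 0
) -> AUCResult:
    """Percentile bootstrap on raw arrays: resample within each truth class
    with replacement, so every replicate keeps both classes by construction."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    pos, neg = _split_by_class(scores, labels)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        p = pos[rng.integers(0, len(pos), len(pos))]
        n = neg[rng.integers(0, len(neg), len(neg))]
        reps[i] = auc_mann_whitney(p, n)
    alpha = (1 - conf_level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return AUCResult(
        auc=auc_mann_whitney(pos, neg),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DeLong's test
# ---------------------------------------------------------------------------

def _placements(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values: for each positive, the fraction of negatives it
    outranks (ties half); conversely for negatives.  Their means equal the
    AUC."""
    pos, neg = _split_by_class(scores, labels)
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(v10.mean())


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single empirical AUC."""
    v10, v01, _ = _placements(scores, labels)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(v10) + s01 / len(v01))


@dataclass
class PairedAUCTest:
    auc_a: float
    auc_b: float
    delta: float
    variance_delta: float
    z: float | None
    p: float | None
    reason: str | None = None


def delong_test(scores_a, scores_b, labels) -> PairedAUCTest:
    """DeLong's paired test for two correlated empirical AUCs.

    Both score vectors must be aligned to the same subjects.  The variance of
    the AUC difference combines the covariance matrices of the two raters'
    placement-value vectors:

        Var(dA) = (S10_aa + S10_bb - 2 S10_ab) / n_pos
                + (S01_aa + S01_bb - 2 S01_ab) / n_neg

    Zero variance (e.g. identical score vectors) yields a null z / p with a
    reason rather than a spurious statistic.
    """
    labels = np.asarray(labels, dtype=int)
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    n_pos, n_neg = len(v10a), len(v01a)
    delta = auc_a - auc_b
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = 0.0
    if n_pos > 1:
        var += d10.var(ddof=1) / n_pos
    if n_neg > 1:
        var += d01.var(ddof=1) / n_neg
    if var <= 0:
        return PairedAUCTest(
            auc_a, auc_b, delta, 0.0, None, None,
            reason="zero variance of the AUC difference",
        )
    z = delta / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return PairedAUCTest(auc_a, auc_b, delta, float(var), float(z), p)


# ---------------------------------------------------------------------------
# Power analysis for two correlated AUCs
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Design parameters for detecting a difference between two correlated AUCs."""

    n_pos: int = 18
    n_neg: int = 20
    r: float = 0.5
    alpha: float = 0.05
    power: float = 0.80
    baseline_auc: float = 0.80
    method: str = "analytic"
    n_sim: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if not -1 <= self.r <= 1:
            raise ValueError("correlation must lie in [-1, 1]")
        if not 0.5 < self.baseline_auc < 1:
            raise ValueError("baseline_auc must lie in (0.5, 1)")
        if self.method not in ("analytic", "simulation"):
            raise ValueError("method must be 'analytic' or 'simulation'")


def hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Exponential-approximation variance of an empirical AUC:
    V = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A)."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    return (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)


def detectable_auc_difference(spec: PowerSpec) -> float:
    """Minimal AUC difference detectable at the specified power.

    Analytic mode: both observers' AUC variances are evaluated at
    ``baseline_auc`` via the exponential approximation, the variance of the
    difference is 2 V (1 - r), and the detectable difference is
    (z_{1-alpha/2} + z_{power}) * sqrt(Var).  Simulation mode solves for the
    difference by bisection over a paired binormal observer model tested with
    DeLong's statistic.
    """
    if spec.method == "analytic":
        v = hanley_mcneil_variance(spec.baseline_auc, spec.n_pos, spec.n_neg)
        var_delta = 2 * v * (1 - spec.r)
        z = norm.ppf(1 - spec.alpha / 2) + norm.ppf(spec.power)
        return float(z * np.sqrt(var_delta))
    return _simulated_detectable_difference(spec)


def _simulated_power(delta: float, spec: PowerSpec, rng: np.random.Generator) -> float:
    """Rejection rate of DeLong's test for true AUCs baseline ± delta/2 under
    a paired binormal model with score correlation r."""
    a_hi = spec.baseline_auc + delta / 2
    a_lo = spec.baseline_auc - delta / 2
    # delta is capped so that both AUCs stay inside [0.5, 1)
    shift_hi = np.sqrt(2) * norm.ppf(a_hi)
    shift_lo = np.sqrt(2) * norm.ppf(a_lo)
    n = spec.n_pos + spec.n_neg
    labels = np.r_[np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    rejections = 0
    valid = 0
    for _ in range(spec.n_sim):
        e1 = rng.standard_normal(n)
        e2 = spec.r * e1 + np.sqrt(1 - spec.r**2) * rng.standard_normal(n)
        x = e1 + shift_hi * labels
        y = e2 + shift_lo * labels
        res = delong_test(x, y, labels)
        if res.p is not None:
            valid += 1
            if res.p < spec.alpha:
                rejections += 1
    if valid == 0:
        raise UndefinedStatistic("no valid DeLong replicates in power simulation")
    return rejections / valid


def _simulated_detectable_difference(spec: PowerSpec) -> float:
    rng = np.random.default_rng(spec.seed)
    if spec.r >= 1:
        return 0.0
    lo = 0.0
    hi = min(2 * (1 - spec.baseline_auc) - 1e-3, 2 * (spec.baseline_auc - 0.5))
    if _simulated_power(hi, spec, rng) < spec.power:
        return float(hi)  # target power unreachable inside the valid range
    for _ in range(11):
        mid = (lo + hi) / 2
        if _simulated_power(mid, spec, rng) >= spec.power:
            hi = mid
        else:
            lo = mid
    return float((lo + hi) / 2)
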