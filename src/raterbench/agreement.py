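"""Continuous-score agreement and variability statistics between observers.

Operates on the paired AD-probability channels of two observers: Pearson and
Spearman correlation, single-measure absolute-agreement ICC, Bland–Altman
limits of agreement, and Levene's test for equality of variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import UndefinedStatistic


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatistic("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties), t-approximation p."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatistic("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc_absolute_single(scores: np.ndarray) -> float:
    """Single-measure absolute-agreement ICC from a two-way ANOVA.

    ``scores`` is a complete subjects × raters matrix.  Using the two-way
    mean squares (rows = subjects, columns = raters),

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    Negative values are legitimate and occur when between-rater disagreement
    exceeds between-subject variance.
    """
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("scores must be finite (complete matrix required)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 1e-300:
        raise UndefinedStatistic("zero total variance")
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        raise UndefinedStatistic("degenerate ANOVA decomposition")
    return (ms_rows - ms_err) / denom


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray  # per-case (x + y) / 2, for plotting
    diffs: np.ndarray  # per-case x - y


def bland_altman(x, y) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD).

    Differences are x − y; the SD uses the n−1 denominator.  A single pair
    yields SD 0 by convention.
    """
    x, y = _paired(x, y, 2)
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        means=(x + y) / 2,
        diffs=d,
    )


def levene(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances across groups.

    ``center="mean"`` is the classical Levene statistic; ``"median"`` gives
    the Brown–Forsythe variant.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    devs = np.concatenate(
        [np.abs(g - (g.mean() if center == "mean" else np.median(g))) for g in arrays]
    )
    if np.ptp(devs) == 0:
        raise UndefinedStatistic(
            "Levene statistic undefined: absolute deviations have zero spread"
        )
    f, p = stats.levene(*arrays, center=center)
    if not np.isfinite(f):
        raise UndefinedStatistic("Levene statistic undefined on these groups")
    return float(f), float(p)
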