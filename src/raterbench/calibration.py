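"""Probability calibration and decision-curve (net benefit) analysis.

All operations act on the continuous disease-class (AD) probability channel
against the binary truth (1 = AD).  The decision-curve positivity convention
matches ROC analysis: a case is called positive iff its probability is at
least the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AssessmentTable


def _aligned(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape or probs.ndim != 1 or len(probs) == 0:
        raise ValueError("probs and labels must be aligned non-empty 1-D vectors")
    return probs, labels


def brier(probs, labels) -> float:
    """Mean squared error between forecast probabilities and binary outcomes."""
    probs, labels = _aligned(probs, labels)
    return float(np.mean((probs - labels) ** 2))


@dataclass
class CalibrationCurve:
    """Reliability diagram data: one (mean predicted, observed fraction,
    count) triple per non-empty bin."""

    mean_predicted: np.ndarray
    observed_fraction: np.ndarray
    counts: np.ndarray
    strategy: str
    n_bins: int


def calibration_curve(
    probs, labels, n_bins: int = 5, strategy: str = "width"
) -> CalibrationCurve:
    """Bin predictions and compare mean forecast with observed event rate.

    ``width`` uses equal-width bins over [0, 1]; ``quantile`` places edges at
    empirical quantiles of the forecasts (duplicate edges collapse).  Bins
    are half-open [lo, hi) with the last bin closed; empty bins are omitted.
    """
    probs, labels = _aligned(probs, labels)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if strategy == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif strategy == "quantile":
        edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 2:
            edges = np.array([edges[0], edges[0] + 1e-12])
    else:
        raise ValueError("strategy must be 'width' or 'quantile'")
    idx = np.digitize(probs, edges[1:-1], right=False)
    mean_pred, obs_frac, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        mean_pred.append(float(probs[mask].mean()))
        obs_frac.append(float(labels[mask].mean()))
        counts.append(int(mask.sum()))
    return CalibrationCurve(
        mean_predicted=np.asarray(mean_pred),
        observed_fraction=np.asarray(obs_frac),
        counts=np.asarray(counts),
        strategy=strategy,
        n_bins=n_bins,
    )


def net_benefit(probs, labels, p_t: float) -> float:
    """Net benefit of calling positive iff prob >= p_t:
    TP/N − (FP/N) · p_t/(1−p_t)."""
    if not 0 < p_t < 1:
        raise ValueError("threshold probability must lie strictly in (0, 1)")
    probs, labels = _aligned(probs, labels)
    calls = probs >= p_t
    n = len(labels)
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    return tp / n - (fp / n) * p_t / (1 - p_t)


def treat_all_net_benefit(labels, p_t: float) -> float:
    """Net benefit of the "diagnose all" strategy; crosses 0 at p_t = prevalence."""
    if not 0 < p_t < 1:
        raise ValueError("threshold probability must lie strictly in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    prev = float(labels.mean())
    return prev - (1 - prev) * p_t / (1 - p_t)


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: dict[str, np.ndarray]  # per rater
    treat_all: np.ndarray
    treat_none: np.ndarray
    positive_over_core_range: dict[str, bool]  # NB > 0 throughout [0.1, 0.9]


def default_threshold_grid(
    start: float = 0.05, stop: float = 0.95, step: float = 0.01
) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 10)


def decision_curve(
    table: AssessmentTable,
    raters=None,
    grid: np.ndarray | None = None,
) -> DecisionCurve:
    """Decision-curve analysis for a set of raters plus reference strategies."""
    raters = list(raters) if raters is not None else list(table.raters)
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    labels = table.binary_truth()
    curves: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    for rater in raters:
        probs = table.positive_scores(rater)
        nb = np.array([net_benefit(probs, labels, t) for t in grid])
        curves[rater] = nb
        core = (grid >= 0.1 - 1e-12) & (grid <= 0.9 + 1e-12)
        flags[rater] = bool(np.all(nb[core] > 0)) if core.any() else False
    treat_all = np.array([treat_all_net_benefit(labels, t) for t in grid])
    return DecisionCurve(
        thresholds=grid,
        net_benefit=curves,
        treat_all=treat_all,
        treat_none=np.zeros_like(grid),
        positive_over_core_range=flags,
    )
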