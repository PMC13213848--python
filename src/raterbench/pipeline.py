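"""End-to-end evaluation pipeline assembling the full metric report.

Runs, in order: tie-aware decision scoring per rater, pairwise agreement on
the continuous AD channel, per-rater discrimination (ROC, bootstrap AUC CI)
plus pairwise DeLong tests, and calibration / decision-curve analysis.  Every
statistic lands in a :class:`~raterbench.data_model.MetricReport`; statistics
that are undefined on the data appear as null with a reason code.  Runs are
byte-deterministic for a fixed config and seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .agreement import bland_altman, icc_absolute_single, levene, pearson, spearman
from .calibration import brier, calibration_curve, decision_curve, default_threshold_grid
from .data_model import (
    AssessmentTable,
    MetricReport,
    UndefinedStatistic,
    config_digest,
)
from .discrimination import (
    PowerSpec,
    bootstrap_auc_ci,
    delong_test,
    detectable_auc_difference,
    roc_points,
)
from .scoring import (
    classification_metrics,
    confusion_matrix,
    credit_matrix,
    labels_to_credit,
    tie_aware_kappa,
)

logger = logging.getLogger("raterbench")


@dataclass
class RunConfig:
    """All tunable parameters of one evaluation run."""

    tie_tolerance: float = 1e-9
    tie_decimals: int | None = None  # reported-precision tie mode
    conf_level: float = 0.95
    ci_method: str = "wilson"
    n_boot: int = 2000
    seed: int = 0
    calibration_bins: int = 5
    calibration_strategy: str = "width"
    dca_start: float = 0.05
    dca_stop: float = 0.95
    dca_step: float = 0.01
    levene_center: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must lie in (0, 1)")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be non-negative")
        if not 0 < self.dca_start < self.dca_stop < 1:
            raise ValueError("decision-curve grid must lie inside (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _catch(fn, *args, **kwargs):
    """Run a statistic, returning (value, reason) with reason set when the
    statistic is undefined on this data."""
    try:
        return fn(*args, **kwargs), None
    except UndefinedStatistic as exc:
        return None, exc.reason


def _kappa_block(a, b):
    value, reason = _catch(tie_aware_kappa, a, b)
    return value, reason


def run_evaluation(table: AssessmentTable, config: RunConfig | None = None) -> MetricReport:
    """Execute the complete comparative analysis on one assessment table."""
    config = config or RunConfig()
    cats = table.categories
    labels = table.binary_truth()
    truth_credit = labels_to_credit(table.truth_labels(), cats)
    report = MetricReport()
    report.provenance = {
        "tool": "raterbench",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config_digest(config.to_dict()),
        "n_subjects": table.n_subjects,
        "n_pos": int(labels.sum()),
        "n_neg": int(len(labels) - labels.sum()),
        "raters": list(table.raters),
        "categories": list(cats.codes),
    }

    credits = {
        r: credit_matrix(table, r, config.tie_tolerance, config.tie_decimals)
        for r in table.raters
    }

    logger.info("stage=classification raters=%d", len(table.raters))
    for rater in table.raters:
        cm = confusion_matrix(table, rater, config.tie_tolerance, config.tie_decimals)
        metrics = classification_metrics(cm, cats, config.conf_level, config.ci_method)
        kappa, kappa_reason = _kappa_block(credits[rater], truth_credit)
        report.classification[rater] = {
            "accuracy": metrics.accuracy,
            "accuracy_ci": list(metrics.accuracy_ci),
            "sensitivity": metrics.sensitivity,
            "sensitivity_ci": list(metrics.sensitivity_ci),
            "specificity": metrics.specificity,
            "specificity_ci": list(metrics.specificity_ci),
            "weighted_f1": metrics.weighted_f1,
            "kappa_vs_truth": kappa,
            "kappa_vs_truth_reason": kappa_reason,
            "n_pos": metrics.n_pos,
            "n_neg": metrics.n_neg,
            "confusion_matrix": {
                "truth_codes": list(cm.truth_codes),
                "pred_codes": list(cm.pred_codes),
                "counts": cm.counts.tolist(),
            },
            "ci_method": config.ci_method,
        }

    logger.info("stage=agreement pairs=%d", len(table.raters) * (len(table.raters) - 1) // 2)
    for a, b in itertools.combinations(table.raters, 2):
        x = table.positive_scores(a)
        y = table.positive_scores(b)
        (r_val, reason_r) = _catch(pearson, x, y)
        (s_val, reason_s) = _catch(spearman, x, y)
        icc, reason_icc = _catch(icc_absolute_single, np.column_stack([x, y]))
        kappa, reason_k = _kappa_block(credits[a], credits[b])
        lev, reason_lev = _catch(levene, [x, y], config.levene_center)
        ba = bland_altman(x, y)
        report.agreement[f"{a}|{b}"] = {
            "pearson_r": None if r_val is None else r_val[0],
            "pearson_p": None if r_val is None else r_val[1],
            "pearson_reason": reason_r,
            "spearman_rho": None if s_val is None else s_val[0],
            "spearman_p": None if s_val is None else s_val[1],
            "spearman_reason": reason_s,
            "icc_a1": icc,
            "icc_a1_reason": reason_icc,
            "kappa_between": kappa,
            "kappa_between_reason": reason_k,
            "bland_altman": {
                "mean_diff": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
            },
            "levene_f": None if lev is None else lev[0],
            "levene_p": None if lev is None else lev[1],
            "levene_reason": reason_lev,
        }

    logger.info("stage=discrimination n_boot=%d", config.n_boot)
    grid = default_threshold_grid(config.dca_start, config.dca_stop, config.dca_step)
    dca = decision_curve(table, table.raters, grid)
    for idx, rater in enumerate(table.raters):
        scores = table.positive_scores(rater)
        curve = roc_points(scores, labels)
        boot_seed = int(
            np.random.SeedSequence((config.seed & 0x7FFFFFFF, 2, idx)).generate_state(1)[0]
            % (2**31)
        )
        auc_res = bootstrap_auc_ci(
            table, rater, config.n_boot, config.conf_level, boot_seed
        )
        cal = calibration_curve(
            scores, labels, config.calibration_bins, config.calibration_strategy
        )
        report.discrimination[rater] = {
            "auc": auc_res.auc,
            "auc_ci": [auc_res.ci_lower, auc_res.ci_upper],
            "n_boot": auc_res.n_boot,
            "bootstrap_seed": auc_res.seed,
            "roc": {
                "thresholds": [
                    "inf" if not np.isfinite(t) else float(t)
                    for t in curve.thresholds
                ],
                "fpr": curve.fpr.tolist(),
                "tpr": curve.tpr.tolist(),
            },
            "brier": brier(scores, labels),
            "calibration": {
                "mean_predicted": cal.mean_predicted.tolist(),
                "observed_fraction": cal.observed_fraction.tolist(),
                "counts": cal.counts.tolist(),
                "strategy": cal.strategy,
                "n_bins": cal.n_bins,
            },
            "net_benefit": dca.net_benefit[rater].tolist(),
            "net_benefit_positive_0p1_0p9": dca.positive_over_core_range[rater],
        }
    report.decision_reference = {
        "thresholds": dca.thresholds.tolist(),
        "treat_all": dca.treat_all.tolist(),
        "treat_none": dca.treat_none.tolist(),
    }

    logger.info("stage=delong")
    for a, b in itertools.combinations(table.raters, 2):
        res = delong_test(
            table.positive_scores(a), table.positive_scores(b), labels
        )
        report.delong[f"{a}|{b}"] = {
            "auc_a": res.auc_a,
            "auc_b": res.auc_b,
            "delta": res.delta,
            "variance_delta": res.variance_delta,
            "z": res.z,
            "p": res.p,
            "reason": res.reason,
        }
    return report


def run_power(spec: PowerSpec) -> float:
    """Minimal detectable AUC difference for the given design."""
    delta = detectable_auc_difference(spec)
    logger.info(
        "power analysis method=%s n_pos=%d n_neg=%d r=%.3g alpha=%.3g power=%.3g "
        "baseline_auc=%.3g -> detectable_delta=%.4f",
        spec.method, spec.n_pos, spec.n_neg, spec.r, spec.alpha, spec.power,
        spec.baseline_auc, delta,
    )
    return delta


# ---------------------------------------------------------------------------
# CSV side-car exports
# ---------------------------------------------------------------------------

def export_report_csvs(report: MetricReport, table: AssessmentTable, out_dir) -> None:
    """Write plotting-friendly CSVs next to the JSON report: confusion
    matrices, ROC points, Bland–Altman pairs, calibration bins and decision
    curves."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rater, block in report.classification.items():
        cm = block["confusion_matrix"]
        with open(out / f"confusion_{rater}.csv", "w") as fh:
            fh.write("truth," + ",".join(cm["pred_codes"]) + "\n")
            for code, row in zip(cm["truth_codes"], cm["counts"]):
                fh.write(code + "," + ",".join(repr(v) for v in row) + "\n")
    for rater, block in report.discrimination.items():
        roc = block["roc"]
        with open(out / f"roc_{rater}.csv", "w") as fh:
            fh.write("threshold,fpr,tpr\n")
            for t, f, s in zip(roc["thresholds"], roc["fpr"], roc["tpr"]):
                fh.write(f"{t},{f!r},{s!r}\n")
        cal = block["calibration"]
        with open(out / f"calibration_{rater}.csv", "w") as fh:
            fh.write("mean_predicted,observed_fraction,count\n")
            for m, o, c in zip(
                cal["mean_predicted"], cal["observed_fraction"], cal["counts"]
            ):
                fh.write(f"{m!r},{o!r},{c}\n")
    thresholds = report.decision_reference["thresholds"]
    with open(out / "decision_curve.csv", "w") as fh:
        raters = list(report.discrimination)
        fh.write("threshold," + ",".join(raters) + ",treat_all,treat_none\n")
        for i, t in enumerate(thresholds):
            vals = [repr(report.discrimination[r]["net_benefit"][i]) for r in raters]
            fh.write(
                f"{t!r}," + ",".join(vals)
                + f",{report.decision_reference['treat_all'][i]!r},"
                + f"{report.decision_reference['treat_none'][i]!r}\n"
            )
    for pair in report.agreement:
        a, b = pair.split("|")
        x = table.positive_scores(a)
        y = table.positive_scores(b)
        ba = bland_altman(x, y)
        safe = pair.replace("|", "_vs_")
        with open(out / f"bland_altman_{safe}.csv", "w") as fh:
            fh.write("mean,difference\n")
            for m, d in zip(ba.means, ba.diffs):
                fh.write(f"{m!r},{d!r}\n")
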