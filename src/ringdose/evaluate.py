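"""Predictive-accuracy metrics and the plan-QA gate.

Model quality is summarized per split (train/val/test/all) by the regression
R value (Pearson correlation of predictions vs targets), the MSE, and the
mean +/- SD of the absolute ratio error |actual - predicted|; predicted and
planned ratios are compared by a paired t test (two-sided, alpha 0.05).  The
QA gate flags a plan when the predicted and planned D2cm3/D90 differ by more
than a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_QA_THRESHOLD = 0.10
QA_RECOMMENDATION = "plan should be further optimized"


def regression_metrics(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """(R, MSE) of predictions vs targets; R is NaN for a constant target."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1 or len(actual) < 2:
        raise ValueError("need two equal-length 1D vectors of length >= 2")
    mse = float(np.mean((predicted - actual) ** 2))
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        return float("nan"), mse
    r = float(stats.pearsonr(predicted, actual).statistic)
    return r, mse


def delta_stats(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD (n-1) of |actual - predicted|."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or len(actual) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = np.abs(actual - predicted)
    return float(d.mean()), float(d.std(ddof=1))


def paired_t_test(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test on (predicted - actual); fails if differences
    have zero variance (t undefined)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or len(actual) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = predicted - actual
    if np.ptp(diff) == 0:
        raise ValueError("paired t undefined: differences have zero variance")
    res = stats.ttest_rel(predicted, actual)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FitReport:
    """Per-split accuracy of one OAR's model, Table-3 style."""

    oar_label: str
    per_split: dict[str, dict] = field(default_factory=dict)  # split -> metrics
    t_stat: float = float("nan")
    p_value: float = float("nan")  # paired test over all sets

    def to_dict(self) -> dict:
        return {"oar": self.oar_label, "per_split": self.per_split,
                "t_stat": self.t_stat, "p_value": self.p_value}

    def to_text(self) -> str:
        lines = [f"OAR: {self.oar_label}"]
        hdr = f"{'set':<8}{'n':>5}{'R':>10}{'MSE':>12}{'delta mean':>12}{'delta SD':>10}"
        lines.append(hdr)
        for split, m in self.per_split.items():
            lines.append(
                f"{split:<8}{m['n']:>5}{m['r_value']:>10.4f}{m['mse']:>12.3e}"
                f"{m['delta_mean']:>12.4f}{m['delta_sd']:>10.4f}"
            )
        lines.append(f"paired t (all sets): t={self.t_stat:.3f}, p={self.p_value:.3f}")
        return "\n".join(lines)


def fit_report(oar_label: str, predicted: np.ndarray, actual: np.ndarray,
               split_labels: np.ndarray) -> FitReport:
    """Assemble R/MSE/delta per split plus the all-sets paired t test."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    split_labels = np.asarray(split_labels)
    report = FitReport(oar_label=oar_label)
    for split in ("train", "val", "test", "all"):
        sel = np.ones(len(actual), bool) if split == "all" else split_labels == split
        if sel.sum() < 2:
            continue
        r, mse = regression_metrics(predicted[sel], actual[sel])
        dmean, dsd = delta_stats(predicted[sel], actual[sel])
        report.per_split[split] = {"n": int(sel.sum()), "r_value": r, "mse": mse,
                                   "delta_mean": dmean, "delta_sd": dsd}
    try:
        report.t_stat, report.p_value = paired_t_test(predicted, actual)
    except ValueError:
        pass
    return report


def qa_check(predicted_ratio: float, planned_ratio: float,
             threshold: float = DEFAULT_QA_THRESHOLD) -> dict:
    """Flag a plan whose planned ratio strays from the prediction.

    The flag uses a strict inequality: |predicted - planned| must exceed the
    threshold; equality passes.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = abs(float(predicted_ratio) - float(planned_ratio))
    flagged = diff > threshold
    line = (f"predicted={predicted_ratio:.4f} planned={planned_ratio:.4f} "
            f"|diff|={diff:.4f} threshold={threshold:.4f}: "
            + (f"FLAGGED - {QA_RECOMMENDATION}" if flagged else "ok"))
    return {"flagged": flagged, "abs_difference": diff, "threshold": float(threshold),
            "report_line": line}


def qa_check_batch(predicted: dict[str, np.ndarray], planned: dict[str, np.ndarray],
                   threshold: float = DEFAULT_QA_THRESHOLD) -> list[dict]:
    """Per-plan QA over a cohort: one record per plan with per-OAR flags."""
    oars = sorted(predicted)
    n = len(next(iter(predicted.values())))
    out = []
    for i in range(n):
        rec = {"plan_index": i}
        for oar in oars:
            rec[oar] = qa_check(predicted[oar][i], planned[oar][i], threshold)
        rec["any_flagged"] = any(rec[o]["flagged"] for o in oars)
        out.append(rec)
    return out
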