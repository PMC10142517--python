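"""Per-plan feature/target assembly and Pearson correlation reporting.

The model's inputs per OAR are the 15 normalized sub-organ (ring) volumes
plus the HR-CTV volume; the target is D2cm3/D90.  The correlation report
relates each OAR's target to the HR-CTV volume, the OAR's own volume, and
every normalized ring volume, marking cells significant at the bilateral
0.01 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ringdose.grid import OAR_LABELS
from ringdose.rings import MAX_RINGS, SubOrganDecomposition

N_FEATURES_PER_OAR = MAX_RINGS + 1  # 15 rings + HR-CTV volume


def ring_columns(oar: str, n_rings: int = MAX_RINGS) -> list[str]:
    return [f"{oar}_ring{k:02d}" for k in range(1, n_rings + 1)]


def feature_columns(oar: str, include_oar_volume: bool = False) -> list[str]:
    cols = ring_columns(oar) + ["hrctv_volume_cc"]
    if include_oar_volume:
        cols.append(f"{oar}_volume_cc")
    return cols


def target_column(oar: str) -> str:
    return f"{oar}_target"


def cohort_columns() -> list[str]:
    """Documented cohort CSV schema, in canonical order."""
    cols = ["plan_id", "patient_id", "prescription_gy", "d90_gy", "n_needles",
            "hrctv_volume_cc"]
    for oar in OAR_LABELS:
        cols += [f"{oar}_volume_cc"] + ring_columns(oar) + [f"{oar}_d2cc_gy", target_column(oar)]
    return cols


def assemble_plan_record(
    decomps: dict[str, SubOrganDecomposition],
    metrics: dict,
    plan_id: int,
    patient_id: int,
    prescription_gy: float,
    d90_gy: float,
    n_needles: int = 0,
) -> dict:
    """Flatten one plan's decompositions and DVH metrics into a cohort row.

    Ring features are zero-padded to the fixed 15-slot layout so the network
    always sees the same input width.
    """
    missing = [o for o in OAR_LABELS if o not in decomps or o not in metrics]
    if missing:
        raise ValueError(f"missing decomposition/metrics for OAR(s): {missing}")
    hvols = {o: decomps[o].hrctv_volume_cc for o in OAR_LABELS}
    if max(hvols.values()) - min(hvols.values()) > 1e-9 * max(hvols.values()):
        raise ValueError(f"inconsistent HR-CTV volumes across decompositions: {hvols}")

    row: dict = {
        "plan_id": int(plan_id),
        "patient_id": int(patient_id),
        "prescription_gy": float(prescription_gy),
        "d90_gy": float(d90_gy),
        "n_needles": int(n_needles),
        "hrctv_volume_cc": float(next(iter(hvols.values()))),
    }
    for oar in OAR_LABELS:
        dec = decomps[oar]
        padded = np.zeros(MAX_RINGS)
        padded[: dec.n_rings] = dec.normalized_volumes
        row[f"{oar}_volume_cc"] = float(dec.oar_volume_cc)
        for k, col in enumerate(ring_columns(oar)):
            row[col] = float(padded[k])
        row[f"{oar}_d2cc_gy"] = float(metrics[oar].d2cc_gy)
        row[target_column(oar)] = float(metrics[oar].ratio)
    return row


def feature_matrix(cohort: pd.DataFrame, oar: str,
                   include_oar_volume: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for one OAR: ring volumes + HR-CTV volume vs D2cm3/D90."""
    cols = feature_columns(oar, include_oar_volume)
    X = cohort[cols].to_numpy(dtype=float)
    y = cohort[target_column(oar)].to_numpy(dtype=float)
    return X, y


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires two 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("pearson_r requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r is undefined for a constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationReport:
    """r / p / significance tables: targets (rows) x predictors (columns)."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # p < alpha, bilateral
    alpha: float = 0.01

    def to_text(self) -> str:
        marked = self.r.round(3).astype(str)
        marked = marked.where(~self.significant, marked + "*")
        marked = marked.mask(self.r.isna(), "-")
        return (f"Pearson r (* = significant at the bilateral {self.alpha} level)\n"
                + marked.to_string())


def correlation_report(cohort: pd.DataFrame, n_rings: int = MAX_RINGS,
                       alpha: float = 0.01) -> CorrelationReport:
    """Correlate each OAR's D2cm3/D90 with anatomy volumes and ring features.

    Cells where the correlation is undefined (constant predictor) are NaN.
    """
    if len(cohort) < 3:
        raise ValueError("correlation report requires >= 3 plans")
    rows_r, rows_p = [], []
    index = []
    for oar in OAR_LABELS:
        y = cohort[target_column(oar)].to_numpy(dtype=float)
        predictors = {"hrctv_volume_cc": cohort["hrctv_volume_cc"],
                      "oar_volume_cc": cohort[f"{oar}_volume_cc"]}
        for k in range(1, n_rings + 1):
            predictors[f"ring{k:02d}"] = cohort[f"{oar}_ring{k:02d}"]
        r_row, p_row = {}, {}
        for name, series in predictors.items():
            try:
                r_row[name], p_row[name] = pearson_r(series.to_numpy(dtype=float), y)
            except ValueError:
                r_row[name], p_row[name] = np.nan, np.nan
        rows_r.append(r_row)
        rows_p.append(p_row)
        index.append(f"d2cc_d90_{oar}")
    r = pd.DataFrame(rows_r, index=index)
    p = pd.DataFrame(rows_p, index=index)
    return CorrelationReport(r=r, p=p, significant=p < alpha, alpha=alpha)
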