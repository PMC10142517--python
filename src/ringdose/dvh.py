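"""Dose-volume-histogram metrics, EQD2 conversion, and plan-constraint audit.

D2cm3 is the minimum dose to the most-irradiated 2 cm3 of a structure; D90 is
the dose covering 90% of a structure.  Both are read off the cumulative DVH
with linear interpolation between voxel dose levels.  The prediction target
of the pipeline is the scale-free ratio D2cm3/D90, which cancels the overall
plan normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ringdose.grid import DoseGrid

# Per-course EQD2 limits (Gy): HR-CTV D90 coverage floor; OAR D2cm3 ceilings.
DEFAULT_CONSTRAINTS = {
    "hrctv_d90_min": 85.0,
    "bladder_d2cc_max": 90.0,
    "rectum_d2cc_max": 75.0,
    "sigmoid_d2cc_max": 75.0,
}

# Linear-quadratic alpha/beta (Gy): 10 for tumor target, 3 for late-responding OARs.
DEFAULT_ALPHA_BETA = {"hrctv": 10.0, "bladder": 3.0, "rectum": 3.0, "sigmoid": 3.0}


@dataclass
class DvhMetrics:
    d2cc_gy: float
    d90_gy: float
    ratio: float  # d2cc of the OAR over d90 of the paired target


def dose_at_absolute_volume(dose: DoseGrid, mask: np.ndarray, v_cc: float) -> float:
    """Largest dose level D such that >= ``v_cc`` of the mask receives >= D.

    Computed by sorting masked voxel doses in descending order and
    interpolating linearly in cumulative volume: after i voxels the cumulative
    volume is i * voxel_volume, so the curve passes through
    (i * vv, d_i) and D(v_cc) is read off it.  Volumes below one voxel clamp
    to the hottest voxel's dose; v_cc equal to the mask volume returns the
    minimum masked dose.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match dose grid {dose.grid.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    vv = dose.grid.voxel_volume_cc
    total = n * vv
    if not 0 < v_cc <= total * (1 + 1e-12):
        raise ValueError(f"v_cc={v_cc} outside (0, mask volume={total:.6g}] cm3")

    d = np.sort(dose.dose_gy[mask])[::-1]
    cum = vv * np.arange(1, n + 1)
    # np.interp needs increasing x with increasing y; negate doses instead.
    return float(-np.interp(min(v_cc, total), cum, -d))


def dose_at_volume_fraction(dose: DoseGrid, mask: np.ndarray, fraction: float) -> float:
    """Dose covering ``fraction`` of the mask volume (D90 uses fraction=0.9)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    mask = np.asarray(mask, dtype=bool)
    v_cc = fraction * float(mask.sum()) * dose.grid.voxel_volume_cc
    return dose_at_absolute_volume(dose, mask, v_cc)


def dvh_metrics(dose: DoseGrid, oar_mask: np.ndarray, hrctv_mask: np.ndarray,
                v_cc: float = 2.0, coverage_fraction: float = 0.9) -> DvhMetrics:
    """D2cm3 of the OAR, D90 of the HR-CTV, and their ratio."""
    d2cc = dose_at_absolute_volume(dose, oar_mask, v_cc)
    d90 = dose_at_volume_fraction(dose, hrctv_mask, coverage_fraction)
    return DvhMetrics(d2cc_gy=d2cc, d90_gy=d90, ratio=d2cc / d90)


def eqd2(total_dose_gy: float, dose_per_fraction_gy: float, alpha_beta_gy: float) -> float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    EQD2 = total * (d + alpha/beta) / (2 + alpha/beta) with d the dose per
    fraction.
    """
    if total_dose_gy <= 0 or dose_per_fraction_gy <= 0 or alpha_beta_gy <= 0:
        raise ValueError("eqd2 arguments must all be positive")
    return total_dose_gy * (dose_per_fraction_gy + alpha_beta_gy) / (2.0 + alpha_beta_gy)


def check_plan_constraints(
    hrctv_d90_eqd2: float,
    bladder_d2cc_eqd2: float,
    rectum_d2cc_eqd2: float,
    sigmoid_d2cc_eqd2: float,
    limits: dict[str, float] | None = None,
) -> dict[str, dict]:
    """Audit EQD2 values against the clinical goals (limits inclusive).

    Pass requires HR-CTV D90 >= 85 Gy and bladder/rectum/sigmoid D2cm3 at or
    below 90/75/75 Gy EQD2 by default.  Always returns a report; never raises.
    """
    lim = dict(DEFAULT_CONSTRAINTS)
    if limits:
        lim.update(limits)
    values = {
        "hrctv": (hrctv_d90_eqd2, lim["hrctv_d90_min"], "ge"),
        "bladder": (bladder_d2cc_eqd2, lim["bladder_d2cc_max"], "le"),
        "rectum": (rectum_d2cc_eqd2, lim["rectum_d2cc_max"], "le"),
        "sigmoid": (sigmoid_d2cc_eqd2, lim["sigmoid_d2cc_max"], "le"),
    }
    report = {}
    for name, (val, limit, sense) in values.items():
        ok = val >= limit if sense == "ge" else val <= limit
        report[name] = {"value_eqd2_gy": float(val), "limit_eqd2_gy": float(limit),
                        "sense": sense, "pass": bool(ok)}
    report["all_pass"] = all(report[n]["pass"] for n in values)
    return report
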