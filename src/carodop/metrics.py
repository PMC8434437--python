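"""Evaluation statistics for segmentation and velocity experiments.

Segmentation accuracy is the Euclidean distance De between the automatically
located and the reference lumen centre; experiments with De above a discard
threshold (default 1 mm) are counted as failed and excluded.  Campaign
summaries report the per-series minimum/maximum/mean and the r.m.s.

    ELPT = sqrt( (1/N) sum De_i^2 )

Velocity accuracy is the signed relative error Err% = 100 (VM - VR)/VR
against the reference velocity, and repeatability is the coefficient of
variation CV% = 100 std(VM)/mean(VM) across repeated measurements
(sample standard deviation, N-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvaluationRecord:
    """One experiment: measured vs reference centre, plus optional velocity."""

    CM: tuple[float, float]          # measured centre (x, y), mm
    CR: tuple[float, float]          # reference centre (x, y), mm
    VM: float = np.nan               # measured peak velocity (same units as VR)
    experiment_id: str = ""
    discarded: bool = False

    @property
    def De(self) -> float:
        return distance_error(self.CM, self.CR)


@dataclass
class SummaryStats:
    """Per-series summary mirroring the evaluation tables."""

    N: int
    min_De: float
    max_De: float
    mean_De: float
    ELPT: float                       # r.m.s. centre error, mm
    n_discarded: int
    VR: float = np.nan
    mean_peak: float = np.nan
    Err_pct: float = np.nan
    CV_pct: float = np.nan
    std: float = np.nan


def distance_error(CM, CR) -> float:
    """Euclidean distance (mm) between measured and reference centres."""
    return math.hypot(CM[0] - CR[0], CM[1] - CR[1])


def rms_error(De_list) -> float:
    """Root-mean-square of a list of centre distances (mm)."""
    d = np.asarray(De_list, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    return float(np.sqrt(np.mean(d**2)))


def relative_error_pct(VM: float, VR: float) -> float:
    """Signed relative error in percent: 100 (VM - VR) / VR."""
    if VR == 0:
        raise ValueError("reference velocity must be nonzero")
    return 100.0 * (VM - VR) / VR


def cv_pct(VM_list) -> float:
    """Coefficient of variation in percent: 100 std(VM)/mean(VM).

    Sample standard deviation (N-1).  Requires >= 2 values and nonzero mean.
    """
    v = np.asarray(VM_list, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def evaluate_campaign(
    records: list[EvaluationRecord],
    VR: float = np.nan,
    discard_threshold_mm: float = 1.0,
) -> SummaryStats:
    """Apply the distance discard rule, then summarize a series of experiments.

    Centre statistics (mean, ELPT) are computed over the survivors of the
    discard rule; velocity statistics (mean peak, Err%, CV%) over survivors
    with a defined measured velocity.  CV% is NaN with fewer than 2 values.
    """
    if not records:
        raise ValueError("no records")
    for rec in records:
        rec.discarded = rec.De > discard_threshold_mm
    kept = [r for r in records if not r.discarded]
    if not kept:
        raise ValueError("all records discarded")
    De = np.array([r.De for r in kept])

    vm = np.array([r.VM for r in kept if np.isfinite(r.VM)])
    mean_peak = float(vm.mean()) if vm.size else np.nan
    err = relative_error_pct(mean_peak, VR) if vm.size and np.isfinite(VR) else np.nan
    cv = cv_pct(vm) if vm.size >= 2 and vm.mean() != 0 else np.nan
    std = float(vm.std(ddof=1)) if vm.size >= 2 else np.nan

    return SummaryStats(
        N=len(kept),
        min_De=float(De.min()), max_De=float(De.max()),
        mean_De=float(De.mean()), ELPT=rms_error(De),
        n_discarded=len(records) - len(kept),
        VR=VR, mean_peak=mean_peak, Err_pct=err, CV_pct=cv, std=std,
    )


def summary_frame(series_stats: dict[str, SummaryStats]) -> pd.DataFrame:
    """Tabulate per-series summaries (rows) in evaluation-table shape."""
    rows = []
    for name, s in series_stats.items():
        rows.append({
            "Series": name,
            "Min (mm)": s.min_De, "Max (mm)": s.max_De,
            "Mean (mm)": s.mean_De, "r.m.s. (mm)": s.ELPT,
            "Mean Peak": s.mean_peak, "Err%": s.Err_pct,
            "CV%": s.CV_pct, "Discarded": s.n_discarded,
        })
    return pd.DataFrame(rows)
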