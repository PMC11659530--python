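"""Whole-tumor ROI aggregation and inter-observer agreement.

Parameter maps are computed on the same grid the ROI was drawn on, so ROI
"transfer" is the identity; aggregation is a per-parameter mean (optionally
median) over the ROI minus any exclusion mask (e.g. the necrotic core) and
minus fit failures.  Observer agreement is quantified with the two-way
random-effects, absolute-agreement, single-measurement intraclass
correlation coefficient, ICC(2,1), from the two-way ANOVA mean squares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_models import ParameterMapSet

__all__ = ["LesionMeasurement", "IccResult", "aggregate_roi", "compute_icc",
           "average_observers", "measurements_to_frame"]


@dataclass
class LesionMeasurement:
    patient_id: str
    observer_id: str
    values: dict                 # parameter name -> scalar
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass
class IccResult:
    parameter: str
    icc: float
    var_patient: float
    var_observer: float
    var_residual: float
    defined: bool = True


def aggregate_roi(maps: ParameterMapSet, roi, exclusion=None,
                  patient_id="", observer_id="", statistic="mean") -> LesionMeasurement:
    """Per-parameter summary over (ROI minus exclusion minus fit failures)."""
    roi = np.asarray(roi, dtype=bool)
    eff = roi & maps.fitted_mask
    if exclusion is not None:
        eff &= ~np.asarray(exclusion, dtype=bool)
    n = int(eff.sum())
    if n == 0:
        raise ValueError("effective ROI is empty after exclusions")
    reducer = {"mean": np.mean, "median": np.median}[statistic]
    values = {name: float(reducer(m[eff])) for name, m in maps.maps.items()}
    return LesionMeasurement(patient_id=patient_id, observer_id=observer_id,
                             values=values, n_voxels=n)


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Long-format frame: one row per patient x observer."""
    rows = []
    for m in measurements:
        row = {"patient_id": m.patient_id, "observer_id": m.observer_id,
               "n_voxels": m.n_voxels}
        row.update(m.values)
        rows.append(row)
    return pd.DataFrame(rows)


def _icc_table(measurements, parameter) -> np.ndarray:
    df = measurements if isinstance(measurements, pd.DataFrame) \
        else measurements_to_frame(measurements)
    wide = df.pivot(index="patient_id", columns="observer_id",
                    values=parameter)
    if wide.shape[1] != 2:
        raise ValueError("exactly two observers are required")
    if wide.isna().any().any():
        raise ValueError("missing cells in the patient x observer table")
    if wide.shape[0] < 3:
        raise ValueError("at least 3 patients are required")
    return wide.to_numpy(dtype=float)


def compute_icc(measurements, parameter: str) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA decomposition with n patients and k observers:

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    Variance components (patient, observer, residual) are reported with
    negative estimates truncated at zero.  A table with zero total variance
    has no defined ICC and is flagged.
    """
    data = _icc_table(measurements, parameter)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if sst <= 0 or denom <= 0:
        return IccResult(parameter, np.nan, 0.0, 0.0, 0.0, defined=False)
    icc = (msr - mse) / denom
    var_patient = max((msr - mse) / k, 0.0)
    var_observer = max((msc - mse) / n, 0.0)
    var_residual = max(mse, 0.0)
    return IccResult(parameter, float(icc), var_patient, var_observer,
                     var_residual)


def average_observers(measurements) -> list:
    """Arithmetic per-parameter mean of the two observers for each patient."""
    df = measurements_to_frame(measurements) \
        if not isinstance(measurements, pd.DataFrame) else measurements
    out = []
    for pid, sub in df.groupby("patient_id", sort=False):
        if sub["observer_id"].nunique() < 2:
            raise ValueError(f"patient {pid} is missing an observer")
        params = [c for c in sub.columns
                  if c not in ("patient_id", "observer_id", "n_voxels")]
        values = {p: float(sub[p].mean()) for p in params}
        out.append(LesionMeasurement(patient_id=pid, observer_id="average",
                                     values=values,
                                     n_voxels=int(sub["n_voxels"].mean())))
    return out
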