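"""End-to-end orchestration: simulate -> fit -> ROI -> statistics.

In-memory entry points (used by the library, the CLI and the examples):

* :func:`simulate_imaging_cohort` — phantoms for each eligible patient;
* :func:`fit_and_measure` — parameter maps + per-observer ROI measurements;
* :func:`observer_agreement_study` — the two-observer ICC experiment;
* :func:`imaging_cohort_table` — full image-based cohort table;
* :func:`run_study` — everything, returning the statistics bundle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (apply_eligibility_filter, generate_screening_roster)
from .phantom import LesionPhantom, generate_lesion_phantom
from .roi import (aggregate_roi, average_observers, compute_icc,
                  measurements_to_frame)
from .signal_models import DwiSeries, fit_volume
from .stats import run_full_analysis

__all__ = ["simulate_imaging_cohort", "fit_and_measure",
           "observer_agreement_study", "imaging_cohort_table", "run_study"]

_PARAMS = ("adc", "d_app", "k_app", "f1", "f2", "f3")


def _child_seeds(seed, n):
    # independent per-patient streams below 2**31
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def simulate_imaging_cohort(n_positive, n_negative, seed=0,
                            grid_shape=(16, 16, 8), snr_at_b0=50.0,
                            noiseless=False):
    """Generate one lesion phantom per patient; returns (ids, groups, phantoms)."""
    groups = ["positive"] * n_positive + ["negative"] * n_negative
    seeds = _child_seeds(seed, len(groups))
    phantoms = [generate_lesion_phantom(g, grid_shape=grid_shape,
                                        seed=int(s), snr_at_b0=snr_at_b0,
                                        noiseless=noiseless)
                for g, s in zip(groups, seeds)]
    ids = [f"P{i + 1:03d}" for i in range(len(groups))]
    return ids, groups, phantoms


def fit_and_measure(patient_id: str, phantom: LesionPhantom,
                    exclude_necrosis=True, nex_weighted=False):
    """Fit all three models over the union of both observers' ROIs and
    aggregate per observer; returns (maps, [measurement_obs1, measurement_obs2])."""
    dwi = DwiSeries(phantom.dwi, phantom.scheme)
    union = phantom.roi_observer1 | phantom.roi_observer2
    maps = fit_volume(dwi, union, models="all", nex_weighted=nex_weighted)
    exclusion = phantom.necrosis_mask if exclude_necrosis else None
    out = []
    for obs, roi in (("obs1", phantom.roi_observer1),
                     ("obs2", phantom.roi_observer2)):
        out.append(aggregate_roi(maps, roi, exclusion=exclusion,
                                 patient_id=patient_id, observer_id=obs))
    return maps, out


def observer_agreement_study(n_patients=30, seed=0, grid_shape=(16, 16, 8),
                             snr_at_b0=50.0):
    """Two-observer agreement experiment.

    Simulates a balanced cohort of lesion phantoms, fits every model, and
    computes the ICC(2,1) between the two observers' whole-tumor means for
    each of the six parameters.  Returns (icc_by_parameter, measurements
    frame).
    """
    n_pos = n_patients // 2
    ids, groups, phantoms = simulate_imaging_cohort(
        n_pos, n_patients - n_pos, seed=seed, grid_shape=grid_shape,
        snr_at_b0=snr_at_b0)
    measurements = []
    for pid, ph in zip(ids, phantoms):
        _, pair = fit_and_measure(pid, ph)
        measurements.extend(pair)
    frame = measurements_to_frame(measurements)
    icc = {p: compute_icc(frame, p).icc for p in _PARAMS}
    return icc, frame


def imaging_cohort_table(n_positive, n_negative, seed=0,
                         grid_shape=(16, 16, 8), snr_at_b0=50.0) -> pd.DataFrame:
    """Image-based cohort table: simulate phantoms, fit, aggregate both
    observers and average them; clinical covariates drawn per group."""
    from .cohort import _draw_covariates  # covariates share the group laws

    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    ids, groups, phantoms = simulate_imaging_cohort(
        n_positive, n_negative, seed=seed, grid_shape=grid_shape,
        snr_at_b0=snr_at_b0)
    measurements = []
    for pid, ph in zip(ids, phantoms):
        _, pair = fit_and_measure(pid, ph)
        measurements.extend(pair)
    averaged = average_observers(measurements)
    rows = []
    for pid, group, m in zip(ids, groups, averaged):
        cov = _draw_covariates(rng, group, 1).iloc[0]
        row = {"patient_id": pid, "age": float(cov["age"]),
               "sex": str(cov["sex"]),
               "max_diameter": float(cov["max_diameter"]),
               "cea": float(cov["cea"]),
               "lnm": 1 if group == "positive" else 0}
        for p in _PARAMS:
            val = m.values[p]
            # report diffusivities in 1e-3 mm^2/s, matching clinical tables
            row[p] = val * 1e3 if p in ("adc", "d_app") else val
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    roster: list
    eligible: list
    cohort: pd.DataFrame
    icc: dict
    report: dict


def run_study(seed=0, n_total=100, exclusion_counts=None,
              grid_shape=(16, 16, 8), snr_at_b0=50.0) -> StudyResult:
    """Screening -> eligibility -> imaging -> ROI -> statistics, end to end."""
    roster = generate_screening_roster(n_total=n_total,
                                       exclusion_counts=exclusion_counts,
                                       seed=seed)
    eligible = apply_eligibility_filter(roster)
    n_pos = sum(1 for r in eligible if r.lnm_label == "positive")
    n_neg = len(eligible) - n_pos
    cohort = imaging_cohort_table(n_pos, n_neg, seed=seed,
                                  grid_shape=grid_shape, snr_at_b0=snr_at_b0)
    icc, _ = observer_agreement_study(n_patients=min(30, len(eligible)),
                                      seed=seed, grid_shape=grid_shape,
                                      snr_at_b0=snr_at_b0)
    report = run_full_analysis(cohort)
    return StudyResult(roster=roster, eligible=eligible, cohort=cohort,
                       icc=icc, report=report)
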