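"""Screening roster, eligibility filtering, and cohort-table simulation.

The screening roster emulates a single-center enrolment stream: ``n_total``
consecutive patients of whom a configurable number fall into each of five
mutually exclusive exclusion categories (non-rectal pathology, inconclusive
pathology, scan-to-biopsy interval over two weeks, incomplete/poor-quality
MRI, prior treatment); the remainder are eligible and carry a binary
lymph-node-metastasis (LNM) label.

``generate_cohort_table`` draws per-patient diffusion parameters directly
from the group-level distributions (normal for ADC/D_app/K_app, calibrated
Dirichlet for the compartment fractions, log-normal CEA), bypassing the
imaging stage; it is the fast substrate for the statistics pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .phantom import group_fraction_alphas

__all__ = [
    "PatientRecord",
    "EXCLUSION_CATEGORIES",
    "DEFAULT_EXCLUSION_COUNTS",
    "GroupDistribution",
    "GROUP_DISTRIBUTIONS",
    "generate_screening_roster",
    "apply_eligibility_filter",
    "generate_cohort_table",
    "COHORT_COLUMNS",
]

EXCLUSION_CATEGORIES = (
    "non_rectal",
    "inconclusive_pathology",
    "interval_gt_2w",
    "incomplete_mri",
    "prior_treatment",
)

# default screening stream: 100 scanned, 23 excluded, 77 enrolled (31 LNM+)
DEFAULT_EXCLUSION_COUNTS = {
    "non_rectal": 5,
    "inconclusive_pathology": 4,
    "interval_gt_2w": 3,
    "incomplete_mri": 6,
    "prior_treatment": 5,
}
DEFAULT_N_TOTAL = 100
DEFAULT_N_POSITIVE = 31
DEFAULT_N_NEGATIVE = 46


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str                      # "male" | "female"
    max_diameter: float           # cm
    cea: float                    # ng/mL
    lnm_label: Optional[str]      # "positive" | "negative" | None if excluded
    exclusion_flag: str = "none"

    def __post_init__(self):
        if self.exclusion_flag not in ("none",) + EXCLUSION_CATEGORIES:
            raise ValueError(f"unknown exclusion flag: {self.exclusion_flag}")
        if self.exclusion_flag == "none" and self.lnm_label not in (
                "positive", "negative"):
            raise ValueError("eligible records need a binary LNM label")
        if self.exclusion_flag != "none" and self.lnm_label is not None:
            raise ValueError("LNM label is defined only for eligible records")


def _lognormal_from_median_iqr(median, q1, q3):
    """(mu, sigma) of a log-normal with the given median and quartiles."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2 * 1.3489795003921634)
    return mu, sigma


@dataclass(frozen=True)
class GroupDistribution:
    """Per-group generative distributions for clinical covariates and
    whole-tumor diffusion parameters (diffusivities in 1e-3 mm^2/s)."""

    age_mean: float
    age_sd: float
    diameter_mean: float
    diameter_sd: float
    cea_median: float
    cea_q1: float
    cea_q3: float
    male_fraction: float
    adc_mean: float
    adc_sd: float
    d_app_mean: float
    d_app_sd: float
    k_app_mean: float
    k_app_sd: float

    @property
    def cea_mu_sigma(self):
        return _lognormal_from_median_iqr(self.cea_median, self.cea_q1,
                                          self.cea_q3)


GROUP_DISTRIBUTIONS = {
    "positive": GroupDistribution(
        age_mean=63.54, age_sd=10.03, diameter_mean=4.24, diameter_sd=1.39,
        cea_median=4.08, cea_q1=1.84, cea_q3=13.35, male_fraction=0.5161,
        adc_mean=1.09, adc_sd=0.29, d_app_mean=1.04, d_app_sd=0.44,
        k_app_mean=0.77, k_app_sd=0.27),
    "negative": GroupDistribution(
        age_mean=60.68, age_sd=10.85, diameter_mean=3.83, diameter_sd=1.26,
        cea_median=2.68, cea_q1=1.21, cea_q3=6.02, male_fraction=0.6957,
        adc_mean=1.57, adc_sd=0.62, d_app_mean=1.85, d_app_sd=0.07,
        k_app_mean=0.49, k_app_sd=0.18),
}


def _truncated_normal(rng, mean, sd, size, lower=1e-3):
    """Normal draws redrawn until positive (truncation mass is tiny for all
    parameters used here)."""
    x = rng.normal(mean, sd, size)
    bad = x <= lower
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= lower
    return x


def _draw_covariates(rng, group: str, n: int) -> pd.DataFrame:
    g = GROUP_DISTRIBUTIONS[group]
    mu, sigma = g.cea_mu_sigma
    return pd.DataFrame({
        "age": rng.normal(g.age_mean, g.age_sd, n),
        "sex": np.where(rng.random(n) < g.male_fraction, "male", "female"),
        "max_diameter": _truncated_normal(rng, g.diameter_mean, g.diameter_sd, n,
                                          lower=0.3),
        "cea": np.exp(rng.normal(mu, sigma, n)),
    })


def generate_screening_roster(n_total=DEFAULT_N_TOTAL, exclusion_counts=None,
                              seed=0, n_positive=None):
    """Generate ``n_total`` screening records with exactly the requested
    number per exclusion category; the rest are eligible and labelled.

    ``n_positive`` (default: the 31/77 enrolment proportion, rounded) sets
    the LNM-positive count among eligible records.
    """
    if exclusion_counts is None:
        exclusion_counts = dict(DEFAULT_EXCLUSION_COUNTS)
    unknown = set(exclusion_counts) - set(EXCLUSION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
    counts = {c: int(exclusion_counts.get(c, 0)) for c in EXCLUSION_CATEGORIES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("exclusion counts must be non-negative")
    n_excluded = sum(counts.values())
    if n_excluded > n_total:
        raise ValueError("exclusion counts exceed roster size")
    n_eligible = n_total - n_excluded
    if n_positive is None:
        n_positive = int(round(n_eligible * DEFAULT_N_POSITIVE /
                               (DEFAULT_N_POSITIVE + DEFAULT_N_NEGATIVE)))
    if n_positive > n_eligible:
        raise ValueError("n_positive exceeds the number of eligible records")

    rng = np.random.default_rng(seed)
    flags = []
    for cat in EXCLUSION_CATEGORIES:
        flags.extend([cat] * counts[cat])
    labels = ["positive"] * n_positive + ["negative"] * (n_eligible - n_positive)
    flags.extend(["none"] * n_eligible)
    order = rng.permutation(len(flags))

    # covariates for excluded records come from the pooled (unlabelled) mix
    roster = []
    label_iter = iter(labels)
    assigned = []
    for pos in order:
        flag = flags[pos]
        label = next(label_iter) if flag == "none" else None
        assigned.append((flag, label))
    for i, (flag, label) in enumerate(assigned):
        group = label if label is not None else (
            "positive" if rng.random() < 0.4 else "negative")
        cov = _draw_covariates(rng, group, 1).iloc[0]
        roster.append(PatientRecord(
            patient_id=f"P{i + 1:03d}", age=float(cov["age"]),
            sex=str(cov["sex"]), max_diameter=float(cov["max_diameter"]),
            cea=float(cov["cea"]), lnm_label=label, exclusion_flag=flag))
    return roster


def apply_eligibility_filter(roster):
    """Records with no exclusion flag, in roster order."""
    return [r for r in roster if r.exclusion_flag == "none"]


COHORT_COLUMNS = ("patient_id", "age", "sex", "max_diameter", "cea",
                  "adc", "d_app", "k_app", "f1", "f2", "f3", "lnm")


def generate_cohort_table(n_positive=DEFAULT_N_POSITIVE,
                          n_negative=DEFAULT_N_NEGATIVE, seed=0) -> pd.DataFrame:
    """Simulate a per-patient cohort table directly from the group-level
    parameter distributions (no imaging stage).

    Columns: clinical covariates, whole-tumor ADC / D_app / K_app
    (1e-3 mm^2/s for the diffusivities), compartment fractions f1..f3 and
    the binary LNM label (1 = positive).
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for group, n in (("positive", n_positive), ("negative", n_negative)):
        if n == 0:
            continue
        g = GROUP_DISTRIBUTIONS[group]
        df = _draw_covariates(rng, group, n)
        df["adc"] = _truncated_normal(rng, g.adc_mean, g.adc_sd, n)
        df["d_app"] = _truncated_normal(rng, g.d_app_mean, g.d_app_sd, n)
        df["k_app"] = _truncated_normal(rng, g.k_app_mean, g.k_app_sd, n)
        f = rng.dirichlet(np.asarray(group_fraction_alphas(group)), size=n)
        df["f1"], df["f2"], df["f3"] = f[:, 0], f[:, 1], f[:, 2]
        df["lnm"] = 1 if group == "positive" else 0
        df.insert(0, "patient_id",
                  [f"S{offset + i + 1:04d}" for i in range(n)])
        offset += n
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[list(COHORT_COLUMNS)]
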