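"""Cohort statistics: group comparisons, logistic regression, ROC, DeLong.

The pipeline mirrors a standard radiology biomarker workup on a two-group
cohort (binary lymph-node-metastasis label):

* per-variable group comparison with a normality gate (Shapiro-Wilk per
  group at alpha = 0.05): both groups normal -> independent-samples t-test,
  otherwise Mann-Whitney U; categorical variables -> chi-square with an
  expected-count guard (Fisher fallback);
* univariate then multivariate logistic regression, continuous predictors
  standardized to unit whole-sample SD so odds ratios are per 1 SD;
  variables with univariate p < 0.1 enter the joint model, no stepwise
  elimination;
* empirical ROC (pairwise counting with half credit for ties, identical to
  the Mann-Whitney U statistic scaled by 1/(n1*n2)), DeLong variance for
  the CI, Youden-maximizing cutoff;
* DeLong's test for paired AUC differences via structural components;
* composite markers realized as in-sample logistic scores over a variable
  list (e.g. the two kurtosis parameters, or the restricted + free-water
  fractions).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupComparisonResult", "LogisticResult", "RocResult", "DeLongResult",
    "compare_groups", "univariate_lr", "multivariate_lr", "roc_analysis",
    "combined_model", "delong_test", "run_full_analysis",
    "DIFFUSION_PARAMETERS", "CLINICAL_VARIABLES",
]

DIFFUSION_PARAMETERS = ("f1", "f2", "f3", "d_app", "k_app", "adc")
CLINICAL_VARIABLES = ("age", "sex", "max_diameter", "cea")
_SEPARATION_COEF = 15.0


# ------------------------------------------------------------------ helpers

def _split_groups(cohort: pd.DataFrame, variable: str, outcome: str):
    y = _binary_outcome(cohort[outcome])
    v = cohort[variable]
    return v[y == 1], v[y == 0], y


def _binary_outcome(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        y = (col.astype(str).str.lower() == "positive").astype(int)
    else:
        y = col.astype(int)
    vals = set(np.unique(y))
    if not vals <= {0, 1} or len(vals) < 2:
        raise ValueError("outcome must contain both classes, coded binary")
    return np.asarray(y)


def _is_categorical(series: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(series) or \
        pd.api.types.is_bool_dtype(series)


# ------------------------------------------------------- group comparisons

@dataclass
class GroupComparisonResult:
    variable: str
    test: str                    # t | mann_whitney | chi_square | fisher
    statistic: float
    p_value: float
    summary_positive: str
    summary_negative: str
    shapiro_p: tuple = (np.nan, np.nan)


def _mean_sd(x):
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def _median_iqr(x):
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def compare_groups(cohort: pd.DataFrame, variable: str, outcome: str = "lnm",
                   alpha: float = 0.05, force: Optional[str] = None
                   ) -> GroupComparisonResult:
    """Compare one variable between the outcome groups.

    Test choice follows the variable's distributional properties:
    categorical -> chi-square (Fisher when any expected count < 5);
    continuous -> Shapiro-Wilk per group at ``alpha``; both normal ->
    independent-samples t-test, otherwise two-sided Mann-Whitney U (exact
    when sample sizes permit, tie-corrected normal approximation otherwise).
    ``force`` overrides the gate with "t", "mann_whitney" or "chi_square".
    """
    pos, neg, y = _split_groups(cohort, variable, outcome)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")

    if force == "chi_square" or (force is None and
                                 _is_categorical(cohort[variable])):
        table = pd.crosstab(cohort[variable], y).to_numpy()
        chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
        test = "chi_square"
        if force is None and (expected < 5).any():
            if table.shape == (2, 2):
                _, p = sps.fisher_exact(table)
                chi2 = np.nan
                test = "fisher"
        def counts(series):
            vc = series.value_counts()
            return ", ".join(f"{k}: {v}" for k, v in vc.items())
        return GroupComparisonResult(variable, test, float(chi2), float(p),
                                     counts(pos), counts(neg))

    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if np.std(np.concatenate([pos, neg])) == 0:
        raise ValueError(f"variable {variable!r} is constant")

    sh_p = (np.nan, np.nan)
    if force is None:
        if min(len(pos), len(neg)) < 3:
            raise ValueError("need >= 3 per group for the normality gate")
        sh_p = (sps.shapiro(pos).pvalue, sps.shapiro(neg).pvalue)
        use_t = sh_p[0] >= alpha and sh_p[1] >= alpha
    else:
        use_t = force == "t"

    if use_t:
        stat, p = sps.ttest_ind(pos, neg, equal_var=True)
        return GroupComparisonResult(variable, "t", float(stat), float(p),
                                     _mean_sd(pos), _mean_sd(neg), sh_p)
    stat, p = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                               method="auto")
    return GroupComparisonResult(variable, "mann_whitney", float(stat),
                                 float(p), _median_iqr(pos), _median_iqr(neg),
                                 sh_p)


# --------------------------------------------------------------- logistic

@dataclass
class LogisticResult:
    variables: tuple
    table: pd.DataFrame          # rows per variable: or_, ci_low, ci_high, p, coef
    converged: bool = True
    separation: bool = False
    collinear: bool = False


def _design(cohort: pd.DataFrame, variables: Sequence[str]):
    """Numeric design matrix; continuous columns standardized to unit
    whole-sample SD (sample SD, ddof=1); binary columns encoded 0/1 as-is."""
    cols = {}
    for v in variables:
        s = cohort[v]
        if _is_categorical(s):
            levels = sorted(s.astype(str).unique())
            if len(levels) != 2:
                raise ValueError(f"categorical predictor {v!r} must be binary")
            cols[v] = (s.astype(str) == levels[-1]).astype(float).to_numpy()
        else:
            x = s.to_numpy(dtype=float)
            sd = np.std(x, ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {v!r} is constant")
            cols[v] = (x - x.mean()) / sd
    return pd.DataFrame(cols)


def _fit_logit(y, X: pd.DataFrame) -> LogisticResult:
    variables = tuple(X.columns)
    exog = sm.add_constant(X.to_numpy(), has_constant="add")
    cond = np.linalg.cond(exog)
    if cond > 1e8:
        return LogisticResult(variables, pd.DataFrame(), converged=False,
                              collinear=True)
    try:
        # separation/non-convergence is detected and flagged below;
        # statsmodels' warnings about it are redundant here
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(np.asarray(y), exog).fit(disp=0, maxiter=200)
    except Exception:
        return LogisticResult(variables, pd.DataFrame(), converged=False,
                              separation=True)
    coefs = res.params[1:]
    if np.any(np.abs(coefs) > _SEPARATION_COEF):
        return LogisticResult(variables, pd.DataFrame(), converged=False,
                              separation=True)
    se = np.sqrt(np.diag(res.cov_params()))[1:]
    z = sps.norm.ppf(0.975)
    table = pd.DataFrame({
        "coef": coefs,
        "or_": np.exp(coefs),
        "ci_low": np.exp(coefs - z * se),
        "ci_high": np.exp(coefs + z * se),
        "p": res.pvalues[1:],
    }, index=list(variables))
    return LogisticResult(variables, table,
                          converged=bool(res.mle_retvals.get("converged", True)))


def univariate_lr(cohort: pd.DataFrame, variable: str,
                  outcome: str = "lnm") -> LogisticResult:
    """Single-predictor logistic model; OR per 1 SD for continuous
    predictors (whole-sample SD)."""
    y = _binary_outcome(cohort[outcome])
    return _fit_logit(y, _design(cohort, [variable]))


def multivariate_lr(cohort: pd.DataFrame, variables: Optional[Sequence[str]] = None,
                    candidates: Optional[Sequence[str]] = None,
                    outcome: str = "lnm", threshold: float = 0.1
                    ) -> LogisticResult:
    """Joint logistic model; if ``variables`` is not given, candidates with
    univariate p < ``threshold`` enter (no stepwise elimination)."""
    if variables is None:
        if candidates is None:
            candidates = [c for c in CLINICAL_VARIABLES + DIFFUSION_PARAMETERS
                          if c in cohort.columns]
        selected = []
        for v in candidates:
            uni = univariate_lr(cohort, v, outcome=outcome)
            if uni.converged and not uni.table.empty and \
                    float(uni.table["p"].iloc[0]) < threshold:
                selected.append(v)
        variables = selected
    if len(variables) == 0:
        raise ValueError("no variables selected for the multivariate model")
    y = _binary_outcome(cohort[outcome])
    return _fit_logit(y, _design(cohort, list(variables)))


# -------------------------------------------------------------------- ROC

@dataclass
class RocResult:
    marker: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str = ">"
    cutoff_scale: str = "marker"   # "probability" for composite models
    n_positive: int = 0
    n_negative: int = 0


def _auc_components(pos: np.ndarray, neg: np.ndarray):
    """Pairwise-counting AUC with half credit for ties, plus the DeLong
    structural components (per-positive and per-negative placements)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def _delong_variance(v10, v01):
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _marker_values(cohort, marker, outcome):
    if isinstance(marker, str):
        values = cohort[marker].to_numpy(dtype=float)
        name = marker
    else:
        values = np.asarray(marker, dtype=float)
        name = "score"
    y = _binary_outcome(cohort[outcome])
    return values, y, name


def roc_analysis(cohort: pd.DataFrame, marker, outcome: str = "lnm",
                 direction: str = ">") -> RocResult:
    """Empirical ROC of a scalar marker.

    ``direction`` ">" treats higher values as predicting the positive class;
    "<" the reverse; "auto" picks the orientation with AUC >= 0.5.  The
    cutoff maximizes Youden's J = sensitivity + specificity - 1; J-ties are
    broken toward the lower cutoff.  The CI is the DeLong normal interval,
    clipped to [0, 1].
    """
    values, y, name = _marker_values(cohort, marker, outcome)
    if direction == "auto":
        auc_gt, _, _ = _auc_components(values[y == 1], values[y == 0])
        direction = ">" if auc_gt >= 0.5 else "<"
    x = values if direction == ">" else -values
    pos, neg = x[y == 1], x[y == 0]
    auc, v10, v01 = _auc_components(pos, neg)
    se = np.sqrt(_delong_variance(v10, v01))
    ci = (max(auc - 1.959963984540054 * se, 0.0),
          min(auc + 1.959963984540054 * se, 1.0))

    cands = np.unique(x)
    sens = (pos[:, None] >= cands[None, :]).mean(axis=0)
    spec = (neg[:, None] < cands[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j))
    reported = cands if direction == ">" else -cands
    pick = tied[np.argmin(reported[tied])]
    return RocResult(marker=name, auc=auc, ci_low=float(ci[0]),
                     ci_high=float(ci[1]), cutoff=float(reported[pick]),
                     sensitivity=float(sens[pick]),
                     specificity=float(spec[pick]), direction=direction,
                     n_positive=len(pos), n_negative=len(neg))


def _logit_score(y, X: pd.DataFrame) -> np.ndarray:
    """In-sample linear predictor of a logistic fit over X.

    Under complete separation the ML estimate diverges; the score then comes
    from a lightly ridge-penalized fit (the penalty only pins the scale, the
    ranking — and hence the ROC — is unaffected).  Collinear designs are
    still rejected.
    """
    fit = _fit_logit(y, X)
    if fit.converged:
        return fit.table["coef"].to_numpy() @ X.to_numpy().T
    if fit.collinear:
        raise ValueError(f"collinear design over {tuple(X.columns)}")
    Xd = sm.add_constant(X.to_numpy(), has_constant="add")
    lam = 1e-3

    def penalized_nll(beta):
        eta = Xd @ beta
        return (np.sum(np.logaddexp(0.0, eta) - np.asarray(y) * eta)
                + 0.5 * lam * np.sum(beta[1:] ** 2))

    from scipy.optimize import minimize
    sol = minimize(penalized_nll, np.zeros(Xd.shape[1]), method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 500})
    return sol.x[1:] @ X.to_numpy().T


def combined_model(cohort: pd.DataFrame, variables: Sequence[str],
                   outcome: str = "lnm", name: Optional[str] = None) -> RocResult:
    """ROC of the in-sample predicted probability of a logistic model over
    ``variables``; the reported cutoff lives on the probability scale."""
    y = _binary_outcome(cohort[outcome])
    eta = _logit_score(y, _design(cohort, list(variables)))
    prob = 1.0 / (1.0 + np.exp(-eta))     # intercept omitted: monotone in eta
    res = roc_analysis(cohort.assign(_score=prob), "_score", outcome=outcome,
                       direction=">")
    res.marker = name or "+".join(variables)
    res.cutoff_scale = "probability"
    return res


@dataclass
class DeLongResult:
    marker_a: str
    marker_b: str
    auc_a: float
    auc_b: float
    auc_difference: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(cohort: pd.DataFrame, marker_a, marker_b,
                outcome: str = "lnm", directions=(">", ">")) -> DeLongResult:
    """DeLong's test for the difference of two correlated (paired) AUCs.

    Structural components are computed per case and per control for both
    markers; the paired variance is var_A + var_B - 2 cov, and
    Z = (AUC_A - AUC_B) / sqrt(paired variance), two-sided normal p.
    """
    va, y, name_a = _marker_values(cohort, marker_a, outcome)
    vb, yb, name_b = _marker_values(cohort, marker_b, outcome)
    if not np.array_equal(y, yb):
        raise ValueError("markers must be measured on the same patients")
    oriented = []
    for v, d in ((va, directions[0]), (vb, directions[1])):
        if d == "auto":
            auc_gt, _, _ = _auc_components(v[y == 1], v[y == 0])
            d = ">" if auc_gt >= 0.5 else "<"
        oriented.append(v if d == ">" else -v)
    xa, xb = oriented
    auc_a, v10a, v01a = _auc_components(xa[y == 1], xa[y == 0])
    auc_b, v10b, v01b = _auc_components(xb[y == 1], xb[y == 0])
    m, n = int((y == 1).sum()), int((y == 0).sum())
    var_a = _delong_variance(v10a, v01a)
    var_b = _delong_variance(v10b, v01b)
    cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m +
           np.cov(v01a, v01b, ddof=1)[0, 1] / n)
    paired_var = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if paired_var <= 1e-16:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return DeLongResult(name_a, name_b, auc_a, auc_b, diff, float(z),
                            float(p), degenerate=True)
    z = diff / np.sqrt(paired_var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(name_a, name_b, auc_a, auc_b, diff, float(z), float(p))


# ------------------------------------------------------------ full report

COMPOSITE_MODELS = {
    "DWI": ("adc",),
    "RSI": ("f1", "f3"),
    "DKI": ("d_app", "k_app"),
}


def run_full_analysis(cohort: pd.DataFrame, outcome: str = "lnm",
                      inclusion_threshold: float = 0.1) -> dict:
    """Full statistics stage on one cohort table.

    Returns a bundle of data frames: ``table1`` (group comparisons),
    ``table2_univariate`` / ``table2_multivariate`` (logistic, OR per SD),
    ``table3`` (ROC of the six parameters and the three composite
    diffusion-model scores), and ``delong`` (paired AUC comparisons of each
    marker against the kurtosis composite plus the model-vs-model pairs).
    """
    variables = [v for v in CLINICAL_VARIABLES + DIFFUSION_PARAMETERS
                 if v in cohort.columns]

    t1_rows = []
    for v in variables:
        r = compare_groups(cohort, v, outcome=outcome)
        t1_rows.append({"variable": v, "test": r.test,
                        "statistic": r.statistic, "p_value": r.p_value,
                        "positive": r.summary_positive,
                        "negative": r.summary_negative})
    table1 = pd.DataFrame(t1_rows)

    uni_rows, selected = [], []
    for v in variables:
        uni = univariate_lr(cohort, v, outcome=outcome)
        if uni.converged and not uni.table.empty:
            row = uni.table.iloc[0]
            uni_rows.append({"variable": v, "or": row["or_"],
                             "ci_low": row["ci_low"],
                             "ci_high": row["ci_high"], "p_value": row["p"]})
            if row["p"] < inclusion_threshold:
                selected.append(v)
        else:
            uni_rows.append({"variable": v, "or": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p_value": np.nan})
    table2_uni = pd.DataFrame(uni_rows)

    if selected:
        multi = multivariate_lr(cohort, variables=selected, outcome=outcome)
        if multi.converged:
            table2_multi = multi.table.rename(
                columns={"or_": "or", "p": "p_value"}).reset_index(
                names="variable")[["variable", "or", "ci_low", "ci_high",
                                   "p_value"]]
        else:
            table2_multi = pd.DataFrame(
                {"variable": selected,
                 "note": [f"not estimable (separation={multi.separation}, "
                          f"collinear={multi.collinear})"] * len(selected)})
    else:
        table2_multi = pd.DataFrame(columns=["variable", "or", "ci_low",
                                             "ci_high", "p_value"])

    roc_results = {}
    t3_rows = []
    for v in DIFFUSION_PARAMETERS:
        r = roc_analysis(cohort, v, outcome=outcome, direction="auto")
        roc_results[v] = r
        t3_rows.append(_roc_row(v, r))
    for model_name, members in COMPOSITE_MODELS.items():
        if len(members) == 1:
            r = roc_analysis(cohort, members[0], outcome=outcome,
                             direction="auto")
            r = RocResult(model_name, r.auc, r.ci_low, r.ci_high, r.cutoff,
                          r.sensitivity, r.specificity, r.direction,
                          "marker", r.n_positive, r.n_negative)
        else:
            r = combined_model(cohort, members, outcome=outcome,
                               name=model_name)
        roc_results[model_name] = r
        t3_rows.append(_roc_row(model_name, r))
    table3 = pd.DataFrame(t3_rows)

    scores = {}
    for key, r in roc_results.items():
        if key in DIFFUSION_PARAMETERS:
            scores[key] = (cohort[key].to_numpy(dtype=float), r.direction)
    for model_name, members in COMPOSITE_MODELS.items():
        if len(members) == 1:
            scores[model_name] = scores[members[0]]
        else:
            y = _binary_outcome(cohort[outcome])
            eta = _logit_score(y, _design(cohort, list(members)))
            scores[model_name] = (eta, ">")

    dl_rows = []
    ref_vals, ref_dir = scores["DKI"]
    for key in list(DIFFUSION_PARAMETERS) + ["RSI", "DWI"]:
        vals, d = scores[key]
        r = delong_test(cohort, vals, ref_vals, outcome=outcome,
                        directions=(d, ref_dir))
        dl_rows.append({"marker_a": key, "marker_b": "DKI",
                        "auc_a": r.auc_a, "auc_b": r.auc_b, "z": r.z,
                        "p_value": r.p_value})
    vals_r, d_r = scores["RSI"]
    vals_w, d_w = scores["DWI"]
    r = delong_test(cohort, vals_r, vals_w, outcome=outcome,
                    directions=(d_r, d_w))
    dl_rows.append({"marker_a": "RSI", "marker_b": "DWI", "auc_a": r.auc_a,
                    "auc_b": r.auc_b, "z": r.z, "p_value": r.p_value})
    delong = pd.DataFrame(dl_rows)

    return {"table1": table1, "table2_univariate": table2_uni,
            "table2_multivariate": table2_multi, "table3": table3,
            "delong": delong}


def _roc_row(name, r: RocResult) -> dict:
    return {"marker": name, "auc": r.auc, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "cutoff": r.cutoff,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "direction": r.direction, "cutoff_scale": r.cutoff_scale}
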