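"""Model fitting and evaluation statistics.

AUC is the Mann-Whitney probability with half credit for ties; its variance
(for confidence intervals and paired comparison) comes from DeLong's
structural components, computed with midranks.  Operating points are chosen
by Youden's J (ties resolved toward higher specificity).  Cohort-comparison
statistics follow the usual clinical-table conventions: Mann-Whitney U for
continuous variables, chi-square (uncorrected) for categorical ones with
Fisher's exact test when any expected 2x2 cell falls below 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelEvaluation",
    "DeLongComparison",
    "FittedLogisticModel",
    "split_cohort",
    "cohort_compare",
    "fit_clinical_model",
    "fit_score_model",
    "auc_mann_whitney",
    "delong_components",
    "evaluate_model",
    "delong_test",
    "calibration_curve",
    "decision_curve",
    "CLINICAL_MODEL_TERMS",
]

#: Clinical-model covariates: the independent risk factors retained by the
#: multivariable analysis (dichotomized age, N2 nodal stage, any driver
#: mutation, EGFR mutation).
CLINICAL_MODEL_TERMS = ("age_ge65", "N2_stage", "gene_mutation", "EGFR")


# ---------------------------------------------------------------------------
# Cohort handling
# ---------------------------------------------------------------------------

def split_cohort(
    table: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    outcome_col: str = "BM",
) -> pd.DataFrame:
    """Stratified random training/validation split tagged in a "split" column.

    Within each outcome stratum, round(n_stratum * ratio) patients go to
    training, so both splits keep the cohort prevalence to within one
    patient.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    split = pd.Series("validation", index=table.index, dtype=object)
    for _, idx in table.groupby(outcome_col).groups.items():
        idx = np.array(list(idx))
        perm = rng.permutation(len(idx))
        n_train = int(round(len(idx) * ratio))
        split.loc[idx[perm[:n_train]]] = "training"
    out = table.copy()
    out["split"] = split
    return out


def _is_continuous(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not (
        pd.api.types.is_bool_dtype(series) or series.nunique() <= 2
    )


def cohort_compare(
    table: pd.DataFrame,
    group_col: str = "split",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable two-group comparison (clinical "Table 1" style).

    Continuous variables: Mann-Whitney U, two-sided.  Categorical variables:
    uncorrected chi-square on the contingency table, or Fisher's exact test
    when the table is 2x2 with any expected count below 5.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"{group_col} must define exactly 2 groups")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if variables is None:
        variables = [c for c in table.columns
                     if c not in (group_col, "patient_id")]
    rows = []
    for var in variables:
        if _is_continuous(table[var]):
            stat, p = sps.mannwhitneyu(
                g1[var], g2[var], alternative="two-sided"
            )
            test = "mann-whitney"
        else:
            cont = pd.crosstab(table[var], table[group_col]).values
            if cont.shape == (2, 2):
                expected = sps.contingency.expected_freq(cont)
                if (expected < 5).any():
                    stat, p = sps.fisher_exact(cont, alternative="two-sided")
                    test = "fisher"
                else:
                    stat, p, _, _ = sps.chi2_contingency(cont, correction=False)
                    test = "chi2"
            else:
                stat, p, _, _ = sps.chi2_contingency(cont, correction=False)
                test = "chi2"
        rows.append({"variable": var, "test": test,
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Logistic models
# ---------------------------------------------------------------------------

@dataclass
class FittedLogisticModel:
    """Maximum-likelihood logistic fit with the usual inferential summary."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    odds_ratios: pd.Series
    aic: float
    converged: bool
    separation_suspected: bool
    _result: object = None

    def predict(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[list(self.terms)].astype(float).values
        x = sm.add_constant(np.asarray(x, dtype=float), has_constant="add")
        return self._result.predict(x)

    def linear_predictor(self, x) -> np.ndarray:
        p = np.clip(self.predict(x), 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


def _fit_logit(x: np.ndarray, y: np.ndarray, terms) -> FittedLogisticModel:
    xc = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, xc)
    converged = True
    try:
        result = model.fit(disp=0, maxiter=200)
        converged = bool(result.mle_retvals.get("converged", True))
    except Exception:
        result = model.fit(disp=0, maxiter=500, method="bfgs")
        converged = False
    names = ["intercept", *terms]
    params = pd.Series(np.asarray(result.params), index=names)
    try:
        bse_arr = np.asarray(result.bse)
        if not np.all(np.isfinite(bse_arr)):
            raise ValueError
    except Exception:
        bse_arr = np.full(len(names), np.inf)  # singular Hessian: separation
        converged = False
    bse = pd.Series(bse_arr, index=names)
    # Quasi-separation shows up as exploding coefficients / standard errors.
    separation = bool(
        (np.abs(params[1:]) > 15).any() or (bse[1:] > 50).any()
        or not converged
    )
    return FittedLogisticModel(
        terms=tuple(terms),
        params=params,
        bse=bse,
        odds_ratios=np.exp(params[1:]),
        aic=float(result.aic),
        converged=converged,
        separation_suspected=separation,
        _result=result,
    )


def fit_clinical_model(
    table: pd.DataFrame,
    terms=CLINICAL_MODEL_TERMS,
    outcome_col: str = "BM",
) -> FittedLogisticModel:
    """Clinical logistic model on the dichotomized risk factors."""
    x = table[list(terms)].astype(float).values
    y = table[outcome_col].astype(int).values
    return _fit_logit(x, y, terms)


def fit_score_model(
    scores: np.ndarray, outcome: np.ndarray, name: str = "radscore"
) -> FittedLogisticModel:
    """Univariable logistic model on a radiomics score."""
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    y = np.asarray(outcome).astype(int)
    return _fit_logit(x, y, (name,))


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_mann_whitney(scores: np.ndarray, outcome: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(int)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    r = _midranks(scores)
    return float((r[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def delong_components(
    scores: np.ndarray, outcome: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, V10, V01): DeLong structural components for one score vector.

    V10 are the per-positive placement values, V01 the per-negative ones;
    the AUC equals the mean of either set.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass(frozen=True)
class ModelEvaluation:
    """ROC summary at the Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    auc_variance: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    aic: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def evaluate_model(scores: np.ndarray, outcome: np.ndarray) -> ModelEvaluation:
    """AUC with DeLong 95% CI plus the Youden-optimal operating point.

    The threshold maximizing J = sensitivity + specificity - 1 over the
    observed scores is chosen; exact ties go to the higher-specificity
    (higher) threshold.  AIC is that of the univariable logistic fit of the
    outcome on the score.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(int)
    auc, v10, v01 = delong_components(scores, y)
    var = _auc_variance(v10, v01)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.unique(scores)
    best = None
    for t in thresholds:  # ascending: later (higher-spec) wins exact ties
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / (y == 1).sum()
        spec = tn / (y == 0).sum()
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or spec >= best[2]:
                best = (j, sens, spec, t)
    _, sens, spec, thr = best
    acc = float(((scores >= thr) == (y == 1)).mean())
    aic = fit_score_model(scores, y).aic if len(np.unique(scores)) > 1 else (
        fit_score_model(scores + 1e-9 * np.arange(len(y)), y).aic
    )
    return ModelEvaluation(
        auc=auc, ci_low=ci[0], ci_high=ci[1], auc_variance=var,
        sensitivity=float(sens), specificity=float(spec), accuracy=acc,
        threshold=float(thr), aic=float(aic),
    )


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    auc_difference: float
    z: float
    p: float


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, outcome: np.ndarray
) -> DeLongComparison:
    """DeLong's test for two paired AUCs (two-sided normal p)."""
    y = np.asarray(outcome).astype(int)
    auc_a, v10a, v01a = delong_components(scores_a, y)
    auc_b, v10b, v01b = delong_components(scores_b, y)
    m, n = len(v10a), len(v01a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-300:
        return DeLongComparison(auc_a, auc_b, diff, 0.0, 1.0)
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongComparison(auc_a, auc_b, float(diff), float(z),
                            float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# Calibration and decision curves
# ---------------------------------------------------------------------------

def calibration_curve(
    probabilities: np.ndarray, outcome: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Per-bin (mean predicted, observed rate, count) over [0, 1].

    Bin edges partition [0, 1] into ``n_bins`` equal-width bins (the last
    right-inclusive); every patient lands in exactly one bin; empty bins are
    omitted.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome).astype(int)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            rows.append({
                "bin": b,
                "mean_predicted": float(p[sel].mean()),
                "observed_rate": float(y[sel].mean()),
                "count": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def decision_curve(
    probabilities: np.ndarray,
    outcome: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none across
    threshold probabilities: NB(pt) = TP/n - (FP/n) * pt / (1 - pt)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.96, 0.01)
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = p >= pt
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        w = pt / (1.0 - pt)
        rows.append({
            "threshold": float(pt),
            "net_benefit": tp / n - (fp / n) * w,
            "treat_all": prev - (1 - prev) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)
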