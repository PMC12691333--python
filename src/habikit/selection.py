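"""Feature selection and radscore construction.

The pipeline follows standard radiomics practice: segmentation-stability
filtering (ICC across repeated segmentations, pass at >= 0.70 by default),
redundancy filtering (greedy elimination of pairwise |Pearson r| > 0.75),
mRMR ranking to a top-m shortlist, and an L1-penalized (LASSO) logistic path
with cross-validated penalty choice.  The selected features and their
penalized coefficients form the radiomics score

    radscore(x) = intercept + sum_f coef_f * x_f,

reported on the raw feature scale so the formula can be published and
re-evaluated verbatim.  Two published radscore models ("paper_voi",
"paper_sub") ship as named fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "StabilityReport",
    "SelectionResult",
    "RadscoreModel",
    "icc",
    "icc_filter",
    "correlation_filter",
    "mrmr_rank",
    "lasso_select",
    "select_features",
    "build_radscore",
    "evaluate_radscore",
    "load_paper_model",
]


# ---------------------------------------------------------------------------
# ICC stability filtering
# ---------------------------------------------------------------------------

def icc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC, i.e.
    ICC(A,1), computed per column of two paired (n_subjects, n_features)
    arrays (two raters / two time points).

    Zero-variance features return NaN (ICC undefined).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("rater tables must have identical shape")
    n = a.shape[0]
    k = 2
    grand = (a + b) / 2
    mu = grand.mean(axis=0)
    ss_rows = k * ((grand - mu) ** 2).sum(axis=0)
    rater_means = np.stack([a.mean(axis=0), b.mean(axis=0)])
    ss_cols = n * ((rater_means - mu) ** 2).sum(axis=0)
    ss_tot = ((a - mu) ** 2).sum(axis=0) + ((b - mu) ** 2).sum(axis=0)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (msr - mse) / denom
    out[np.abs(denom) < 1e-30] = np.nan
    return out


@dataclass
class StabilityReport:
    """Per-feature inter-/intra-reader ICC with the pass decision."""

    table: pd.DataFrame  # columns: inter_icc, intra_icc (may be NaN), passed
    threshold: float

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])


def icc_filter(
    reader_a: pd.DataFrame,
    reader_b: pd.DataFrame,
    threshold: float = 0.70,
    reader_a_repeat: pd.DataFrame | None = None,
) -> StabilityReport:
    """Stability filter on repeated segmentations.

    ``reader_a`` / ``reader_b`` are feature tables from the two readers'
    masks (same patients, same columns); ``reader_a_repeat`` optionally adds
    the intra-reader re-segmentation.  A feature passes when every available
    ICC is >= ``threshold``; undefined (zero-variance) ICCs fail.
    """
    if list(reader_a.columns) != list(reader_b.columns) or len(reader_a) != len(
        reader_b
    ):
        raise ValueError("reader tables must share patients and columns")
    inter = icc(reader_a.values, reader_b.values)
    intra = (
        icc(reader_a.values, reader_a_repeat.values)
        if reader_a_repeat is not None
        else np.full(len(inter), np.nan)
    )
    passed = (np.nan_to_num(inter, nan=-np.inf) >= threshold)
    if reader_a_repeat is not None:
        passed &= np.nan_to_num(intra, nan=-np.inf) >= threshold
    table = pd.DataFrame(
        {"inter_icc": inter, "intra_icc": intra, "passed": passed},
        index=reader_a.columns,
    )
    return StabilityReport(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

def correlation_filter(
    table: pd.DataFrame,
    r_max: float = 0.75,
    outcome: np.ndarray | None = None,
) -> list[str]:
    """Greedy elimination of features with pairwise |Pearson r| > ``r_max``.

    Features are visited in order of outcome relevance (|correlation with
    the binary outcome|) or, without an outcome, descending variance; within
    a violating pair the later (less relevant) feature is dropped, so the
    surviving set has pairwise |r| <= r_max.  Ties break lexicographically.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 patients")
    x = table.values.astype(np.float64)
    names = np.array(table.columns)
    sd = x.std(axis=0)
    if outcome is not None:
        y = np.asarray(outcome, dtype=np.float64)
        yc = y - y.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.abs((x - x.mean(0)).T @ yc) / (
                sd * yc.std() * len(y) + 1e-300
            )
        score = np.nan_to_num(score)
    else:
        score = x.var(axis=0)
    order = np.lexsort((names, -score))

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=1.0)

    kept: list[int] = []
    for idx in order:
        if all(abs(corr[idx, j]) <= r_max for j in kept):
            kept.append(idx)
    kept_names = set(names[kept])
    return [c for c in table.columns if c in kept_names]


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _quantile_codes(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) of two discrete code vectors, from the joint histogram."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float((pj[nz] * np.log(pj[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(
    table: pd.DataFrame,
    outcome: np.ndarray,
    m: int | None = None,
    n_bins: int = 4,
) -> list[str]:
    """Greedy mRMR ranking (MID scheme: relevance minus mean redundancy).

    Features are quantile-discretized into ``n_bins`` codes; at each step the
    feature maximizing I(f; y) - mean_{s in selected} I(f; s) is added.
    Ties break toward the lexicographically smaller name.
    """
    y = np.asarray(outcome).astype(np.int64)
    if m is None:
        m = table.shape[1]
    m = min(m, table.shape[1])
    cols = sorted(table.columns)  # fixed lexicographic base order
    codes = {c: _quantile_codes(table[c].values, n_bins) for c in cols}
    relevance = {c: _mutual_information(codes[c], y) for c in cols}

    selected: list[str] = []
    remaining = list(cols)
    redundancy_sum = {c: 0.0 for c in cols}
    while remaining and len(selected) < m:
        best, best_score = None, -np.inf
        for c in remaining:
            red = redundancy_sum[c] / len(selected) if selected else 0.0
            score = relevance[c] - red
            if score > best_score + 1e-15:
                best, best_score = c, score
        assert best is not None
        selected.append(best)
        remaining.remove(best)
        for c in remaining:
            redundancy_sum[c] += _mutual_information(codes[c], codes[best])
    return selected


# ---------------------------------------------------------------------------
# LASSO path
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Trace of the staged selection: surviving names per stage, the LASSO
    path, the chosen penalty, and the final (raw-scale) coefficients."""

    stage_survivors: dict[str, list[str]]
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    lambda_: float
    lambda_grid: np.ndarray = field(repr=False, default=None)
    coef_path: np.ndarray = field(repr=False, default=None)  # (n_lambda, p) raw scale
    cv_deviance: np.ndarray = field(repr=False, default=None)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "stage_survivors": self.stage_survivors,
            "selected": self.selected,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "seed": self.seed,
        }


def _l1_logistic(x, y, lam, max_iter=5000, tol=1e-7):
    """L1 logistic fit at penalty ``lam`` (glmnet-style mean-loss scale);
    the intercept is unpenalized."""
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0, solver="saga", C=1.0 / (lam * n), max_iter=max_iter,
        tol=tol, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x, y)
    coef = model.coef_[0]
    b0 = float(model.intercept_[0])
    if np.all(np.abs(coef) < 1e-12):
        # fully shrunk: the unpenalized-intercept optimum is closed form
        b0 = float(np.log(y.mean() / (1.0 - y.mean())))
    return coef, b0


def _l1_path(x, y, lambdas, max_iter=2000, tol=1e-5):
    """Warm-started L1 logistic sweep down a descending lambda grid.

    Returns (coefs, intercepts) with one row per lambda.
    """
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0, solver="saga", max_iter=max_iter, tol=tol,
        warm_start=True, random_state=0,
    )
    null_intercept = float(np.log(y.mean() / (1.0 - y.mean())))
    coefs = np.zeros((len(lambdas), x.shape[1]))
    intercepts = np.zeros(len(lambdas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            model.C = 1.0 / (lam * n)
            model.fit(x, y)
            coefs[i] = model.coef_[0]
            intercepts[i] = float(model.intercept_[0])
            if np.all(np.abs(coefs[i]) < 1e-12):
                intercepts[i] = null_intercept
    return coefs, intercepts


def lasso_select(
    table: pd.DataFrame,
    outcome: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
    rule: str = "lambda_min",
) -> SelectionResult:
    """L1-penalized logistic path with cross-validated penalty choice.

    Features are z-standardized internally for the fit; the reported
    coefficients and intercept are transformed back to the raw feature scale
    so ``intercept + sum(coef * x_raw)`` is the final radscore formula.  The
    penalty is chosen by mean held-out deviance (``lambda_min`` default,
    ``lambda_1se`` for the sparser within-one-SE choice) over stratified
    folds; fold counts are capped so every fold contains both classes.
    """
    y = np.asarray(outcome).astype(np.int64)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary with both classes present")
    names = list(table.columns)
    x = table.values.astype(np.float64)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xs = (x - mu) / sd

    n = len(y)
    lam_max = np.abs(xs.T @ (y - y.mean())).max() / n
    lambdas = np.geomspace(lam_max * 1.05, lam_max * 1e-3, n_lambda)

    minority = min((y == 0).sum(), (y == 1).sum())
    folds = max(2, min(n_folds, int(minority)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    deviance = np.zeros((len(lambdas), folds))
    for f, (tr, te) in enumerate(skf.split(xs, y)):
        coefs, intercepts = _l1_path(xs[tr], y[tr], lambdas)
        for i in range(len(lambdas)):
            eta = xs[te] @ coefs[i] + intercepts[i]
            p = 1.0 / (1.0 + np.exp(-eta))
            deviance[i, f] = 2 * log_loss(y[te], p, labels=[0, 1])

    mean_dev = deviance.mean(axis=1)
    i_min = int(np.argmin(mean_dev))
    if rule == "lambda_1se":
        se = deviance.std(axis=1, ddof=1) / np.sqrt(folds)
        cutoff = mean_dev[i_min] + se[i_min]
        candidates = np.nonzero(mean_dev <= cutoff)[0]
        i_chosen = int(candidates[0])  # largest lambda within one SE
    elif rule == "lambda_min":
        i_chosen = i_min
    else:
        raise ValueError(f"unknown rule {rule!r}")
    lam = float(lambdas[i_chosen])

    path_std, _ = _l1_path(xs, y, lambdas)
    path = path_std / sd  # raw scale

    coef_std, b0_std = _l1_logistic(xs, y, lam)
    coef_raw = coef_std / sd
    intercept = b0_std - float((coef_std * mu / sd).sum())
    nonzero = np.abs(coef_std) > 1e-10
    selected = [nm for nm, nz in zip(names, nonzero) if nz]
    return SelectionResult(
        stage_survivors={"lasso": selected},
        selected=selected,
        coefficients={nm: float(c) for nm, c, nz in
                      zip(names, coef_raw, nonzero) if nz},
        intercept=float(intercept),
        lambda_=lam,
        lambda_grid=lambdas,
        coef_path=path,
        cv_deviance=mean_dev,
        seed=seed,
    )


def select_features(
    table: pd.DataFrame,
    outcome: np.ndarray,
    reader_b_table: pd.DataFrame | None = None,
    icc_threshold: float = 0.70,
    r_max: float = 0.75,
    mrmr_top: int = 50,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "lambda_min",
) -> SelectionResult:
    """Full staged selection: ICC -> correlation -> mRMR -> LASSO.

    Stages are strictly nested; each operates only on the survivors of the
    previous one.  The ICC stage runs only when a second-reader table is
    supplied.  NaN columns (e.g. habitat features of an absent habitat) are
    dropped up front.
    """
    table = table.loc[:, table.notna().all(axis=0)]
    stage: dict[str, list[str]] = {"all": list(table.columns)}

    if reader_b_table is not None:
        report = icc_filter(
            table, reader_b_table[table.columns], threshold=icc_threshold
        )
        stage["icc"] = report.passing
        table = table[stage["icc"]]

    stage["correlation"] = correlation_filter(table, r_max=r_max,
                                              outcome=outcome)
    table = table[stage["correlation"]]

    stage["mrmr"] = mrmr_rank(table, outcome, m=mrmr_top)
    table = table[stage["mrmr"]]

    result = lasso_select(table, outcome, n_folds=n_folds, seed=seed,
                          rule=rule)
    result.stage_survivors = {**stage, "lasso": result.selected}
    return result


# ---------------------------------------------------------------------------
# Radscore
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadscoreModel:
    """Linear radiomics score: intercept + sum of coef * feature."""

    name: str
    intercept: float
    coefficients: dict[str, float]

    def score(self, features) -> float | np.ndarray:
        """Evaluate on a mapping / Series (scalar) or DataFrame (vector)."""
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.coefficients if f not in features.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            out = np.full(len(features), self.intercept, dtype=np.float64)
            for f, c in self.coefficients.items():
                out += c * features[f].values
            return out
        missing = [f for f in self.coefficients if f not in features]
        if missing:
            raise KeyError(f"missing model features: {missing}")
        return float(
            self.intercept
            + sum(c * float(features[f]) for f, c in self.coefficients.items())
        )


def build_radscore(selection: SelectionResult, name: str = "radscore") -> RadscoreModel:
    return RadscoreModel(name=name, intercept=selection.intercept,
                         coefficients=dict(selection.coefficients))


def evaluate_radscore(model: RadscoreModel, features):
    return model.score(features)


def load_paper_model(name: str) -> RadscoreModel:
    """Load a published radscore fixture: "paper_voi" or "paper_sub"."""
    text = resources.files("habikit.data").joinpath(
        "radscore_paper.json").read_text()
    models = json.loads(text)
    if name not in models:
        raise KeyError(f"unknown paper model {name!r}; have {sorted(models)}")
    entry = models[name]
    return RadscoreModel(name=name, intercept=float(entry["intercept"]),
                         coefficients={k: float(v) for k, v in
                                       entry["coefficients"].items()})
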