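"""Quintile-based hazard comparison of oximetry metrics.

Per-subject metric values are ranked in ascending order and split into
quintiles, each covering 20% of the sample; quintile 1 is the reference.
Model 0 regresses survival on the quintile dummies alone; Model 1 adds
demographic covariates (age, gender, race, BMI, COPD, smoking, alcohol,
sleep duration) and cardiometabolic covariates (diabetes, hypertension,
congestive heart failure, angina, myocardial infarction, coronary
revascularization, stroke, lipid-lowering medication). Cox fitting,
confidence intervals and survival prediction delegate to lifelines; the
Benjamini-Hochberg step-up correction delegates to statsmodels. This
module owns covariate encoding, quintile grouping and reporting only.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import (
    ConvergenceFailure,
    NoEvents,
    OutOfRange,
    TooFewSubjects,
    UnfittedModel,
)

logger = logging.getLogger(__name__)

#: Categorical covariates with their category lists; the first listed
#: category is the reference level of the dummy encoding.
CATEGORICAL = {
    "gender": ["Female", "Male"],
    "race": ["White", "Black", "Other"],
    "smoking": ["never", "former", "current"],
    "alcohol": ["<1", "1-12", ">=13"],
    "sleep_duration": ["<=5h", "5-8h", ">=8h"],
}
CONTINUOUS = ["age", "bmi"]
BINARY = ["copd", "diabetes", "hypertension", "chf", "angina", "mi",
          "revascularization", "stroke", "lipid_med"]


def assign_quintiles(values) -> np.ndarray:
    """Rank-based quintile labels in {1..5}, Q1 lowest.

    Group sizes are n/5 with the remainder going to the earlier groups;
    ties are broken by stable input order. All-equal input is legal but
    the cut points are degenerate (logged warning).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        raise TooFewSubjects(f"need at least 5 subjects, got {n}")
    if np.unique(values).size == 1:
        logger.warning("all metric values equal; quintile cuts are degenerate")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    sizes = [n // 5 + (1 if i < n % 5 else 0) for i in range(5)]
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = q
        start += size
    return labels


def _design_matrix(table: pd.DataFrame, metric: str, model: str) -> pd.DataFrame:
    quintile = assign_quintiles(table[metric].to_numpy())
    X = pd.DataFrame(index=table.index)
    for q in (2, 3, 4, 5):
        X[f"Q{q}"] = (quintile == q).astype(float)
    if model == "model1":
        for col in CONTINUOUS:
            X[col] = pd.to_numeric(table[col])
        for col in BINARY:
            X[col] = pd.to_numeric(table[col]).astype(float)
        for col, cats in CATEGORICAL.items():
            vals = table[col].astype(str)
            unknown = set(vals) - set(cats)
            if unknown:
                raise ValueError(f"{col}: unknown categories {sorted(unknown)}")
            for cat in cats[1:]:  # first listed category is the reference
                X[f"{col}[{cat}]"] = (vals == cat).astype(float)
        # constant covariates carry no information and break the fit
        for col in list(X.columns):
            if not col.startswith("Q") and X[col].nunique() == 1:
                logger.warning("dropping zero-variance covariate %s", col)
                X = X.drop(columns=[col])
    X["survival_time"] = pd.to_numeric(table["survival_time"])
    X["event_indicator"] = pd.to_numeric(table["event_indicator"]).astype(int)
    return X


def _check_vif(X: pd.DataFrame) -> None:
    cols = [c for c in X.columns if c not in ("survival_time", "event_indicator")]
    mat = X[cols].to_numpy(dtype=float)
    keep = mat.std(axis=0) > 0
    mat = np.column_stack([np.ones(len(mat)), mat[:, keep]])
    names = [c for c, k in zip(cols, keep) if k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names, start=1):
            try:
                vif = variance_inflation_factor(mat, j)
            except Exception:
                continue
            if vif > 5:
                logger.warning("covariate %s has VIF %.1f (> 5)", name, vif)


class FittedCoxModel:
    """A fitted quintile Cox model plus the table it was fit on."""

    def __init__(self, cph: CoxPHFitter, design: pd.DataFrame,
                 quintile: np.ndarray, metric: str, model: str):
        self.cph = cph
        self.design = design
        self.quintile = quintile
        self.metric = metric
        self.model = model

    @property
    def hr_table(self) -> pd.DataFrame:
        """Per-quintile hazard ratios vs Q1 with 95% CI and p-values."""
        s = self.cph.summary
        rows = []
        for q in (2, 3, 4, 5):
            r = s.loc[f"Q{q}"]
            rows.append({
                "metric": self.metric,
                "model": self.model,
                "quintile": q,
                "hr": float(np.exp(r["coef"])),
                "ci_low": float(np.exp(r["coef lower 95%"])),
                "ci_high": float(np.exp(r["coef upper 95%"])),
                "p": float(r["p"]),
            })
        df = pd.DataFrame(rows)
        df["p_bh"] = bh_adjust(df["p"].to_numpy())
        return df


def fit_cox_models(
    table: pd.DataFrame, metric: str, model: str = "model0"
) -> FittedCoxModel:
    """Fit the Model-0 or Model-1 Cox regression for one metric.

    Model 0 uses the quintile dummies Q2..Q5 alone; Model 1 adds the
    demographic and cardiometabolic covariate sets (categoricals
    dummy-encoded against their first listed level). Variance inflation
    factors above 5 are logged as warnings.
    """
    if model not in ("model0", "model1"):
        raise ValueError("model must be 'model0' or 'model1'")
    if metric not in table.columns:
        raise KeyError(
            f"metric {metric!r} not in table; available: {list(table.columns)}"
        )
    X = _design_matrix(table, metric, model)
    if X["event_indicator"].sum() == 0:
        raise NoEvents("no observed events in the table")
    if model == "model1":
        _check_vif(X)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="survival_time",
                    event_col="event_indicator")
    except ConvergenceError as exc:
        raise ConvergenceFailure(str(exc)) from exc
    quintile = np.zeros(len(X), dtype=int)
    dummies = X[[f"Q{q}" for q in (2, 3, 4, 5)]].to_numpy()
    quintile = np.where(dummies.any(axis=1), dummies.argmax(axis=1) + 2, 1)
    return FittedCoxModel(cph, X, quintile, metric, model)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise OutOfRange("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def averaged_survival_curves(
    fitted: FittedCoxModel,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quintile-averaged predicted survival curves.

    Predicts an individual survival curve for every subject from the
    fitted model, then averages within quintile on a common time grid.
    Returns a long DataFrame (time, quintile, mean_survival).
    """
    if fitted is None or not isinstance(fitted, FittedCoxModel):
        raise UnfittedModel("averaged_survival_curves needs a FittedCoxModel")
    X = fitted.design.drop(columns=["survival_time", "event_indicator"])
    surv = fitted.cph.predict_survival_function(X, times=times)
    rows = []
    for q in (1, 2, 3, 4, 5):
        sel = fitted.quintile == q
        if not sel.any():
            continue
        mean = surv.loc[:, surv.columns[sel]].mean(axis=1)
        for t, s in mean.items():
            rows.append({"time": float(t), "quintile": q,
                         "mean_survival": float(s)})
    return pd.DataFrame(rows)
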