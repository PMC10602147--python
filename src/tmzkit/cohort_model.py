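"""Proliferation-adjusted expression and the hypermutation association model.

Cell proliferation inflates expression of replication-associated genes, so
raw RAD18 expression is first regressed on a proliferation score by ordinary
least squares and the residual (observed minus fitted) is taken as the
adjusted expression.  Patients are stratified into low/medium/high tertiles
of the adjusted value, hypermutation is called from the Signature-11 count
(strictly greater than the threshold), and the association is estimated with
a binomial-logit GLM::

    Hypermutation ~ rad18_adj + MGMT

fit by iteratively reweighted least squares, with Wald z statistics and
p-values per coefficient.  Rows flagged POLE-mutated are excluded before any
computation, since proofreading-polymerase mutations are an independent
route to hypermutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import CohortTable

__all__ = [
    "AdjustedCohort",
    "LogisticFit",
    "adjust_expression",
    "stratify_tertiles",
    "fit_hypermutation_model",
]

log = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class AdjustedCohort:
    """Cohort rows plus rad18_adj residuals, tertile groups and labels."""

    table: pd.DataFrame  # adds rad18_adj, rad18_group, hypermutation
    slope: float
    intercept: float
    mgmt_kind: str
    n_excluded_pole: int = 0


@dataclass
class LogisticFit:
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    converged: bool
    n_iter: int
    n_obs: int
    log_likelihood: float


def stratify_tertiles(values) -> np.ndarray:
    """Rank-based split into low/medium/high groups of near-equal size.

    Group sizes differ by at most one; when n is not divisible by 3 the
    extra member(s) go to "low" first, then "medium".  Ties are broken by
    stable input order, so the labelling is deterministic.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need >= 3 values to form tertiles")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    order = np.argsort(v, kind="stable")
    labels = np.empty(n, dtype=object)
    start = 0
    for size, lab in zip(sizes, TERTILE_LABELS):
        labels[order[start:start + size]] = lab
        start += size
    return labels


def adjust_expression(
    cohort: CohortTable, hypermutation_threshold: float = 500.0
) -> AdjustedCohort:
    """OLS-adjust expression for proliferation; attach groups and calls.

    rad18_adj is the residual of rad18_expression on proliferation_score.
    Hypermutation is taken from the cohort's own column when present,
    otherwise derived as signature11_count > threshold (strict).
    """
    df = cohort.table.copy()
    n_pole = 0
    if "pole_mutated" in df.columns:
        n_pole = int(df["pole_mutated"].sum())
        if n_pole:
            log.info("excluding %d POLE-mutated sample(s)", n_pole)
        df = df.loc[~df["pole_mutated"]].reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("need >= 3 patients after exclusions")
    x = df["proliferation_score"].to_numpy(dtype=float)
    y = df["rad18_expression"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("proliferation_score is constant; slope unidentifiable")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = ols.params
    df["rad18_adj"] = ols.resid
    df["rad18_group"] = stratify_tertiles(df["rad18_adj"].to_numpy())
    if "hypermutation" not in df.columns:
        df["hypermutation"] = (
            df["signature11_count"].astype(float) > hypermutation_threshold
        )
    return AdjustedCohort(table=df, slope=float(slope),
                          intercept=float(intercept),
                          mgmt_kind=cohort.mgmt_kind,
                          n_excluded_pole=n_pole)


def _mgmt_covariate(adjusted: AdjustedCohort) -> np.ndarray:
    col = adjusted.table["mgmt_status"]
    if adjusted.mgmt_kind == "status":
        return (col == "low").to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for name in X.columns:
        if name == "intercept":
            continue
        v = X[name].to_numpy(dtype=float)
        if len(np.unique(v)) < 2:
            continue
        if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
            raise ValueError(
                f"perfect separation: covariate {name!r} completely splits "
                "the outcome classes"
            )


def fit_hypermutation_model(
    adjusted: AdjustedCohort, max_iter: int = 100, tol: float = 1e-10
) -> LogisticFit:
    """Binomial-logit GLM of hypermutation on rad18_adj and MGMT (IRLS)."""
    df = adjusted.table
    y = df["hypermutation"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model unidentifiable")
    X = pd.DataFrame({
        "intercept": np.ones(len(df)),
        "rad18_adj": df["rad18_adj"].to_numpy(dtype=float),
        "mgmt": _mgmt_covariate(adjusted),
    })
    _check_separation(X, y)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol)
    if not res.converged:
        raise RuntimeError("IRLS did not converge; no estimates reported")
    return LogisticFit(
        coef=res.params, se=res.bse, z=res.tvalues, p=res.pvalues,
        converged=bool(res.converged), n_iter=int(res.fit_history["iteration"]),
        n_obs=int(res.nobs), log_likelihood=float(res.llf),
    )
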