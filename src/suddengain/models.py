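"""Linear mixed-effects models for outcome and process analyses.

Two model families, both random-intercept models estimated by maximum
likelihood (statsmodels ``MixedLM``):

* the *outcome* model regresses endpoint LSAS on time (post-intervention
  vs 3-month follow-up), sudden-gain status, their interaction, and
  baseline LSAS as a covariate, with a participant random intercept; the
  quantities of interest are the covariate-adjusted group differences at
  each timepoint;

* the *process* models regress each around-gain measure on the 6-level
  categorical timepoint factor (n-2..n+3) with a participant random
  intercept; the quantities of interest are the five consecutive
  contrasts (n-2 vs n-1, ..., n+2 vs n+3), Bonferroni-corrected within
  measure (factor 5).

Contrast p-values use a Student-t reference with residual degrees of
freedom (observations minus fixed-effect columns) — a between-within
style approximation that is exact for balanced designs and mildly
conservative otherwise.  Effect sizes are Cohen's d on the raw score
scale: |estimate| divided by the pooled sample SD of the measure in the
two cells being compared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .around import TIMEPOINTS

CONTRAST_LABELS = tuple(
    f"{a} vs {b}" for a, b in zip(TIMEPOINTS[:-1], TIMEPOINTS[1:])
)


class ModelError(RuntimeError):
    """Raised when a model's preconditions are not met."""


def cohens_d(estimate: float, dispersion: float) -> float:
    """Raw-score standardised effect size |estimate| / dispersion."""
    if dispersion is None or not np.isfinite(dispersion) or dispersion <= 0:
        return float("nan")
    return abs(estimate) / dispersion


def pooled_sd(x: Sequence[float], y: Sequence[float]) -> float:
    """Pooled sample SD of two cells, weighting by their (n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    num = (len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)
    return math.sqrt(num / (len(x) + len(y) - 2))


def _fit_mixedlm(model: sm.MixedLM):
    """ML fit with convergence-warning suppression and a robust retry."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            return model.fit(reml=False, method="lbfgs")
        except Exception:
            return model.fit(reml=False, method="powell", maxiter=500)


def _wald(result, L: np.ndarray, df_resid: float) -> tuple[float, float, float]:
    """Estimate, SE and two-sided t p-value for the linear combination L.b."""
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    est = float(L @ beta)
    se = float(math.sqrt(L @ cov @ L))
    if se == 0:
        return est, se, float("nan")
    tval = est / se
    p = 2 * stats.t.sf(abs(tval), df_resid)
    return est, se, float(p)


# -- outcome model ---------------------------------------------------------

@dataclass
class OutcomeModelResult:
    """Adjusted group differences plus Table-2-style raw descriptives."""

    differences: pd.DataFrame      # time, estimate, se, p, d
    cell_stats: pd.DataFrame       # sg, time, n, mean, sd
    n_participants: int
    converged: bool
    loglike: float = float("nan")


def fit_outcome_model(endpoints: pd.DataFrame) -> OutcomeModelResult:
    """Fit the endpoint LSAS model and extract per-timepoint contrasts.

    ``endpoints`` is long with columns ``participant_id, time, lsas, sg,
    baseline_lsas``; ``time`` takes values ``post`` and ``followup`` and
    ``sg`` is boolean gain status.  Rows with a missing LSAS are dropped
    (participants may contribute one or both timepoints).  The reported
    "adjusted difference" at each timepoint is (no-gain mean) - (gain
    mean) holding baseline fixed, so a positive value means the gain
    group ends up less symptomatic.
    """
    df = endpoints.dropna(subset=["lsas", "baseline_lsas"]).copy()
    df["sg"] = df["sg"].astype(bool)
    if df["sg"].nunique() < 2:
        raise ModelError("all participants fall in one gain-status group")
    if not set(df["time"]) <= {"post", "followup"}:
        raise ModelError("time must be 'post' or 'followup'")
    df["time"] = pd.Categorical(df["time"], categories=["post", "followup"])
    df["sg_i"] = df["sg"].astype(int)
    df["base_c"] = df["baseline_lsas"] - df["baseline_lsas"].mean()

    # Cell descriptives on the raw scale (for reporting and for d).
    cells = (
        df.groupby(["sg", "time"], observed=True)["lsas"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )

    formula = "lsas ~ C(time) * sg_i + base_c"
    residual_var = _ols_residual_variance(df, formula)
    if residual_var < 1e-10:
        # Degenerate noiseless data: the mixed model's residual variance
        # collapses; the fixed effects are then the exact OLS solution.
        result = smf.ols(formula, data=df).fit()
        fe = result.params
        cov = result.cov_params()
        converged = True
        loglike = float(result.llf)
        get = lambda L: _wald_ols(fe, cov, L, result.df_resid)
    else:
        model = smf.mixedlm(formula, data=df, groups=df["participant_id"])
        result = _fit_mixedlm(model)
        converged = bool(result.converged)
        loglike = float(result.llf)
        k = len(result.fe_params)
        df_resid = max(len(df) - k, 1)
        get = lambda L: _wald(result, np.asarray(L, dtype=float), df_resid)

    # fixed-effect order: Intercept, C(time)[T.followup], sg_i, time:sg, base_c
    names = list(result.fe_params.index if hasattr(result, "fe_params") else result.params.index)
    L_post = _contrast_vector(names, {"sg_i": -1.0, "C(time)[T.followup]:sg_i": 0.0})
    L_fu = _contrast_vector(names, {"sg_i": -1.0, "C(time)[T.followup]:sg_i": -1.0})

    rows = []
    for time, L in (("post", L_post), ("followup", L_fu)):
        est, se, p = get(L)
        cell_sg = df.loc[(df["sg"]) & (df["time"] == time), "lsas"]
        cell_no = df.loc[(~df["sg"]) & (df["time"] == time), "lsas"]
        d = cohens_d(est, pooled_sd(cell_sg, cell_no))
        rows.append({"time": time, "estimate": est, "se": se, "p": p, "d": d})

    return OutcomeModelResult(
        differences=pd.DataFrame(rows),
        cell_stats=cells,
        n_participants=df["participant_id"].nunique(),
        converged=converged,
        loglike=loglike,
    )


def _ols_residual_variance(df: pd.DataFrame, formula: str) -> float:
    res = smf.ols(formula, data=df).fit()
    return float(res.ssr / max(res.nobs, 1))


def _wald_ols(params, cov, L, df_resid):
    L = np.asarray(L, dtype=float)
    est = float(L @ np.asarray(params))
    se = float(math.sqrt(L @ np.asarray(cov) @ L))
    if se == 0:
        return est, se, float("nan")
    p = 2 * stats.t.sf(abs(est / se), df_resid)
    return est, se, float(p)


def _contrast_vector(names: list[str], weights: dict[str, float]) -> np.ndarray:
    L = np.zeros(len(names))
    for key, w in weights.items():
        if w == 0.0:
            continue
        try:
            L[names.index(key)] = w
        except ValueError as exc:
            raise ModelError(f"fixed effect {key!r} not found in {names}") from exc
    return L


# -- process models --------------------------------------------------------

@dataclass
class ProcessModelFit:
    """A fitted around-gain random-intercept model for one measure."""

    measure: str
    result: object                 # statsmodels results wrapper
    data: pd.DataFrame             # rows actually used (missing dropped)
    df_resid: float
    marginal_means: dict[str, float] = field(default_factory=dict)


def fit_process_model(around_long: pd.DataFrame, measure: str) -> ProcessModelFit:
    """Random-intercept model of one measure on the timepoint factor.

    Rows with a missing value are dropped (no imputation); at least two
    timepoints with two or more observations each are required.
    """
    df = around_long[around_long["measure"] == measure].dropna(subset=["value"]).copy()
    counts = df.groupby("timepoint", observed=True).size()
    if (counts >= 2).sum() < 2:
        raise ModelError(
            f"measure {measure!r}: fewer than 2 timepoints with >= 2 observations"
        )
    present = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=present)

    if float(df.groupby("timepoint", observed=True)["value"].var().fillna(0).max()) < 1e-12:
        result = smf.ols("value ~ C(timepoint)", data=df).fit()
        df_resid = float(result.df_resid)
    else:
        model = smf.mixedlm("value ~ C(timepoint)", data=df, groups=df["participant_id"])
        result = _fit_mixedlm(model)
        k = len(result.fe_params)
        df_resid = max(len(df) - k, 1)

    params = result.fe_params if hasattr(result, "fe_params") else result.params
    intercept = float(params.iloc[0])
    means = {}
    for t in present:
        key = f"C(timepoint)[T.{t}]"
        means[t] = intercept + (float(params[key]) if key in params.index else 0.0)
    return ProcessModelFit(measure=measure, result=result, data=df,
                           df_resid=df_resid, marginal_means=means)


def consecutive_contrasts(fit: ProcessModelFit, bonferroni_m: int = 5) -> pd.DataFrame:
    """Five consecutive-timepoint contrasts for one fitted process model.

    Estimates are later-minus-earlier (a symptom drop is negative), with
    Bonferroni-adjusted p = min(1, m x raw p) within the measure and a
    raw-scale Cohen's d from the two cells' pooled SD.  Contrasts whose
    either timepoint was absent from the data are reported as NaN rows.
    """
    result = fit.result
    params = result.fe_params if hasattr(result, "fe_params") else result.params
    names = list(params.index)
    rows = []
    present = set(fit.data["timepoint"].cat.categories)
    for label, (a, b) in zip(CONTRAST_LABELS, zip(TIMEPOINTS[:-1], TIMEPOINTS[1:])):
        if a not in present or b not in present:
            rows.append({"measure": fit.measure, "contrast": label,
                         "estimate": np.nan, "se": np.nan, "p": np.nan,
                         "p_adj": np.nan, "d": np.nan})
            continue
        weights: dict[str, float] = {}
        for t, w in ((b, 1.0), (a, -1.0)):
            key = f"C(timepoint)[T.{t}]"
            if key in names:
                weights[key] = w
        L = _contrast_vector(names, weights)
        if hasattr(result, "fe_params"):
            est, se, p = _wald(result, L, fit.df_resid)
        else:
            est, se, p = _wald_ols(params, result.cov_params(), L, fit.df_resid)
        cell_a = fit.data.loc[fit.data["timepoint"] == a, "value"]
        cell_b = fit.data.loc[fit.data["timepoint"] == b, "value"]
        rows.append({
            "measure": fit.measure,
            "contrast": label,
            "estimate": est,
            "se": se,
            "p": p,
            "p_adj": min(1.0, bonferroni_m * p) if np.isfinite(p) else np.nan,
            "d": cohens_d(est, pooled_sd(cell_a, cell_b)),
        })
    return pd.DataFrame(rows)


def contrast_table(around_long: pd.DataFrame, measures: Sequence[str]) -> pd.DataFrame:
    """Fit every measure's process model and stack the contrast rows."""
    tables = []
    for measure in measures:
        fit = fit_process_model(around_long, measure)
        tables.append(consecutive_contrasts(fit))
    return pd.concat(tables, ignore_index=True)
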