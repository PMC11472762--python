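"""Regressions linking radiographic measurements to keel damage.

Two model families from the study design:

* the damage model — per-age regression of a dissected-keel damage
  response on the radiographic predictors,

      y = b0 + b1*operator + b2*tibiotarsal + b3*keel + b4*xlm
          + b5*bodyweight + e

  fit as ordinary linear regression (equally spaced ordinal scores),
  logistic regression (binary damage), or right-censored Poisson
  regression (fracture counts, where "4" means ">= four");

* the pelvic model — keel condition on a body-weight-adjusted pelvic
  dimension, tibiotarsal density, and their interaction,

      y = b0 + b1*operator + b2*pelvic + b3*tibiotarsal
          + b4*pelvic*tibiotarsal + e.

Pelvic dimensions correlate strongly (about 0.65) with body weight, so
before modelling they are residualised on body weight by OLS and
re-centred at their original mean.

The censored-Poisson likelihood treats a flagged count c as the event
{Y >= c}:

    logL = sum_uncensored [y log(lam) - lam - log y!]
         + sum_censored  log P(Y >= c; lam),   lam = exp(X b).

OLS and logistic fits are delegated to statsmodels; the censored
Poisson is maximised directly (BFGS with analytic gradient, Wald SEs
from the observed information).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger("keelmorph")

FAMILIES = ("linear", "logistic", "censored_poisson")

DAMAGE_PREDICTORS = ("tibiotarsal", "keel", "xlm", "bodyweight")


@dataclass
class PelvicDims:
    """Post-mortem pelvic dimensions (mm): width, depth, their product."""

    width_mm: float
    depth_mm: float
    capacity_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("pelvic dimensions must be positive")
        expected = self.width_mm * self.depth_mm
        if self.capacity_mm2 is None:
            self.capacity_mm2 = expected
        elif abs(self.capacity_mm2 - expected) > 1e-9 * max(1.0, expected):
            raise ValueError(
                f"capacity {self.capacity_mm2} inconsistent with "
                f"width x depth = {expected}")


@dataclass
class RegressionResult:
    """Tidy coefficient table plus fit diagnostics."""

    family: str
    terms: list
    params: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    pvalues: np.ndarray
    n: int
    loglik: float | None = None
    residuals: np.ndarray | None = None
    converged: bool = True
    separation: bool = False
    dropped_terms: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.params,
            "se": self.se,
            "statistic": self.statistic,
            "p": self.pvalues,
            "n": self.n,
            "family": self.family,
        })


# ---------------------------------------------------------------------------
# Body-weight adjustment

def adjust_for_bodyweight(pelvic, bodyweight) -> np.ndarray:
    """Residualise a pelvic dimension on body weight, keeping its mean.

    OLS of pelvic on (intercept, body weight); the returned values are
    the residuals plus the original pelvic mean, so the adjusted
    variable is uncorrelated with body weight but keeps its scale.
    """
    pelvic = np.asarray(pelvic, dtype=float)
    bodyweight = np.asarray(bodyweight, dtype=float)
    if pelvic.shape != bodyweight.shape:
        raise ValueError("pelvic and bodyweight must have equal length")
    if pelvic.size < 10:
        raise ValueError("need at least 10 observations to adjust")
    if np.std(bodyweight) == 0:
        raise ValueError("constant body weight; cannot adjust")
    X = np.column_stack([np.ones_like(bodyweight), bodyweight])
    beta, *_ = np.linalg.lstsq(X, pelvic, rcond=None)
    resid = pelvic - X @ beta
    return resid + pelvic.mean()


# ---------------------------------------------------------------------------
# Design-matrix plumbing

def _design(df: pd.DataFrame, predictors, interactions=()) -> tuple:
    """Build (X, names) with intercept, treatment-coded operator, mains,
    and products; raises on rank deficiency naming offending columns."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    dropped: list[str] = []
    for p in predictors:
        if p not in df.columns:
            raise ValueError(f"missing predictor column {p!r}")
        if p == "operator":
            levels = sorted(pd.unique(df[p].astype(str)))
            if len(levels) == 1:
                warnings.warn("operator has a single level; term dropped")
                dropped.append("operator")
                continue
            for lev in levels[1:]:  # reference = first level alphabetically
                cols.append((df[p].astype(str) == lev).to_numpy(float))
                names.append(f"operator[{lev}]")
        else:
            cols.append(df[p].to_numpy(dtype=float))
            names.append(p)
    for a, b in interactions:
        cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a collinear culprit: smallest singular direction
        _, _, vt = np.linalg.svd(X - X.mean(0, keepdims=True) * 0)
        worst = np.argsort(np.abs(vt[-1]))[::-1][:2]
        raise ValueError(
            "design matrix is rank deficient; collinear columns include "
            + ", ".join(names[i] for i in worst))
    return X, names, dropped


# ---------------------------------------------------------------------------
# Fitters

def fit_linear(y, X, names=None) -> RegressionResult:
    """OLS with intercept-bearing design X, classical SEs and t-tests."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    res = sm.OLS(y, X).fit()
    names = list(names) if names is not None else [f"b{i}" for i in range(X.shape[1])]
    return RegressionResult(
        family="linear", terms=names,
        params=np.asarray(res.params), se=np.asarray(res.bse),
        statistic=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
        n=int(res.nobs), loglik=float(res.llf),
        residuals=np.asarray(res.resid), converged=True)


def fit_logistic(y, X, names=None) -> RegressionResult:
    """ML logistic fit with Wald SEs; perfect separation is flagged."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # hard separation: Newton Hessian is singular; BFGS still
            # reports the boundary-drifting coefficients
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="bfgs")
            separation = True
        separation = separation or any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught)
    # fitted probabilities pinned at 0/1 also indicate separation
    fitted = res.predict(X)
    if np.all((fitted > 0.999) == (y > 0.5)) and np.all(
            (fitted < 0.001) == (y < 0.5)):
        separation = True
    if separation:
        warnings.warn("perfect separation detected; coefficients at boundary")
    names = list(names) if names is not None else [f"b{i}" for i in range(X.shape[1])]
    return RegressionResult(
        family="logistic", terms=names,
        params=np.asarray(res.params), se=np.asarray(res.bse),
        statistic=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
        n=int(res.nobs), loglik=float(res.llf),
        residuals=np.asarray(res.resid_response),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation)


def _censored_poisson_nll_grad(beta, y, X, cens, censor_point):
    eta = X @ beta
    eta = np.clip(eta, -30, 30)
    lam = np.exp(eta)
    unc = ~cens
    ll = float(np.sum(y[unc] * eta[unc] - lam[unc]
                      - special.gammaln(y[unc] + 1.0)))
    score_w = np.empty_like(lam)
    score_w[unc] = y[unc] - lam[unc]
    if cens.any():
        lam_c = lam[cens]
        sf = stats.poisson.sf(censor_point - 1, lam_c)  # P(Y >= c)
        sf = np.maximum(sf, 1e-300)
        ll += float(np.sum(np.log(sf)))
        # d/d lam P(Y >= c) = pmf(c-1; lam); chain through lam = e^eta
        pmf = stats.poisson.pmf(censor_point - 1, lam_c)
        score_w[cens] = lam_c * pmf / sf
    grad = X.T @ score_w
    return -ll, -grad


def fit_censored_poisson(y, censored, X, censor_point: int,
                         names=None) -> RegressionResult:
    """Right-censored Poisson regression with log link.

    Counts flagged ``censored`` contribute P(Y >= censor_point) to the
    likelihood; with no flags set the fit is exactly ordinary Poisson
    regression.  Wald SEs come from the numerically observed
    information at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if np.any(cens & (y != censor_point)):
        raise ValueError(
            f"censored flags only allowed where y == {censor_point}")
    if cens.all():
        raise ValueError("all observations censored; model not identifiable")

    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(max(y.mean(), 0.1))
    res = optimize.minimize(
        _censored_poisson_nll_grad, beta0, args=(y, X, cens, censor_point),
        jac=True, method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
    beta = res.x

    def nll(b):
        return _censored_poisson_nll_grad(b, y, X, cens, censor_point)[0]

    from .association_stats import _num_hessian

    H = _num_hessian(nll, beta, eps=1e-5)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    names = list(names) if names is not None else [f"b{i}" for i in range(X.shape[1])]
    lam = np.exp(np.clip(X @ beta, -30, 30))
    return RegressionResult(
        family="censored_poisson", terms=names,
        params=beta, se=se, statistic=zstat, pvalues=pvals,
        n=int(y.size), loglik=float(-res.fun),
        residuals=y - lam, converged=bool(res.success))


# ---------------------------------------------------------------------------
# The study's two model surfaces

def _filter_timepoint(df: pd.DataFrame, timepoint: str | None) -> pd.DataFrame:
    if timepoint is None or "timepoint" not in df.columns:
        return df
    out = df[df["timepoint"] == timepoint]
    if out.empty:
        raise ValueError(f"no records at timepoint {timepoint!r}")
    return out


def damage_model(
    records: pd.DataFrame,
    response: str,
    family: str = "linear",
    timepoint: str | None = None,
    censor_point: int = 4,
) -> RegressionResult:
    """Per-age regression of a keel-damage response on radiographic
    predictors (operator, tibiotarsal, keel, xlm, bodyweight).

    ``records`` is a tidy frame with one row per bird at the requested
    timepoint, holding the response column, ``operator`` and the four
    radiographic predictor columns.  Coefficients are reported in the
    fixed order intercept, operator, tibiotarsal, keel, xlm, bodyweight.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    df = _filter_timepoint(records, timepoint)
    need = [response, "operator", *DAMAGE_PREDICTORS]
    absent = [c for c in need if c not in df.columns]
    if absent:
        raise ValueError(f"missing predictor/response columns {absent}")
    df = df.dropna(subset=need)
    X, names, dropped = _design(df, ("operator", *DAMAGE_PREDICTORS))
    y = df[response].to_numpy(dtype=float)
    if family == "linear":
        out = fit_linear(y, X, names)
    elif family == "logistic":
        out = fit_logistic(y, X, names)
    else:
        cens = (df["fracture_censored"].to_numpy(bool)
                if "fracture_censored" in df.columns
                else np.zeros(len(df), bool))
        out = fit_censored_poisson(y, cens, X, censor_point, names)
    out.dropped_terms = dropped
    return out


PELVIC_VARIABLES = ("pelvic_width", "pelvic_depth", "pelvic_capacity")


def validate_pelvic_capacity(df: pd.DataFrame, tol: float = 1e-6) -> None:
    """Capacity must equal width x depth (relative tolerance)."""
    need = {"pelvic_width", "pelvic_depth", "pelvic_capacity"}
    if not need <= set(df.columns):
        return
    expected = df["pelvic_width"] * df["pelvic_depth"]
    bad = np.abs(df["pelvic_capacity"] - expected) > tol * np.maximum(1.0, expected)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have pelvic_capacity inconsistent with "
            "pelvic_width x pelvic_depth")


def pelvic_model(
    records: pd.DataFrame,
    response: str,
    pelvic_variable: str = "all",
    family: str = "linear",
    adjust_bodyweight: bool = True,
    timepoint: str | None = None,
):
    """Keel condition on a pelvic dimension with the pelvic x tibiotarsal
    interaction.

    Each pelvic dimension is first residualised on body weight (the two
    correlate about 0.65).  ``pelvic_variable="all"`` fits all three
    dimensions and returns a dict keyed by variable name.
    """
    if pelvic_variable == "all":
        return {v: pelvic_model(records, response, v, family,
                                adjust_bodyweight, timepoint)
                for v in PELVIC_VARIABLES}
    if pelvic_variable not in PELVIC_VARIABLES:
        raise ValueError(f"pelvic_variable must be 'all' or one of "
                         f"{PELVIC_VARIABLES}")
    df = _filter_timepoint(records, timepoint)
    need = [response, "operator", pelvic_variable, "tibiotarsal"]
    if adjust_bodyweight:
        need.append("bodyweight")
    df = df.dropna(subset=need).copy()
    validate_pelvic_capacity(df)
    if adjust_bodyweight:
        df[pelvic_variable] = adjust_for_bodyweight(
            df[pelvic_variable].to_numpy(float),
            df["bodyweight"].to_numpy(float))
    X, names, dropped = _design(
        df, ("operator", pelvic_variable, "tibiotarsal"),
        interactions=[(pelvic_variable, "tibiotarsal")])
    y = df[response].to_numpy(dtype=float)
    if family == "linear":
        out = fit_linear(y, X, names)
    elif family == "logistic":
        out = fit_logistic(y, X, names)
    else:
        raise ValueError("pelvic model supports linear or logistic families")
    out.dropped_terms = dropped
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Optional BH-adjusted p-values for cross-model summaries."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
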