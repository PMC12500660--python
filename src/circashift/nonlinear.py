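"""Nonlinearity screening and breakpoint (segmented) regression.

A generalized additive model with penalized cubic B-spline smooths screens
each continuous predictor of the selected GLMs for nonlinearity: smoothing
parameters are chosen by generalized cross-validation, and a term is flagged
nonlinear when its effective degrees of freedom (EDoF, the trace of the
term's smoother matrix) are substantially above 1 (default > 1.2) with a
significant smooth (p < 0.05).

Demand variables that screen nonlinear then get a continuous two-segment
("broken-stick") fit: for each candidate breakpoint c the mean is
``b0 + b1*x + b2*max(0, x - c)`` (continuous at c by construction); the
candidate minimizing the SSE over an exhaustive grid of observed x values
wins.  The below-segment slope is ``b1``, the above-segment slope
``b1 + b2``, and the hinge coefficient ``b2`` is the structural-change
(slope-contrast) test statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "SmoothTermResult",
    "GAMFit",
    "BreakpointFit",
    "fit_gam",
    "fit_piecewise",
    "slope_contrast",
    "EDOF_FLAG",
    "ALPHA_LEVEL",
]

EDOF_FLAG = 1.2       # EDoF "substantially > 1" convention
ALPHA_LEVEL = 0.05
DEFAULT_BASIS_DF = 10


@dataclass(frozen=True)
class SmoothTermResult:
    """One smooth term of a fitted GAM."""

    term: str
    edof: float
    p: float
    basis_df: int
    alpha: float     # selected smoothing penalty weight

    @property
    def nonlinear(self) -> bool:
        return self.edof > EDOF_FLAG and self.p < ALPHA_LEVEL


@dataclass
class GAMFit:
    """Per-term smooth results plus whole-model summaries."""

    terms: list[SmoothTermResult]
    pseudo_r2: float
    gcv: float
    total_edof: float
    sm_result: object = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"term": t.term, "edof": t.edof, "p": t.p, "basis_df": t.basis_df,
             "alpha": t.alpha, "nonlinear": t.nonlinear}
            for t in self.terms])


def fit_gam(cohort: pd.DataFrame, outcome: str, smooth_terms: Sequence[str],
            factor_terms: Sequence[str] = (), family: str = "gaussian",
            basis_df: int = DEFAULT_BASIS_DF,
            alphas: Sequence[float] | None = None) -> GAMFit:
    """Penalized-spline GAM with GCV-selected smoothing parameters.

    ``smooth_terms`` are continuous predictors (cubic B-spline basis of size
    ``basis_df`` each); ``factor_terms`` enter as unpenalized 0/1 columns.
    Passing ``alphas`` fixes the penalty weights instead of selecting them
    by GCV (used e.g. to check the linear limit as the penalty grows).
    """
    n = len(cohort)
    if n < 30:
        raise ValueError("GAM screening needs at least 30 observations")
    y = cohort[outcome].astype(float).to_numpy()
    xs = cohort[list(smooth_terms)].astype(float).to_numpy()
    # discrete scores with few distinct values get a correspondingly
    # smaller spline basis; below 5 levels a smooth is not identifiable
    dfs = []
    for j, name in enumerate(smooth_terms):
        n_unique = len(np.unique(xs[:, j]))
        if n_unique < 5:
            raise ValueError(
                f"smooth term {name!r} has only {n_unique} distinct values; "
                "basis would be rank-deficient — use a factor term instead")
        dfs.append(min(basis_df, n_unique - 1))
    exog = np.ones((n, 1))
    exog_names = ["intercept"]
    for name in factor_terms:
        exog = np.column_stack([exog, cohort[name].astype(float).to_numpy()])
        exog_names.append(name)

    fam = (sm.families.Gaussian() if family == "gaussian"
           else sm.families.Poisson(sm.families.links.Log()))
    smoother = BSplines(xs, df=dfs, degree=[3] * len(smooth_terms))
    if alphas is None:
        model = GLMGam(y, exog=exog, smoother=smoother,
                       alpha=[1.0] * len(smooth_terms), family=fam)
        # statsmodels 0.14 reads self.scale before the first fit inside
        # select_penweight; pre-seed the attributes it restores afterwards.
        for attr, val in (("scale", 1.0), ("scaletype", None)):
            if not hasattr(model, attr):
                setattr(model, attr, val)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alphas, _, _ = model.select_penweight(criterion="gcv")
    res = GLMGam(y, exog=exog, smoother=smoother, alpha=alphas, family=fam).fit()

    terms = []
    edf = np.asarray(res.edf, dtype=float)
    k0 = exog.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(smooth_terms):
            ncol = smoother.smoothers[i].basis.shape[1]
            term_edof = float(edf[k0:k0 + ncol].sum())
            tt = res.test_significance(i)
            pval = float(np.atleast_1d(tt.pvalue)[0])
            terms.append(SmoothTermResult(term=name, edof=term_edof, p=pval,
                                          basis_df=dfs[i],
                                          alpha=float(alphas[i])))
            k0 += ncol

    dev = float(res.deviance)
    null_dev = float(res.null_deviance)
    pr2 = 1.0 - dev / null_dev if null_dev > 0 else np.nan
    total_edof = float(edf.sum())
    resid = y - np.asarray(res.fittedvalues, dtype=float)
    gcv = n * float((resid ** 2).sum()) / (n - total_edof) ** 2
    return GAMFit(terms=terms, pseudo_r2=pr2, gcv=gcv,
                  total_edof=total_edof, sm_result=res)


# ---------------------------------------------------------------------------
# piecewise (broken-stick) regression
# ---------------------------------------------------------------------------

@dataclass
class BreakpointFit:
    """Continuous hinge fit: mean = b0 + b1*x + b2*max(0, x - breakpoint)."""

    breakpoint: float
    intercept: float
    slope_below: float
    p_below: float
    slope_above: float
    p_above: float
    hinge_coef: float
    hinge_se: float
    sse: float
    profile: pd.DataFrame         # candidate breakpoint -> SSE
    coef: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    n: int = 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope_below * x
                + self.hinge_coef * np.maximum(0.0, x - self.breakpoint))


def _hinge_ols(x: np.ndarray, y: np.ndarray, c: float):
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    return coef, sse, X


def fit_piecewise(x: Sequence[float], y: Sequence[float],
                  grid: Sequence[float] | None = None,
                  min_side: int = 10,
                  trim: tuple[float, float] = (5.0, 95.0)) -> BreakpointFit:
    """Exhaustive-grid breakpoint search for the continuous hinge model.

    The default candidate grid is every distinct observed x between the 5th
    and 95th percentiles; candidates leaving fewer than ``min_side`` points
    strictly on either side are dropped.  Segment slopes get Wald p-values
    (the above-segment slope via the linear combination b1 + b2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        lo, hi = np.percentile(x, trim)
        grid = np.unique(x[(x >= lo) & (x <= hi)])
    candidates = [c for c in np.asarray(grid, dtype=float)
                  if (x < c).sum() >= min_side and (x > c).sum() >= min_side]
    if not candidates:
        raise ValueError(
            f"no candidate breakpoint leaves >= {min_side} points on each side")

    sses = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        _, sses[i], _ = _hinge_ols(x, y, c)
    best = int(np.argmin(sses))
    c_star = float(candidates[best])
    coef, sse, X = _hinge_ols(x, y, c_star)

    n, p = X.shape
    dof = n - p
    sigma2 = sse / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2 * XtX_inv
    se_below = float(np.sqrt(max(cov[1, 1], 0.0)))
    var_above = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
    se_above = float(np.sqrt(max(var_above, 0.0)))
    se_hinge = float(np.sqrt(max(cov[2, 2], 0.0)))

    def wald_p(est, se):
        if se == 0:   # zero residual variance: exact fit up to rounding
            return 0.0 if abs(est) > 1e-8 else 1.0
        return float(2 * stats.t.sf(abs(est / se), dof))

    slope_below = float(coef[1])
    slope_above = float(coef[1] + coef[2])
    return BreakpointFit(
        breakpoint=c_star,
        intercept=float(coef[0]),
        slope_below=slope_below,
        p_below=wald_p(slope_below, se_below),
        slope_above=slope_above,
        p_above=wald_p(slope_above, se_above),
        hinge_coef=float(coef[2]),
        hinge_se=se_hinge,
        sse=sse,
        profile=pd.DataFrame({"breakpoint": candidates, "sse": sses}),
        coef=coef, cov=cov, n=n,
    )


def slope_contrast(fit: BreakpointFit) -> tuple[float, float]:
    """Structural-change Wald test on the hinge coefficient (slope change).

    Returns (t statistic, two-sided p).  A zero hinge coefficient means the
    two segment slopes coincide.
    """
    dof = fit.n - 3
    if fit.hinge_se == 0:
        exact_zero = abs(fit.hinge_coef) <= 1e-8
        return (0.0 if exact_zero else np.inf, 1.0 if exact_zero else 0.0)
    t = fit.hinge_coef / fit.hinge_se
    return float(t), float(2 * stats.t.sf(abs(t), dof))
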