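"""Moderated generalized linear models for sleep quality and depression.

For each outcome (PSQI total, PHQ-9 total) three candidate GLMs are compared;
they share the main-effect set (the other symptom score, circadian type
scores FR/LV, the three shift-demand variables, and confounders) and differ
in which shift-demand variable acts as the *moderator*, i.e. enters the
interaction terms: total night shift count, shift work hours, or shift
workload exposure.  Candidates are ranked by AIC (then BIC, then pseudo R^2).

Continuous predictors are Yeo-Johnson transformed and z-scored via a
:class:`~circashift.preprocess.TransformRecipe`; interactions are products of
the standardized mains, so coefficients are on a standardized scale.  The
outcome stays on its raw count scale under a log link (Poisson family by
default; the score intercepts then sit near the log of the outcome medians).

``REFERENCE_COEFS`` holds the standardized coefficient sets of the optimal
(shift-work-hours-moderated) models reported for the motivating shift-nurse
cohort; they are the generative truth for the parameter-recovery simulations
in :mod:`circashift.synthetic` and the default predictive functions for
:mod:`circashift.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import TransformRecipe

__all__ = [
    "ModelSpec",
    "FittedGLM",
    "build_design",
    "fit_glm",
    "vif",
    "compare_candidates",
    "residual_diagnostics",
    "candidate_specs",
    "psqi_model_spec",
    "phq9_model_spec",
    "REFERENCE_COEFS",
    "OUTCOME_SUPPORT",
]

#: Instrument score ranges used for clipping model output.
OUTCOME_SUPPORT = {"psqi": (0, 21), "phq9": (0, 27)}

MODERATORS = ("night_count", "shift_work_hours", "shift_workload_exposure")

#: Standardized coefficient sets of the optimal moderated models (generative
#: truth for recovery simulations; interaction keys are "a:b" products).
REFERENCE_COEFS: dict[str, dict[str, float]] = {
    "psqi": {
        "intercept": 2.114,
        "gender": -0.064,
        "phq9": 0.245,
        "shift_work_hours": 0.093,
        "phq9:shift_work_hours": -0.047,
        "lv": 0.065,
        "phq9:lv": -0.035,
        "shift_work_hours:lv": 0.014,
        "night_count": -0.050,
        "shift_workload_exposure": 0.002,
        "age": 0.022,
        "bmi": -0.056,
        "day_workload_exposure": 0.062,
        "fr": 0.042,
    },
    "phq9": {
        "intercept": 1.809,
        "gender": 0.075,
        "psqi": 0.314,
        "fr": -0.129,
        "psqi:fr": 0.091,
        "lv": 0.159,
        "psqi:lv": 0.004,
        "shift_work_hours": -0.054,
        "psqi:shift_work_hours": -0.008,
        "fr:shift_work_hours": -0.020,
        "lv:shift_work_hours": 0.069,
        "age": 0.009,
        "night_count": 0.028,
        "shift_workload_exposure": 0.008,
        "day_workload_exposure": -0.083,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate moderated GLM."""

    outcome: str
    mains: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    moderator: str
    family: str = "poisson"            # "poisson" (log) or "gaussian" (identity)
    binary: tuple[str, ...] = ("gender",)

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.mains or b not in self.mains:
                raise ValueError(f"interaction ({a}, {b}) references undeclared mains")
        if self.moderator not in self.mains:
            raise ValueError(f"moderator {self.moderator!r} must be a declared main term")

    @property
    def terms(self) -> list[str]:
        return list(self.mains) + [f"{a}:{b}" for a, b in self.interactions]


def psqi_model_spec(moderator: str = "shift_work_hours", family: str = "poisson") -> ModelSpec:
    """Candidate sleep-quality model: PHQ-9 and LV interact with the moderator."""
    return ModelSpec(
        outcome="psqi",
        mains=("gender", "phq9", "shift_work_hours", "lv", "night_count",
               "shift_workload_exposure", "age", "bmi", "day_workload_exposure", "fr"),
        interactions=(("phq9", moderator), ("phq9", "lv"), (moderator, "lv")),
        moderator=moderator,
        family=family,
    )


def phq9_model_spec(moderator: str = "shift_work_hours", family: str = "poisson") -> ModelSpec:
    """Candidate depression model: PSQI, FR and LV interact with the moderator."""
    return ModelSpec(
        outcome="phq9",
        mains=("gender", "psqi", "fr", "lv", "shift_work_hours", "age",
               "night_count", "shift_workload_exposure", "day_workload_exposure"),
        interactions=(("psqi", "fr"), ("psqi", "lv"), ("psqi", moderator),
                      ("fr", moderator), ("lv", moderator)),
        moderator=moderator,
        family=family,
    )


def candidate_specs(outcome: str, family: str = "poisson") -> dict[str, ModelSpec]:
    """The three candidate models (one per moderator) for an outcome."""
    builder = psqi_model_spec if outcome == "psqi" else phq9_model_spec
    return {m: builder(moderator=m, family=family) for m in MODERATORS}


def build_design(cohort: pd.DataFrame, spec: ModelSpec, recipe: TransformRecipe
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (named columns, no intercept) and outcome vector.

    Continuous mains pass through the recipe (fence/impute/YJ/z); binary
    mains are coded 0/1 as-is; interactions are elementwise products of the
    standardized mains.
    """
    missing = [v for v in (*spec.mains, spec.outcome) if v not in cohort.columns]
    if missing:
        raise KeyError(f"cohort missing model variables: {missing}")
    cols = {}
    for name in spec.mains:
        if name in spec.binary:
            cols[name] = cohort[name].astype(float).to_numpy()
        else:
            if name not in recipe.columns:
                raise KeyError(f"transform recipe has no entry for predictor {name!r}")
            col = cohort[name].astype(float)
            cr = recipe.columns[name]
            col = col.mask((col < cr.fence_lo) | (col > cr.fence_hi)).fillna(cr.impute_value)
            cols[name] = cr.transform(col.to_numpy())
    for a, b in spec.interactions:
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    X = pd.DataFrame(cols, index=cohort.index)
    y = cohort[spec.outcome].astype(float)
    return X, y


@dataclass
class FittedGLM:
    """A fitted candidate model with its coefficient table and diagnostics."""

    spec: ModelSpec
    params: pd.DataFrame          # term, beta, se, z, p, ci_low, ci_high
    llf: float
    aic: float
    bic: float
    pseudo_r2: float
    vif: pd.Series
    recipe: TransformRecipe
    n: int
    k: int                        # number of estimated parameters
    sm_result: object = None      # statsmodels GLMResults (not serialized)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.params["term"], self.params["beta"]))

    def coefficient_table(self) -> pd.DataFrame:
        return self.params.copy()


_FAMILIES = {
    "poisson": lambda: sm.families.Poisson(sm.families.links.Log()),
    "gaussian": lambda: sm.families.Gaussian(sm.families.links.Identity()),
    "gaussian-log": lambda: sm.families.Gaussian(sm.families.links.Log()),
}


def fit_glm(X: pd.DataFrame, y: pd.Series, family: str = "poisson",
            spec: ModelSpec | None = None, recipe: TransformRecipe | None = None,
            pseudo_r2: str = "deviance", cov_type: str = "nonrobust") -> FittedGLM:
    """Fit a GLM by IRLS and assemble the coefficient/diagnostic bundle.

    ``pseudo_r2``: "deviance" (1 - deviance/null deviance, default) or
    "mcfadden" (1 - llf/llf_null).
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors plus intercept")
    const = X.to_numpy().std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant non-intercept columns: {list(X.columns[const])}")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; options: {sorted(_FAMILIES)}")
    Xc = sm.add_constant(X, prepend=True)
    model = sm.GLM(np.asarray(y, dtype=float), Xc, family=_FAMILIES[family]())
    try:
        res = model.fit(maxiter=100, tol=1e-8, cov_type=cov_type)
    except Exception as exc:   # pragma: no cover - non-convergence path
        raise RuntimeError(f"GLM IRLS failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"GLM IRLS did not converge in {res.fit_history['iteration']} iterations")

    terms = ["intercept"] + list(X.columns)
    ci = res.conf_int()
    params = pd.DataFrame({
        "term": terms,
        "beta": np.asarray(res.params, dtype=float),
        "se": np.asarray(res.bse, dtype=float),
        "z": np.asarray(res.tvalues, dtype=float),
        "p": np.asarray(res.pvalues, dtype=float),
        "ci_low": np.asarray(ci)[:, 0],
        "ci_high": np.asarray(ci)[:, 1],
    })
    k = len(terms) + (1 if family.startswith("gaussian") else 0)  # + scale param
    llf = float(res.llf)
    null_dev = float(res.null_deviance)
    if pseudo_r2 == "deviance":
        pr2 = 1.0 - float(res.deviance) / null_dev if null_dev > 0 else np.nan
    elif pseudo_r2 == "mcfadden":
        pr2 = 1.0 - llf / float(res.llnull)
    else:
        raise ValueError(f"unknown pseudo_r2 definition {pseudo_r2!r}")
    return FittedGLM(
        spec=spec, params=params, llf=llf,
        aic=-2 * llf + 2 * k, bic=-2 * llf + k * np.log(n),
        pseudo_r2=pr2, vif=vif(X), recipe=recipe, n=n, k=k, sm_result=res,
    )


VIF_CAP = 1e6


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from auxiliary OLS of each column on the rest.

    The auxiliary regressions include an intercept; a VIF above ``VIF_CAP``
    (e.g. a duplicated column) is reported as ``inf``.
    """
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    out = {}
    for j, name in enumerate(X.columns, start=1):
        yj = A[:, j]
        Aj = np.delete(A, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(Aj, yj, rcond=None)
        resid = yj - Aj @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / tss if tss > 0 else 0.0
        out[name] = np.inf if r2 >= 1 - 1 / VIF_CAP else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def compare_candidates(fits: Mapping[str, FittedGLM]) -> tuple[pd.DataFrame, str]:
    """Rank candidate fits by AIC, then BIC, then pseudo R^2, then fewer params.

    Returns the comparison table (best first) and the selected candidate key.
    """
    rows = [{"candidate": name, "moderator": f.spec.moderator if f.spec else name,
             "aic": f.aic, "bic": f.bic, "pseudo_r2": f.pseudo_r2,
             "llf": f.llf, "k": f.k, "n": f.n}
            for name, f in fits.items()]
    table = pd.DataFrame(rows)
    table = table.sort_values(by=["aic", "bic", "pseudo_r2", "k"],
                              ascending=[True, True, False, True],
                              kind="mergesort").reset_index(drop=True)
    return table, str(table.loc[0, "candidate"])


def _sign_runs_p(signs: np.ndarray) -> float:
    """Wald-Wolfowitz runs test on residual signs (misspecification screen)."""
    signs = signs[signs != 0]
    n1, n2 = int((signs > 0).sum()), int((signs < 0).sum())
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int((np.diff(signs) != 0).sum())
    mu = 1 + 2 * n1 * n2 / (n1 + n2)
    var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def residual_diagnostics(fit: FittedGLM) -> dict:
    """Deviance-residual diagnostics: residual-vs-fitted, QQ pairs, runs test.

    The residual-vs-fitted table is sorted by fitted value so a U-shaped
    (misspecification) trend shows up as too few sign runs.
    """
    res = fit.sm_result
    fitted = np.asarray(res.fittedvalues, dtype=float)
    dev = np.asarray(res.resid_deviance, dtype=float)
    order = np.argsort(fitted)
    rvf = pd.DataFrame({"fitted": fitted[order], "deviance_residual": dev[order]})
    qq = stats.probplot(dev, dist="norm")
    qq_pairs = pd.DataFrame({"theoretical": qq[0][0], "empirical": qq[0][1]})
    slope, intercept = qq[1][0], qq[1][1]
    return {
        "residual_vs_fitted": rvf,
        "qq": qq_pairs,
        "qq_slope": float(slope),
        "qq_intercept": float(intercept),
        "sign_runs_p": _sign_runs_p(np.sign(rvf["deviance_residual"].to_numpy())),
    }
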