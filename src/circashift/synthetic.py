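"""Synthetic shift-nurse cohorts, shift logs, and unit census tables.

The study data behind this pipeline are not deposited, so every downstream
stage is exercised against synthetic cohorts with the published statistical
structure:

* **descriptive mode** — a Gaussian copula draws a latent multivariate
  normal, converts each margin through its quantile function onto a bounded
  (discrete) instrument scale, and targets the published Spearman
  correlations via the exact bivariate-normal identity
  ``r_latent = 2 sin(pi * rho_s / 6)``.
* **model mode** — covariates come from the copula, the outcome is drawn
  from a declared GLM (standardized linear predictor -> inverse link ->
  count noise), so refitting the model tests parameter recovery against a
  known truth.
* **piecewise mode** — a continuous two-segment (broken-stick) dose-response
  in shift work hours with Gaussian noise, for breakpoint-recovery tests.
* **shift-log mode** — four-week rosters (long nights 18:00-08:00 with a
  three-hour nap, evenings 18:00-24:00, day shifts) plus a unit census table,
  for the workload metrics.

Bounded marginals are scaled beta distributions discretized to the
instrument grid; ``(alpha, beta)`` are solved numerically from two published
targets per variable (median + IQR, or a screening-prevalence CDF point +
IQR when a prevalence is published for that instrument).
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import glm as _glm
from .preprocess import TransformRecipe

__all__ = [
    "MarginalSpec",
    "DependenceSpec",
    "GenerativeGLMSpec",
    "PiecewiseSpec",
    "ScheduleConfig",
    "ConfigurationError",
    "default_marginals",
    "default_dependence",
    "default_glm_spec",
    "default_piecewise_spec",
    "generate_descriptive",
    "generate_model_mode",
    "generate_piecewise_mode",
    "generate_shift_log",
    "spearman_to_latent",
    "nearest_psd",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (bad marginals, dependence, or terms)."""


def spearman_to_latent(rho_s: float | np.ndarray) -> float | np.ndarray:
    """Latent-normal Pearson correlation targeting a Spearman rho (exact for
    the bivariate normal copula): ``r = 2 sin(pi * rho_s / 6)``."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def latent_to_spearman(r: float | np.ndarray) -> float | np.ndarray:
    return 6.0 / np.pi * np.arcsin(np.asarray(r) / 2.0)


# ---------------------------------------------------------------------------
# marginals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalSpec:
    """One bounded marginal distribution.

    ``kind``:
      * ``"beta"`` — beta scaled to [lo, hi], optionally discretized by
        rounding; two calibration targets pin (alpha, beta): the IQR plus
        either the median or a CDF point ``cdf_point=(cut, prob)`` (used for
        instruments whose screening prevalence is published — the prevalence
        pins the CDF at the cutoff half-integer more sharply than the
        median alone).
      * ``"bernoulli"`` — 0/1 with P(1) = ``p_one``.
      * ``"uniform-int"`` — discrete uniform on [lo, hi].
    """

    name: str
    lo: float
    hi: float
    median: float | None = None
    iqr: float | None = None
    kind: str = "beta"
    discrete: bool = True
    cdf_point: tuple[float, float] | None = None
    p_one: float | None = None

    def __post_init__(self) -> None:
        if self.lo >= self.hi and self.kind != "bernoulli":
            raise ConfigurationError(f"{self.name}: lo must be < hi")
        if self.kind == "beta":
            if self.iqr is None or self.iqr < 0 or self.iqr > self.hi - self.lo:
                raise ConfigurationError(f"{self.name}: IQR must be in [0, hi-lo]")
            if self.cdf_point is None:
                if self.median is None or not (self.lo <= self.median <= self.hi):
                    raise ConfigurationError(
                        f"{self.name}: median must lie within [{self.lo}, {self.hi}]")
        if self.kind == "bernoulli" and not (0 < (self.p_one or 0) < 1):
            raise ConfigurationError(f"{self.name}: bernoulli needs p_one in (0,1)")

    def beta_params(self) -> tuple[float, float]:
        """Solve (alpha, beta) from the two calibration targets (cached)."""
        return _solve_beta(self.lo, self.hi, self.median, self.iqr,
                           self.cdf_point, self.name)

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Map uniforms (copula probabilities) onto the marginal's support."""
        if self.kind == "bernoulli":
            return (u > 1.0 - self.p_one).astype(float)
        if self.kind == "uniform-int":
            k = np.floor(u * (self.hi - self.lo + 1))
            return np.clip(self.lo + k, self.lo, self.hi)
        a, b = self.beta_params()
        x = self.lo + (self.hi - self.lo) * stats.beta.ppf(u, a, b)
        if self.discrete:
            x = np.round(x)
        return np.clip(x, self.lo, self.hi)


@functools.lru_cache(maxsize=None)
def _solve_beta(lo: float, hi: float, median: float | None, iqr: float,
                cdf_point: tuple[float, float] | None, name: str
                ) -> tuple[float, float]:
    span = hi - lo

    def equations(logp):
        a, b = np.exp(logp)
        q1, q2, q3 = stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        eq_iqr = span * (q3 - q1) - iqr
        if cdf_point is not None:
            cut, prob = cdf_point
            eq_loc = stats.beta.cdf((cut - lo) / span, a, b) - prob
        else:
            eq_loc = lo + span * q2 - median
        return [eq_loc, eq_iqr]

    sol, info, ier, msg = optimize.fsolve(
        equations, [np.log(2.0), np.log(2.0)], full_output=True)
    if ier != 1:
        res = optimize.least_squares(equations, sol, method="lm")
        sol = res.x
        if not res.success or np.max(np.abs(res.fun)) > 1e-6:
            raise ConfigurationError(
                f"{name}: could not solve beta parameters ({msg})")
    a, b = np.exp(sol)
    return float(a), float(b)


@dataclass(frozen=True)
class DependenceSpec:
    """Target Spearman correlations for named variable pairs.

    Unspecified cells default to 0 (only significant pairs are published).
    The implied latent matrix is repaired to the nearest PSD matrix by
    eigenvalue clipping; a repair that moves a *specified* pair's Spearman
    by more than ``repair_tol`` raises, naming the offending pairs.
    """

    pairs: tuple[tuple[str, str, float], ...] = ()
    repair_tol: float = 0.10

    def __post_init__(self) -> None:
        for a, b, r in self.pairs:
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"rho({a},{b})={r} outside [-1, 1]")

    def latent_matrix(self, names: Sequence[str]) -> tuple[np.ndarray, list[dict]]:
        idx = {n: i for i, n in enumerate(names)}
        k = len(names)
        R = np.eye(k)
        for a, b, r in self.pairs:
            if a not in idx or b not in idx:
                raise ConfigurationError(f"dependence pair ({a},{b}) names unknown variable")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = spearman_to_latent(r)
        R_psd = nearest_psd(R)
        repair_log = []
        offending = []
        for a, b, r in self.pairs:
            achieved = float(latent_to_spearman(R_psd[idx[a], idx[b]]))
            repair_log.append({"pair": (a, b), "target_spearman": r,
                               "repaired_spearman": achieved})
            if abs(achieved - r) > self.repair_tol:
                offending.append((a, b, r, round(achieved, 4)))
        if offending:
            raise ConfigurationError(
                "dependence matrix not PSD-repairable within tolerance; "
                f"offending pairs (target -> repaired): {offending}")
        return R_psd, repair_log


def nearest_psd(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest positive-semi-definite correlation matrix by eigenvalue
    clipping, rescaled to a unit diagonal."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym
    w_clipped = np.clip(w, eps, None)
    fixed = v @ np.diag(w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# published calibration defaults
# ---------------------------------------------------------------------------

#: PSQI > 7 screens positive for insomnia; PHQ-9 >= 10 for probable depression.
INSOMNIA_CUT = 7.5
DEPRESSION_CUT = 9.5
INSOMNIA_PREVALENCE = 0.5139
DEPRESSION_PREVALENCE = 0.2431
FEMALE_PROPORTION = 0.8958

#: Baseline four-week shift-work demand condition (night count, shift hours,
#: shift workload exposure median) used by the trajectory simulations.
BASELINE_DEMAND = {"night_count": 4.0, "shift_work_hours": 44.0,
                   "shift_workload_exposure": 147.0}


def default_marginals() -> list[MarginalSpec]:
    """Published cohort marginals (medians/IQRs/ranges; prevalence-pinned
    CDF points for PSQI and PHQ-9; gender split 89.58% female)."""
    return [
        MarginalSpec("gender", 0, 1, kind="bernoulli", p_one=FEMALE_PROPORTION),
        MarginalSpec("age", 24, 44, kind="uniform-int"),
        MarginalSpec("bmi", 15.0, 32.0, median=21.5, iqr=3.0, discrete=False),
        MarginalSpec("fr", 5, 25, median=13, iqr=6),
        MarginalSpec("lv", 6, 30, median=18, iqr=6),
        MarginalSpec("psqi", 1, 17, median=8, iqr=4,
                     cdf_point=(INSOMNIA_CUT, 1.0 - INSOMNIA_PREVALENCE)),
        MarginalSpec("phq9", 0, 22, median=7, iqr=5,
                     cdf_point=(DEPRESSION_CUT, 1.0 - DEPRESSION_PREVALENCE)),
        MarginalSpec("night_count", 0, 9, median=4, iqr=2),
        MarginalSpec("shift_work_hours", 0, 96, median=44, iqr=20),
        MarginalSpec("shift_workload_exposure", 0, 400, median=147, iqr=80,
                     discrete=False),
        MarginalSpec("day_workload_exposure", 0, 400, median=120, iqr=60,
                     discrete=False),
    ]


def default_dependence() -> DependenceSpec:
    """Published significant Spearman correlations; all other cells 0."""
    return DependenceSpec(pairs=(
        ("psqi", "phq9", 0.560),
        ("psqi", "lv", 0.356),
        ("psqi", "bmi", -0.122),
        ("phq9", "fr", -0.179),
        ("phq9", "lv", 0.412),
    ))


# ---------------------------------------------------------------------------
# descriptive mode
# ---------------------------------------------------------------------------

def _copula_draw(marginals: Sequence[MarginalSpec], dependence: DependenceSpec,
                 n: int, rng: np.random.Generator) -> tuple[pd.DataFrame, list[dict]]:
    names = [m.name for m in marginals]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate marginal names")
    R, repair_log = dependence.latent_matrix(names)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ L.T
    u = stats.norm.cdf(z)
    data = {m.name: m.quantile(u[:, j]) for j, m in enumerate(marginals)}
    return pd.DataFrame(data), repair_log


def generate_descriptive(
    marginals: Sequence[MarginalSpec] | None = None,
    dependence: DependenceSpec | None = None,
    n: int = 288,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Gaussian-copula cohort with the published marginal/correlation structure.

    Returns (cohort table, provenance record).  Identical (config, seed)
    gives an identical table.
    """
    if n < 10:
        raise ConfigurationError("descriptive mode needs n >= 10")
    marginals = list(marginals) if marginals is not None else default_marginals()
    dependence = dependence if dependence is not None else default_dependence()
    rng = np.random.default_rng(seed)
    table, repair_log = _copula_draw(marginals, dependence, n, rng)
    table.insert(0, "nurse_id", [f"N{i:04d}" for i in range(1, n + 1)])
    provenance = {
        "generator": "circashift.synthetic.generate_descriptive",
        "mode": "descriptive",
        "n": n,
        "seed": seed,
        "marginals": [asdict(m) for m in marginals],
        "dependence": [list(p) for p in dependence.pairs],
        "dependence_repair": repair_log,
    }
    return table, provenance


# ---------------------------------------------------------------------------
# model mode (planted-GLM outcome for parameter recovery)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeGLMSpec:
    """Generative truth for one outcome: a GLM on standardized covariates."""

    outcome: str
    coefficients: Mapping[str, float]     # term -> standardized beta (+ intercept)
    family: str = "poisson"
    support: tuple[float, float] = (0, 21)
    dispersion: float = 1.0               # Gaussian noise SD when family=gaussian

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if "intercept" not in self.coefficients:
            raise ConfigurationError("coefficient set must include an intercept")


def default_glm_spec(outcome: str = "psqi") -> GenerativeGLMSpec:
    """Published optimal-model coefficient set as the generative truth."""
    if outcome not in _glm.REFERENCE_COEFS:
        raise ConfigurationError(f"no reference coefficient set for {outcome!r}")
    return GenerativeGLMSpec(
        outcome=outcome,
        coefficients=dict(_glm.REFERENCE_COEFS[outcome]),
        family="poisson",
        support=_glm.OUTCOME_SUPPORT[outcome],
    )


def _model_spec_for(outcome: str) -> _glm.ModelSpec:
    return (_glm.psqi_model_spec() if outcome == "psqi" else _glm.phq9_model_spec())


def generate_model_mode(
    glm_spec: GenerativeGLMSpec | None = None,
    n: int = 288,
    seed: int = 0,
    marginals: Sequence[MarginalSpec] | None = None,
    dependence: DependenceSpec | None = None,
    outcome: str = "psqi",
) -> tuple[pd.DataFrame, dict]:
    """Cohort whose outcome is drawn from a declared GLM truth.

    Covariates (including a copula-drawn version of the partner symptom
    score) come from descriptive mode with the outcome variable excluded;
    the outcome is then generated conditionally, which avoids the circular
    PSQI<->PHQ-9 definition while preserving each model's recovery test.
    The planted coefficients are recorded in provenance.
    """
    if glm_spec is None:
        glm_spec = default_glm_spec(outcome)
    outcome = glm_spec.outcome
    marginals = list(marginals) if marginals is not None else default_marginals()
    covar_marginals = [m for m in marginals if m.name != outcome]
    if len(covar_marginals) == len(marginals):
        raise ConfigurationError(f"outcome {outcome!r} not among the marginals")
    dependence = dependence if dependence is not None else default_dependence()
    dep_cov = DependenceSpec(
        pairs=tuple(p for p in dependence.pairs if outcome not in p[:2]),
        repair_tol=dependence.repair_tol)

    rng = np.random.default_rng(seed)
    table, repair_log = _copula_draw(covar_marginals, dep_cov, n, rng)

    spec = _model_spec_for(outcome)
    missing = [t for t in spec.mains if t not in table.columns]
    if missing:
        raise ConfigurationError(f"GLM terms reference missing covariates: {missing}")
    continuous = [m for m in spec.mains if m not in spec.binary]
    recipe = TransformRecipe.fit(table, continuous)
    table[outcome] = 0.0   # placeholder so build_design can locate the outcome
    X, _ = _glm.build_design(table, spec, recipe)

    coefs = dict(glm_spec.coefficients)
    unknown = set(coefs) - {"intercept", *X.columns}
    if unknown:
        raise ConfigurationError(f"coefficients name unknown terms: {sorted(unknown)}")
    eta = np.full(n, coefs["intercept"], dtype=float)
    for term, beta in coefs.items():
        if term != "intercept":
            eta = eta + beta * X[term].to_numpy()

    lo, hi = glm_spec.support
    if glm_spec.family == "poisson":
        y = rng.poisson(np.exp(eta)).astype(float)
    elif glm_spec.family == "gaussian":
        y = eta + rng.normal(0.0, glm_spec.dispersion, size=n)
    else:
        raise ConfigurationError(f"unknown generative family {glm_spec.family!r}")
    table[outcome] = np.clip(np.round(y), lo, hi)
    table.insert(0, "nurse_id", [f"N{i:04d}" for i in range(1, n + 1)])

    provenance = {
        "generator": "circashift.synthetic.generate_model_mode",
        "mode": "model",
        "n": n,
        "seed": seed,
        "outcome": outcome,
        "family": glm_spec.family,
        "planted_coefficients": coefs,
        "support": list(glm_spec.support),
        "dependence_repair": repair_log,
    }
    return table, provenance


def refit_planted(table: pd.DataFrame, outcome: str = "psqi",
                  family: str = "poisson") -> _glm.FittedGLM:
    """Refit the reference model structure on a model-mode cohort.

    Uses the same recipe-fitting procedure as generation, so estimates are
    directly comparable with the planted standardized coefficients.
    """
    spec = _model_spec_for(outcome)
    continuous = [m for m in spec.mains if m not in spec.binary]
    recipe = TransformRecipe.fit(table, continuous)
    X, y = _glm.build_design(table, spec, recipe)
    return _glm.fit_glm(X, y, family=family, spec=spec, recipe=recipe)


# ---------------------------------------------------------------------------
# piecewise mode (planted dose-response)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseSpec:
    """Continuous two-segment linear dose-response in a demand variable.

    Default parameters plant the published shift-hours dose-response: a
    breakpoint at 24 h per 4 weeks with slopes -0.221 below and +0.031 above
    on the PSQI scale, Gaussian score noise, x uniform on [0, 80] h.
    """

    x_var: str = "shift_work_hours"
    outcome: str = "psqi"
    breakpoint: float = 24.0
    slope_below: float = -0.221
    slope_above: float = 0.031
    intercept: float = 9.0               # mean outcome at x = 0
    noise_sd: float = 2.0
    x_lo: float = 0.0
    x_hi: float = 80.0
    support: tuple[float, float] = (0, 21)
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        frac_below = (self.breakpoint - self.x_lo) / (self.x_hi - self.x_lo)
        if not 0.2 <= frac_below <= 0.8:
            raise ConfigurationError(
                "breakpoint must leave >= 20% of the x mass on each side")

    def mean(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope_below * x
                + (self.slope_above - self.slope_below)
                * np.maximum(0.0, x - self.breakpoint))


def default_piecewise_spec() -> PiecewiseSpec:
    return PiecewiseSpec()


def generate_piecewise_mode(spec: PiecewiseSpec | None = None, n: int = 288,
                            seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Cohort with a planted broken-stick dose-response (x, outcome columns).

    With ``discretize`` the outcome is rounded/clipped to the instrument
    grid; the exact-recovery (noiseless) oracle requires ``discretize=False``.
    """
    spec = spec if spec is not None else default_piecewise_spec()
    rng = np.random.default_rng(seed)
    x = rng.uniform(spec.x_lo, spec.x_hi, size=n)
    y = spec.mean(x)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.discretize:
        y = np.clip(np.round(y), *spec.support)
    table = pd.DataFrame({
        "nurse_id": [f"N{i:04d}" for i in range(1, n + 1)],
        spec.x_var: x,
        spec.outcome: y,
    })
    provenance = {
        "generator": "circashift.synthetic.generate_piecewise_mode",
        "mode": "piecewise",
        "n": n,
        "seed": seed,
        "spec": asdict(spec),
    }
    return table, provenance


# ---------------------------------------------------------------------------
# shift-log mode (rosters + unit census)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Weekly roster mix over a 28-day window.

    The default emulates the predominant day-night (DN) rotation: one long
    night (18:00-08:00, three-hour nap, 11 net hours) per week plus four
    8-hour day shifts.  An APN-style mix adds evening shifts (18:00-24:00).
    """

    weeks: int = 4
    long_nights_per_week: int = 1
    evenings_per_week: int = 0
    day_shifts_per_week: int = 4
    day_shift: tuple[float, float] = (8.0, 16.0)
    evening_shift: tuple[float, float] = (18.0, 24.0)
    long_night: tuple[float, float] = (18.0, 32.0)   # 18:00 -> 08:00 next day
    nap_hours: float = 3.0
    n_units: int = 6
    window_start: str = "2024-01-01"

    def __post_init__(self) -> None:
        if self.weeks != 4:
            raise ConfigurationError("the observation window is fixed at 4 weeks")
        total = self.long_nights_per_week + self.evenings_per_week + self.day_shifts_per_week
        if total > 7:
            raise ConfigurationError(
                f"{total} shifts per week cannot be placed on distinct days "
                "without overlapping events")


def generate_shift_log(config: ScheduleConfig | None = None, n: int = 288,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-nurse shift events and a matching unit census table.

    Events are non-overlapping per nurse (each shift occupies a distinct
    roster day; all shifts start at or after 08:00 and nights end at 08:00).
    Long nights carry ``nap_hours``.  The census covers every (unit, weekly
    period) so work-intensity metrics are computable for all nurses.
    """
    config = config if config is not None else ScheduleConfig()
    rng = np.random.default_rng(seed)
    start0 = datetime.fromisoformat(config.window_start)
    units = [f"U{k + 1}" for k in range(config.n_units)]

    rows = []
    for i in range(n):
        nurse = f"N{i + 1:04d}"
        unit = units[i % config.n_units]
        for w in range(config.weeks):
            days = rng.permutation(7)
            k = 0
            for _ in range(config.long_nights_per_week):
                d = start0 + timedelta(days=7 * w + int(days[k])); k += 1
                rows.append((nurse,
                             d + timedelta(hours=config.long_night[0]),
                             d + timedelta(hours=config.long_night[1]),
                             config.nap_hours, unit))
            for _ in range(config.evenings_per_week):
                d = start0 + timedelta(days=7 * w + int(days[k])); k += 1
                rows.append((nurse,
                             d + timedelta(hours=config.evening_shift[0]),
                             d + timedelta(hours=config.evening_shift[1]),
                             0.0, unit))
            for _ in range(config.day_shifts_per_week):
                d = start0 + timedelta(days=7 * w + int(days[k])); k += 1
                rows.append((nurse,
                             d + timedelta(hours=config.day_shift[0]),
                             d + timedelta(hours=config.day_shift[1]),
                             0.0, unit))
    events = pd.DataFrame(rows, columns=["nurse_id", "start", "end",
                                         "nap_hours", "unit_id"])
    events = events.sort_values(["nurse_id", "start"]).reset_index(drop=True)

    census_rows = []
    for unit in units:
        for w in range(config.weeks):
            census_rows.append({
                "unit_id": unit,
                "period": f"W{w + 1}",
                "active_nurses": int(rng.integers(8, 16)),
                "assigned_patients": int(rng.integers(30, 50)),
                "cmi": float(np.round(rng.uniform(0.6, 1.6), 3)),
            })
    census = pd.DataFrame(census_rows)
    provenance = {
        "generator": "circashift.synthetic.generate_shift_log",
        "mode": "shift_log",
        "n": n,
        "seed": seed,
        "config": asdict(config),
    }
    return events, census, provenance


def events_from_frame(events: pd.DataFrame):
    """Convert a shift-log table into :class:`~circashift.workload.ShiftEvent`s."""
    from .workload import ShiftEvent
    out = []
    for row in events.itertuples(index=False):
        start = row.start if isinstance(row.start, datetime) else datetime.fromisoformat(str(row.start))
        end = row.end if isinstance(row.end, datetime) else datetime.fromisoformat(str(row.end))
        out.append(ShiftEvent(nurse_id=row.nurse_id, start=start, end=end,
                              nap_hours=float(row.nap_hours), unit_id=row.unit_id))
    return out
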