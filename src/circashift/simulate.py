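"""Monte-Carlo trajectory simulation of sleep quality and depression.

From the two selected GLMs (PSQI and PHQ-9) the engine derives raw-scale
predictive functions (raw covariates -> recipe-standardized terms -> linear
predictor -> inverse link, clipped to the instrument range) and iterates a
coupled daily system for 100 days: each day's predicted PSQI uses yesterday's
smoothed PHQ-9 and fixed covariates/demand, and vice versa; both states are
then updated by exponentially weighted smoothing

    s_t = alpha * prediction_t + (1 - alpha) * s_{t-1},       alpha = 0.2

(20% current, 80% previous) and clipped to the instrument bounds.  Updates
are synchronous: both predictions are computed from the day-(t-1) states
before either state is advanced, so the result does not depend on equation
order.

Population runs bootstrap 1,000 virtual individuals from a cohort;
scenario runs group individuals by circadian adaptability profile
(M / H / L percentile rules on FR and LV) and scale a baseline four-week
demand condition (4 night shifts, 44 shift hours, 147 shift workload
exposure) by dose multipliers.  Trajectories start from the low-symptom
baseline (the minimum observed PSQI = 1 and PHQ-9 = 0).

Threshold crossings are read off the group mean trajectory: PSQI > 7
(insomnia screen) and PHQ-9 >= 10 (probable depression); the per-individual
crossing fraction is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import FittedGLM, OUTCOME_SUPPORT
from .synthetic import BASELINE_DEMAND

__all__ = [
    "SimulationConfig",
    "TrajectorySet",
    "predictive_function",
    "ews_update",
    "simulate_individual",
    "simulate_population",
    "classify_adaptability",
    "scenario_run",
    "crossing_day",
    "INSOMNIA_THRESHOLD",
    "DEPRESSION_THRESHOLD",
    "DEMAND_VARS",
]

INSOMNIA_THRESHOLD = 7.0        # positive when mean PSQI > 7
DEPRESSION_THRESHOLD = 10.0     # positive when mean PHQ-9 >= 10
DEMAND_VARS = ("night_count", "shift_work_hours", "shift_workload_exposure")

PSQI_RANGE = OUTCOME_SUPPORT["psqi"]
PHQ9_RANGE = OUTCOME_SUPPORT["phq9"]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one trajectory run.

    ``demand``: fixed demand condition applied to every individual (None
    keeps each bootstrap individual's own demand columns).  The
    ``demand_multiplier`` scales the three demand variables jointly.
    ``noise`` adds per-day Gaussian prediction noise (off by default: the
    trajectories are mean-field).
    """

    alpha: float = 0.2
    horizon: int = 100
    n_individuals: int = 1000
    init_psqi: float = 1.0      # minimum observed PSQI (low-symptom baseline)
    init_phq9: float = 0.0      # minimum observed PHQ-9
    demand: Mapping[str, float] | None = None
    demand_multiplier: float = 1.0
    seed: int = 0
    noise: bool = False
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("smoothing factor alpha must be in (0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be at least one day")
        if not PSQI_RANGE[0] <= self.init_psqi <= PSQI_RANGE[1]:
            raise ValueError("init_psqi outside the PSQI instrument range")
        if not PHQ9_RANGE[0] <= self.init_phq9 <= PHQ9_RANGE[1]:
            raise ValueError("init_phq9 outside the PHQ-9 instrument range")


def ews_update(previous, predicted, alpha: float):
    """Exponentially weighted smoothing: alpha*predicted + (1-alpha)*previous."""
    return alpha * np.asarray(predicted, dtype=float) \
        + (1.0 - alpha) * np.asarray(previous, dtype=float)


class _Predictor:
    """Raw-scale predictive function with one dynamic covariate.

    Splits the linear predictor into a fixed part (covariates and demand,
    computed once) and the dynamic partner-score part, whose standardized
    value enters the mains and any interaction with fixed terms:
    eta = eta_fixed + z_dyn * w, with w = beta_dyn + sum beta_int * z_other.
    """

    def __init__(self, fit: FittedGLM, dynamic_var: str):
        if fit.spec is None or fit.recipe is None:
            raise ValueError("predictive function needs a fit with spec and recipe")
        self.fit = fit
        self.spec = fit.spec
        self.recipe = fit.recipe
        self.coef = fit.coef
        self.dynamic_var = dynamic_var
        self.support = OUTCOME_SUPPORT[self.spec.outcome]
        if dynamic_var not in self.spec.mains:
            raise ValueError(f"{dynamic_var!r} is not a main term of the model")

    def _z(self, name: str, raw) -> np.ndarray:
        if name in self.spec.binary:
            return np.asarray(raw, dtype=float)
        return np.asarray(self.recipe.transform_value(name, raw, winsorize=True))

    def prepare(self, covariates: pd.DataFrame) -> None:
        """Precompute the fixed-covariate pieces for a set of individuals."""
        z = {}
        for name in self.spec.mains:
            if name == self.dynamic_var:
                continue
            if name not in covariates.columns:
                raise KeyError(f"covariate table missing model term {name!r}")
            z[name] = self._z(name, covariates[name].to_numpy())
        n = len(covariates)
        eta = np.full(n, self.coef["intercept"], dtype=float)
        w = np.full(n, self.coef.get(self.dynamic_var, 0.0), dtype=float)
        for a, b in self.spec.interactions:
            beta = self.coef[f"{a}:{b}"]
            if a == self.dynamic_var:
                w += beta * z[b]
            elif b == self.dynamic_var:
                w += beta * z[a]
            else:
                eta += beta * z[a] * z[b]
        for name, zv in z.items():
            eta += self.coef[name] * zv
        self._eta_fixed, self._w = eta, w

    def predict(self, dynamic_raw) -> np.ndarray:
        """Expected outcome given the current raw partner score(s)."""
        z_dyn = self._z(self.dynamic_var, dynamic_raw)
        eta = self._eta_fixed + z_dyn * self._w
        mu = np.exp(eta) if self.spec.family in ("poisson", "gaussian-log") else eta
        return np.clip(mu, *self.support)


def predictive_function(fit: FittedGLM, dynamic_var: str) -> _Predictor:
    """Build the raw-scale predictor for a fitted GLM.

    ``dynamic_var`` is the partner symptom score updated daily by the
    coupled simulation ("phq9" for the PSQI model and vice versa).  Raw
    covariates outside a recipe's outlier fences are winsorized to the
    fences before transformation.
    """
    return _Predictor(fit, dynamic_var)


@dataclass
class TrajectorySet:
    """Per-day cross-individual summaries of one simulated group."""

    days: np.ndarray
    mean_psqi: np.ndarray
    sd_psqi: np.ndarray
    mean_phq9: np.ndarray
    sd_phq9: np.ndarray
    crossing: dict
    crossing_fraction: dict
    n_individuals: int
    provenance: dict = field(default_factory=dict)

    def to_frame(self, group: str = "", multiplier: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame({
            "group": group, "multiplier": multiplier, "day": self.days,
            "mean_psqi": self.mean_psqi, "sd_psqi": self.sd_psqi,
            "mean_phq9": self.mean_phq9, "sd_phq9": self.sd_phq9,
        })


def crossing_day(trajectory: Sequence[float], threshold: float,
                 direction: str = ">") -> int | None:
    """First 1-based day at which the trajectory crosses a threshold.

    ``direction`` is ">" (PSQI insomnia convention) or ">=" (PHQ-9
    probable-depression convention).  Returns None when never crossed.
    """
    t = np.asarray(trajectory, dtype=float)
    hits = t > threshold if direction == ">" else t >= threshold
    idx = np.flatnonzero(hits)
    return int(idx[0]) + 1 if idx.size else None


def _run_engine(covariates: pd.DataFrame, psqi_fit: FittedGLM,
                phq9_fit: FittedGLM, config: SimulationConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled daily system; returns (horizon, n) score arrays."""
    cov = covariates.reset_index(drop=True).copy()
    if config.demand is not None:
        for name in DEMAND_VARS:
            if name in config.demand:
                cov[name] = float(config.demand[name])
    if config.demand_multiplier != 1.0:
        for name in DEMAND_VARS:
            cov[name] = cov[name].astype(float) * config.demand_multiplier

    p_psqi = predictive_function(psqi_fit, dynamic_var="phq9")
    p_phq9 = predictive_function(phq9_fit, dynamic_var="psqi")
    p_psqi.prepare(cov)
    p_phq9.prepare(cov)

    n = len(cov)
    s_psqi = np.full(n, float(config.init_psqi))
    s_phq9 = np.full(n, float(config.init_phq9))
    psqi_paths = np.empty((config.horizon, n))
    phq9_paths = np.empty((config.horizon, n))
    if config.noise and rng is None:
        rng = np.random.default_rng(config.seed)
    for t in range(config.horizon):
        pred_psqi = p_psqi.predict(s_phq9)   # synchronous: both use day t-1
        pred_phq9 = p_phq9.predict(s_psqi)
        if config.noise:
            pred_psqi = pred_psqi + rng.normal(0.0, config.noise_sd, size=n)
            pred_phq9 = pred_phq9 + rng.normal(0.0, config.noise_sd, size=n)
        s_psqi = np.clip(ews_update(s_psqi, pred_psqi, config.alpha), *PSQI_RANGE)
        s_phq9 = np.clip(ews_update(s_phq9, pred_phq9, config.alpha), *PHQ9_RANGE)
        psqi_paths[t] = s_psqi
        phq9_paths[t] = s_phq9
    return psqi_paths, phq9_paths


def _trajectory_set(psqi_paths: np.ndarray, phq9_paths: np.ndarray,
                    provenance: dict) -> TrajectorySet:
    horizon, n = psqi_paths.shape
    mean_psqi = psqi_paths.mean(axis=1)
    mean_phq9 = phq9_paths.mean(axis=1)
    return TrajectorySet(
        days=np.arange(1, horizon + 1),
        mean_psqi=mean_psqi,
        sd_psqi=psqi_paths.std(axis=1, ddof=0),
        mean_phq9=mean_phq9,
        sd_phq9=phq9_paths.std(axis=1, ddof=0),
        crossing={
            "insomnia": crossing_day(mean_psqi, INSOMNIA_THRESHOLD, ">"),
            "depression": crossing_day(mean_phq9, DEPRESSION_THRESHOLD, ">="),
        },
        crossing_fraction={
            "insomnia": float((psqi_paths > INSOMNIA_THRESHOLD).any(axis=0).mean()),
            "depression": float((phq9_paths >= DEPRESSION_THRESHOLD).any(axis=0).mean()),
        },
        n_individuals=n,
        provenance=provenance,
    )


def simulate_individual(covariates: Mapping[str, float], psqi_fit: FittedGLM,
                        phq9_fit: FittedGLM, config: SimulationConfig,
                        demand: Mapping[str, float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Daily PSQI and PHQ-9 paths for one individual (arrays of length horizon)."""
    cov = dict(covariates)
    if demand is not None:
        cov.update(demand)
    frame = pd.DataFrame([cov])
    psqi_paths, phq9_paths = _run_engine(frame, psqi_fit, phq9_fit, config)
    return psqi_paths[:, 0], phq9_paths[:, 0]


def simulate_population(cohort: pd.DataFrame, psqi_fit: FittedGLM,
                        phq9_fit: FittedGLM, config: SimulationConfig
                        ) -> TrajectorySet:
    """Bootstrap ``n_individuals`` virtual nurses from the cohort and simulate.

    Each virtual individual keeps the covariate row it was resampled from
    (including its own demand variables unless ``config.demand`` overrides
    them).  Seed-reproducible.
    """
    if cohort.empty:
        raise ValueError("cannot simulate from an empty cohort")
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, len(cohort), size=config.n_individuals)
    rows = cohort.iloc[idx]
    paths = _run_engine(rows, psqi_fit, phq9_fit, config, rng=rng)
    provenance = {"engine": "simulate_population", "config": _config_dict(config),
                  "cohort_n": len(cohort)}
    return _trajectory_set(*paths, provenance)


def classify_adaptability(fr: float, lv: float,
                          fr_quartiles: tuple[float, float],
                          lv_quartiles: tuple[float, float]) -> str:
    """Adaptability profile from FR/LV scores and cohort quartiles (P25, P75).

    H (high): flexible and vigorous (FR >= P75, LV <= P25); L (low): rigid
    and languid (FR <= P25, LV >= P75); M (moderate): both scores within the
    interquartile band.  Everything else is UNCLASSIFIED.
    """
    fr25, fr75 = fr_quartiles
    lv25, lv75 = lv_quartiles
    if fr >= fr75 and lv <= lv25:
        return "H"
    if fr <= fr25 and lv >= lv75:
        return "L"
    if fr25 <= fr <= fr75 and lv25 <= lv <= lv75:
        return "M"
    return "UNCLASSIFIED"


def adaptability_labels(cohort: pd.DataFrame) -> pd.Series:
    """Label every cohort row with its M/H/L/UNCLASSIFIED profile."""
    fr_q = tuple(np.percentile(cohort["fr"].astype(float), [25, 75]))
    lv_q = tuple(np.percentile(cohort["lv"].astype(float), [25, 75]))
    return cohort.apply(
        lambda r: classify_adaptability(float(r["fr"]), float(r["lv"]), fr_q, lv_q),
        axis=1)


def scenario_run(cohort: pd.DataFrame, psqi_fit: FittedGLM, phq9_fit: FittedGLM,
                 config: SimulationConfig,
                 multipliers: Sequence[float] = (0.25, 1.0, 1.5, 2.0),
                 groups: Sequence[str] = ("M", "H", "L"),
                 ) -> tuple[dict, pd.DataFrame]:
    """Adaptability-profile x demand-multiplier scenario grid.

    For each (group, multiplier): bootstrap ``n_individuals`` members from
    the group's region of the cohort, fix the baseline demand condition
    scaled by the multiplier, and simulate.  Returns the TrajectorySet grid
    and a dose-response summary table.
    """
    labels = adaptability_labels(cohort)
    demand = dict(config.demand) if config.demand is not None else dict(BASELINE_DEMAND)
    results: dict[tuple[str, float], TrajectorySet] = {}
    rows = []
    for gi, group in enumerate(groups):
        members = cohort[labels == group]
        if members.empty:
            rows.append({"group": group, "multiplier": np.nan, "n_members": 0,
                         "note": "no cohort members in this profile"})
            continue
        for mi, mult in enumerate(multipliers):
            seed_seq = np.random.SeedSequence(config.seed, spawn_key=(gi, mi))
            rng = np.random.default_rng(seed_seq)
            idx = rng.integers(0, len(members), size=config.n_individuals)
            sub = members.iloc[idx]
            cfg = replace(config, demand=demand, demand_multiplier=mult)
            paths = _run_engine(sub, psqi_fit, phq9_fit, cfg, rng=rng)
            ts = _trajectory_set(*paths, {
                "engine": "scenario_run", "group": group, "multiplier": mult,
                "config": _config_dict(cfg), "n_members": len(members)})
            results[(group, mult)] = ts
            rows.append({
                "group": group, "multiplier": mult, "n_members": len(members),
                "final_mean_psqi": float(ts.mean_psqi[-1]),
                "final_mean_phq9": float(ts.mean_phq9[-1]),
                "insomnia_day": ts.crossing["insomnia"],
                "depression_day": ts.crossing["depression"],
                "insomnia_fraction": ts.crossing_fraction["insomnia"],
                "depression_fraction": ts.crossing_fraction["depression"],
            })
    return results, pd.DataFrame(rows)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if d.get("demand") is not None:
        d["demand"] = dict(d["demand"])
    return d


def plot_trajectories(results: Mapping, path: str, title: str = "") -> None:
    """Write a trajectory figure (mean +/- SD band per scenario) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for key, ts in results.items():
        label = str(key)
        axes[0].plot(ts.days, ts.mean_psqi, label=label)
        axes[0].fill_between(ts.days, ts.mean_psqi - ts.sd_psqi,
                             ts.mean_psqi + ts.sd_psqi, alpha=0.15)
        axes[1].plot(ts.days, ts.mean_phq9, label=label)
        axes[1].fill_between(ts.days, ts.mean_phq9 - ts.sd_phq9,
                             ts.mean_phq9 + ts.sd_phq9, alpha=0.15)
    axes[0].axhline(INSOMNIA_THRESHOLD, ls="--", c="grey", lw=0.8)
    axes[0].set(xlabel="day", ylabel="PSQI", title="Sleep quality")
    axes[1].axhline(DEPRESSION_THRESHOLD, ls="--", c="grey", lw=0.8)
    axes[1].set(xlabel="day", ylabel="PHQ-9", title="Depressive symptoms")
    axes[0].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
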