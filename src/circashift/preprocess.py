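"""Cleaning, transformation recipes, and univariate statistics.

Instrument scores and demand variables are skewed and bounded, so the
modelling pipeline (a) fences gross outliers at 3 x IQR, (b) imputes
missing values (median for continuous, mode for categorical), (c) applies a
Yeo-Johnson power transform with maximum-likelihood lambda, and (d) z-scores
the result.  The fitted per-column parameters form a :class:`TransformRecipe`
that downstream model fitting and simulation reuse, so raw scores can always
be mapped onto the standardized model scale.

Univariate statistics are the nonparametric set appropriate for skewed
scores: tie-corrected Spearman rank correlations, Mann-Whitney U for
two-group contrasts, Kruskal-Wallis H for three or more groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ColumnRecipe",
    "TransformRecipe",
    "CorrelationMatrix",
    "fence_outliers",
    "impute_missing",
    "yeo_johnson",
    "apply_yeo_johnson",
    "zscore",
    "spearman_matrix",
    "group_compare",
]

FENCE_MULTIPLIER = 3.0          # bounded, skewed instrument scores: wide fences
MAX_IMPUTE_FRACTION = 0.20


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    # linear-interpolation (type-7) quartiles; fences depend on this convention
    q1, q3 = np.percentile(x, [25, 75])
    return float(q1), float(q3)


def fence_outliers(values: Sequence[float] | pd.Series,
                   multiplier: float = FENCE_MULTIPLIER
                   ) -> tuple[pd.Series, pd.Series, tuple[float, float]]:
    """Set values outside [Q1 - m*IQR, Q3 + m*IQR] to missing.

    Returns (cleaned column, boolean removal flags, (lower, upper) fences).
    Quartiles use the type-7 linear-interpolation convention.
    """
    s = pd.Series(values, dtype=float)
    nonmiss = s.dropna()
    if len(nonmiss) < 8:
        raise ValueError("need at least 8 non-missing values to fence outliers")
    q1, q3 = _quartiles(nonmiss.to_numpy())
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    flags = (s < lo) | (s > hi)
    cleaned = s.mask(flags)
    return cleaned, flags.fillna(False), (lo, hi)


def impute_missing(column: Sequence[float] | pd.Series, kind: str = "continuous",
                   max_fraction: float | None = None
                   ) -> tuple[pd.Series, float, int]:
    """Median (continuous) or mode (categorical) imputation.

    Returns (completed column, imputation value, number imputed).  Aborts
    when everything is missing, or — with ``max_fraction`` set, as the
    recipe-fitting pipeline does at 20% — when too much of the column would
    be imputed.
    """
    s = pd.Series(column)
    n_miss = int(s.isna().sum())
    if n_miss == len(s):
        raise ValueError("cannot impute a fully missing column")
    if max_fraction is not None and n_miss > max_fraction * len(s):
        raise ValueError(
            f"{n_miss}/{len(s)} missing exceeds the {max_fraction:.0%} imputation cap"
        )
    if kind == "continuous":
        value = float(s.dropna().astype(float).median())
    elif kind == "categorical":
        value = s.dropna().mode().iloc[0]
    else:
        raise ValueError(f"unknown column kind {kind!r}")
    return s.fillna(value), value, n_miss


def yeo_johnson(column: Sequence[float] | np.ndarray) -> tuple[np.ndarray, float]:
    """Yeo-Johnson transform with lambda chosen by maximum likelihood."""
    x = np.asarray(column, dtype=float)
    if np.isnan(x).any():
        raise ValueError("Yeo-Johnson input must be complete (impute first)")
    if np.ptp(x) == 0:
        return x.copy(), 1.0   # constant column: transform is irrelevant
    transformed, lmbda = stats.yeojohnson(x)
    return np.asarray(transformed), float(lmbda)


def apply_yeo_johnson(x: np.ndarray | float, lmbda: float) -> np.ndarray | float:
    """Apply the Yeo-Johnson transform with a fixed, previously learned lambda."""
    return stats.yeojohnson(np.asarray(x, dtype=float), lmbda=lmbda)


def zscore(column: np.ndarray, mean: float | None = None, sd: float | None = None
           ) -> tuple[np.ndarray, float, float]:
    """Standardize a column; learns (mean, sd) when not supplied."""
    x = np.asarray(column, dtype=float)
    if mean is None:
        mean = float(x.mean())
    if sd is None:
        sd = float(x.std(ddof=0))
    if sd <= 0:
        raise ValueError("cannot z-score a constant column (SD = 0)")
    return (x - mean) / sd, mean, sd


@dataclass
class ColumnRecipe:
    """Learned preprocessing parameters for one continuous variable."""

    fence_lo: float
    fence_hi: float
    impute_value: float
    lmbda: float
    mean: float
    sd: float
    n_fenced: int = 0
    n_imputed: int = 0

    def transform(self, raw, winsorize: bool = False) -> np.ndarray | float:
        """Map raw values onto the standardized model scale.

        During training-data replay, out-of-fence values were removed and
        imputed; for new raw inputs (e.g. simulation scenarios) pass
        ``winsorize=True`` to clamp them to the fences instead.
        """
        x = np.asarray(raw, dtype=float)
        if winsorize:
            x = np.clip(x, self.fence_lo, self.fence_hi)
        y = apply_yeo_johnson(x, self.lmbda)
        out = (y - self.mean) / self.sd
        return float(out) if np.ndim(raw) == 0 else out


@dataclass
class TransformRecipe:
    """Per-variable preprocessing recipes (fence -> impute -> YJ -> z)."""

    columns: dict[str, ColumnRecipe] = field(default_factory=dict)

    @classmethod
    def fit(cls, table: pd.DataFrame, variables: Iterable[str],
            fence: bool = True) -> "TransformRecipe":
        recipe = cls()
        for name in variables:
            col = table[name].astype(float)
            if fence:
                cleaned, flags, (lo, hi) = fence_outliers(col)
                n_fenced = int(flags.sum())
            else:
                cleaned, (lo, hi), n_fenced = col, (-np.inf, np.inf), 0
            completed, impute_value, n_imputed = impute_missing(
                cleaned, "continuous", max_fraction=MAX_IMPUTE_FRACTION)
            transformed, lmbda = yeo_johnson(completed.to_numpy())
            _, mean, sd = zscore(transformed)
            recipe.columns[name] = ColumnRecipe(
                fence_lo=float(lo), fence_hi=float(hi),
                impute_value=impute_value, lmbda=lmbda, mean=mean, sd=sd,
                n_fenced=n_fenced, n_imputed=n_imputed)
        return recipe

    def transform_table(self, table: pd.DataFrame) -> pd.DataFrame:
        """Standardize every recipe variable present in ``table``."""
        out = table.copy()
        for name, cr in self.columns.items():
            if name not in out.columns:
                raise KeyError(f"recipe variable {name!r} missing from table")
            col = out[name].astype(float)
            col = col.mask((col < cr.fence_lo) | (col > cr.fence_hi))
            col = col.fillna(cr.impute_value)
            out[name] = cr.transform(col.to_numpy())
        return out

    def transform_value(self, name: str, raw, winsorize: bool = True):
        if name not in self.columns:
            raise KeyError(f"no recipe entry for variable {name!r}")
        return self.columns[name].transform(raw, winsorize=winsorize)

    # -- persistence ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {k: asdict(v) for k, v in self.columns.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "TransformRecipe":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path, encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(columns={k: ColumnRecipe(**v) for k, v in payload.items()})


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with p-values and pairwise n."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format (var_i, var_j, rho, p, n) table for CSV export."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append({"var_i": a, "var_j": b,
                             "rho": self.rho.loc[a, b],
                             "p": self.p.loc[a, b],
                             "n": self.n.loc[a, b]})
        return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Tie-corrected Spearman rank correlation matrix with asymptotic p-values."""
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables, dtype=float)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables, dtype=float)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=variables, columns=variables)
    np.fill_diagonal(n.values, len(table))
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            pair = table[[a, b]].dropna()
            res = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
            n.loc[a, b] = n.loc[b, a] = len(pair)
    return CorrelationMatrix(variables=list(variables), rho=rho, p=p, n=n)


@dataclass(frozen=True)
class GroupTest:
    test: str          # "mann-whitney-u" or "kruskal-wallis-h"
    statistic: float
    p: float
    group_sizes: tuple[int, ...]


def group_compare(values: Sequence[float], groups: Sequence) -> GroupTest:
    """Two groups -> Mann-Whitney U (two-sided); three or more -> Kruskal-Wallis H."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    samples = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("group", sort=True)]
    if len(samples) < 2:
        raise ValueError("group comparison needs at least two groups")
    sizes = tuple(len(s) for s in samples)
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupTest("mann-whitney-u", float(res.statistic), float(res.pvalue), sizes)
    res = stats.kruskal(*samples)
    return GroupTest("kruskal-wallis-h", float(res.statistic), float(res.pvalue), sizes)
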