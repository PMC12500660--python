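"""Objective shift-work demand metrics.

Work *quantity* is tallied from a nurse's shift log over a four-week
observation window: evening / night / total shift counts and the hours worked
in shift versus day time.  Work *intensity* relates staffing to patient need:
``workload`` is the ratio of the *expected* nurse-to-patient ratio (NPR,
derived from unit-level patient severity) to the *actual* NPR (active primary
nurses / assigned patients), and ``workload exposure`` multiplies that ratio
by the corresponding hours worked.

Shift-time definitions
----------------------
Shift work is work performed between 18:00 and 08:00.  An event counts as an
EVENING shift when it contains at least four consecutive worked hours inside
[18:00, 24:00), and as a NIGHT shift when it contains at least four
consecutive worked hours inside [00:00, 08:00).  A long night (18:00-08:00
with a three-hour nap break) satisfies both windows and is classified NIGHT
(night precedence).  Everything else is a DAY shift.  Net hours are gross
duration minus nap hours.

Expected NPR
------------
Patient severity ``s`` (unit CMI min-max normalised onto [0, 2]) maps to an
expected NPR through the exponential curve ``a * exp(b * s)``, fitted by
least squares *on the original scale* to the anchor points severity 0 -> 1:8,
1 -> 1:3, 2 -> 1:1 (mild / moderate / severe).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "ShiftClass",
    "ShiftEvent",
    "NPRCurve",
    "DemandSummary",
    "classify_shift",
    "summarize_demand",
    "fit_npr_curve",
    "expected_npr",
    "normalize_cmi",
    "NPR_ANCHORS",
]

#: Severity -> expected NPR anchor points (mild 1:8, moderate 1:3, severe 1:1).
NPR_ANCHORS: tuple[tuple[float, float], ...] = ((0.0, 1 / 8), (1.0, 1 / 3), (2.0, 1.0))

_EVENING = (18.0, 24.0)
_NIGHT = (0.0, 8.0)
_MIN_CLASS_HOURS = 4.0
_WINDOW_DAYS = 28


class ShiftClass(str, enum.Enum):
    DAY = "DAY"
    EVENING = "EVENING"
    NIGHT = "NIGHT"


class MalformedEventError(ValueError):
    """Raised for events that violate the shift-event contract."""


@dataclass(frozen=True)
class ShiftEvent:
    """One contiguous worked interval for one nurse.

    ``nap_hours`` is the scheduled nap inside a long night; it is netted out
    of worked hours and, for window classification, out of the night window
    (the window containing the nap by convention).
    """

    nurse_id: str
    start: datetime
    end: datetime
    nap_hours: float = 0.0
    unit_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MalformedEventError(f"event end {self.end} not after start {self.start}")
        if self.nap_hours < 0:
            raise MalformedEventError("nap_hours must be >= 0")
        if self.nap_hours >= self.gross_hours:
            raise MalformedEventError("nap_hours must be smaller than the gross duration")

    @property
    def gross_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def net_hours(self) -> float:
        return self.gross_hours - self.nap_hours


@dataclass(frozen=True)
class NPRCurve:
    """Expected nurse-to-patient ratio as ``a * exp(b * severity)``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("NPR curve coefficient a must be positive")

    def __call__(self, severity: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.exp(self.b * np.asarray(severity, dtype=float))


@dataclass
class DemandSummary:
    """Four-week work-quantity and work-intensity aggregates for one nurse.

    Intensity fields (``*_workload``, ``*_workload_exposure``) are ``None``
    when unit census data are unavailable for the nurse's events, mirroring
    the exclusion of units without census coverage from intensity analysis.
    """

    nurse_id: str = ""
    evening_count: int = 0
    night_count: int = 0
    shift_work_hours: float = 0.0
    day_work_hours: float = 0.0
    day_workload: float | None = None
    shift_workload: float | None = None

    @property
    def total_shift_count(self) -> int:
        return self.evening_count + self.night_count

    @property
    def total_work_hours(self) -> float:
        return self.day_work_hours + self.shift_work_hours

    @property
    def day_workload_exposure(self) -> float | None:
        if self.day_workload is None:
            return None
        return self.day_workload * self.day_work_hours

    @property
    def shift_workload_exposure(self) -> float | None:
        if self.shift_workload is None:
            return None
        return self.shift_workload * self.shift_work_hours

    def as_dict(self) -> dict:
        return {
            "nurse_id": self.nurse_id,
            "evening_count": self.evening_count,
            "night_count": self.night_count,
            "total_shift_count": self.total_shift_count,
            "shift_work_hours": self.shift_work_hours,
            "day_work_hours": self.day_work_hours,
            "total_work_hours": self.total_work_hours,
            "day_workload": self.day_workload,
            "shift_workload": self.shift_workload,
            "day_workload_exposure": self.day_workload_exposure,
            "shift_workload_exposure": self.shift_workload_exposure,
        }


def _window_overlaps(event: ShiftEvent, lo: float, hi: float) -> list[float]:
    """Contiguous overlap hours of the event with each daily instance of [lo, hi).

    The event spans at most 24 h so at most two instances of a given daily
    window can intersect it; each intersection is itself contiguous.
    """
    out = []
    day = datetime(event.start.year, event.start.month, event.start.day)
    for offset in (-1, 0, 1):
        d = day + timedelta(days=offset)
        w_start = d + timedelta(hours=lo)
        w_end = d + timedelta(hours=hi)
        s = max(event.start, w_start)
        e = min(event.end, w_end)
        if e > s:
            out.append((e - s).total_seconds() / 3600.0)
    return out


def classify_shift(event: ShiftEvent) -> tuple[ShiftClass, float]:
    """Classify one event as DAY / EVENING / NIGHT and return its net hours.

    Night takes precedence when both the evening and the night window rule
    hold (the long-night case).  The nap is deducted from the night window
    before the four-hour rule is applied, and from net hours.
    """
    if event.gross_hours > 24.0:
        raise MalformedEventError(
            f"event for {event.nurse_id!r} spans {event.gross_hours:.1f} h (> 24 h)"
        )
    evening_hours = max(_window_overlaps(event, *_EVENING), default=0.0)
    night_hours = max(_window_overlaps(event, *_NIGHT), default=0.0)
    if night_hours > 0:
        night_hours = max(night_hours - event.nap_hours, 0.0)
    if night_hours >= _MIN_CLASS_HOURS:
        cls = ShiftClass.NIGHT
    elif evening_hours >= _MIN_CLASS_HOURS:
        cls = ShiftClass.EVENING
    else:
        cls = ShiftClass.DAY
    return cls, event.net_hours


def default_period(event: ShiftEvent, window_start: datetime) -> str:
    """Map an event to a census period: the week index W1..W4 of its start."""
    week = int((event.start - window_start).days // 7)
    return f"W{week + 1}"


def normalize_cmi(cmi_values: Sequence[float] | np.ndarray,
                  fixed_range: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max map CMI values onto the [0, 2] severity scale.

    A constant input maps to 1.0 (the scale midpoint) by convention.  When
    ``fixed_range`` is given, that (min, max) is used instead of the
    empirical range (values outside are clipped).
    """
    x = np.asarray(cmi_values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one CMI value")
    lo, hi = (float(x.min()), float(x.max())) if fixed_range is None else fixed_range
    if hi <= lo:
        return np.ones_like(x)
    return np.clip(2.0 * (x - lo) / (hi - lo), 0.0, 2.0)


def fit_npr_curve(anchors: Iterable[tuple[float, float]] = NPR_ANCHORS) -> NPRCurve:
    """Least-squares fit of ``NPR = a * exp(b * severity)`` on the original scale.

    For fixed ``b`` the optimal ``a`` has the closed form
    ``sum(y * exp(b s)) / sum(exp(2 b s))``; the scalar profile over ``b`` is
    minimised numerically.  This differs from (and original-scale dominates)
    the log-linear regression fit.
    """
    pts = list(anchors)
    if len({s for s, _ in pts}) < 2:
        raise ValueError("need at least two distinct severity anchors")
    if any(y <= 0 for _, y in pts):
        raise ValueError("NPR anchors must be positive ratios")
    s = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)

    def a_of_b(b: float) -> float:
        e = np.exp(b * s)
        return float((y * e).sum() / (e * e).sum())

    def sse(b: float) -> float:
        return float(((y - a_of_b(b) * np.exp(b * s)) ** 2).sum())

    res = minimize_scalar(sse, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-12})
    b = float(res.x)
    return NPRCurve(a=a_of_b(b), b=b)


def expected_npr(curve: NPRCurve, severity: float | np.ndarray) -> float | np.ndarray:
    """Expected nurse-to-patient ratio at a severity score in [0, 2]."""
    sev = np.asarray(severity, dtype=float)
    if np.any(sev < 0) or np.any(sev > 2):
        raise ValueError("severity must lie in [0, 2]")
    out = curve(sev)
    return float(out) if np.isscalar(severity) or np.ndim(severity) == 0 else out


def _intensity_table(census: pd.DataFrame, curve: NPRCurve,
                     cmi_range: tuple[float, float] | None) -> pd.DataFrame:
    """Per (unit, period) workload ratio = expected NPR / actual NPR."""
    c = census.copy()
    required = {"unit_id", "period", "active_nurses", "assigned_patients", "cmi"}
    missing = required - set(c.columns)
    if missing:
        raise ValueError(f"census table missing columns: {sorted(missing)}")
    if (c["assigned_patients"] <= 0).any():
        raise ValueError("assigned_patients must be positive for actual-NPR computation")
    c["severity"] = normalize_cmi(c["cmi"].to_numpy(), fixed_range=cmi_range)
    c["expected_npr"] = curve(c["severity"].to_numpy())
    c["actual_npr"] = c["active_nurses"] / c["assigned_patients"]
    c["workload"] = c["expected_npr"] / c["actual_npr"]
    return c.set_index(["unit_id", "period"])


def summarize_demand(
    events: Sequence[ShiftEvent],
    window_start: datetime,
    census: pd.DataFrame | None = None,
    curve: NPRCurve | None = None,
    cmi_range: tuple[float, float] | None = None,
    nurse_id: str | None = None,
) -> DemandSummary:
    """Aggregate one nurse's events over a 28-day window into a DemandSummary.

    Work-intensity fields require a census table with a row for every
    (unit, period) touched by the nurse's events; when census is absent or
    incomplete they are left ``None``.  Workload is the net-hours-weighted
    mean of per-period expected/actual NPR ratios, so that exposure equals
    mean workload times the corresponding hours.
    """
    # an event belongs to the window its start falls in; a long night begun
    # on the final window day may end past window_end but still counts here
    window_end = window_start + timedelta(days=_WINDOW_DAYS)
    offenders = [e for e in events
                 if e.start < window_start or e.start >= window_end]
    if offenders:
        desc = ", ".join(f"{e.nurse_id}@{e.start.isoformat()}" for e in offenders[:5])
        raise ValueError(f"{len(offenders)} event(s) outside the 28-day window: {desc}")

    nid = nurse_id if nurse_id is not None else (events[0].nurse_id if events else "")
    summary = DemandSummary(nurse_id=nid)

    intensity = None
    if census is not None and curve is not None and len(census):
        intensity = _intensity_table(census, curve, cmi_range)

    day_wh = 0.0     # sum workload * hours, day events
    shift_wh = 0.0
    census_ok = intensity is not None
    for ev in events:
        cls, net = classify_shift(ev)
        if cls is ShiftClass.NIGHT:
            summary.night_count += 1
            summary.shift_work_hours += net
        elif cls is ShiftClass.EVENING:
            summary.evening_count += 1
            summary.shift_work_hours += net
        else:
            summary.day_work_hours += net
        if census_ok:
            key = (ev.unit_id, default_period(ev, window_start))
            if key not in intensity.index:
                census_ok = False
                continue
            w = float(intensity.loc[key, "workload"])
            if cls is ShiftClass.DAY:
                day_wh += w * net
            else:
                shift_wh += w * net
    if census_ok and events:
        summary.day_workload = (day_wh / summary.day_work_hours
                                if summary.day_work_hours > 0 else 0.0)
        summary.shift_workload = (shift_wh / summary.shift_work_hours
                                  if summary.shift_work_hours > 0 else 0.0)
    elif not events:
        # an empty roster is a defined all-zero summary
        summary.day_workload = 0.0
        summary.shift_workload = 0.0
    return summary


def demand_table(
    events: Sequence[ShiftEvent],
    window_start: datetime,
    census: pd.DataFrame | None = None,
    curve: NPRCurve | None = None,
    cmi_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-nurse demand summaries for a mixed event list, keyed by nurse_id."""
    by_nurse: dict[str, list[ShiftEvent]] = {}
    for ev in events:
        by_nurse.setdefault(ev.nurse_id, []).append(ev)
    rows = [
        summarize_demand(evs, window_start, census=census, curve=curve,
                         cmi_range=cmi_range, nurse_id=nid).as_dict()
        for nid, evs in sorted(by_nurse.items())
    ]
    return pd.DataFrame(rows)
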