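"""Nesting effort and Mayfield nest-success estimation.

Nest histories are visit tables (nest_id, colony, species, date, status)
with status ``active``, ``failed`` or ``fledged``. Exposure days follow the
classic accounting: an interval ending with the nest still alive
contributes its full length; an interval ending in failure contributes half
(the failure is assigned to the interval midpoint), and fractional days are
kept. Daily survival is the Mayfield estimator s = 1 − F/E with the Hensler
variance s(1 − s)/E, and success over a nest period of T days is s^T.
Annual success is the unweighted mean of colony period-success values;
annual effort is the maximum nest count across survey rounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATUS_ACTIVE = "active"
STATUS_FAILED = "failed"
STATUS_FLEDGED = "fledged"
TERMINAL = {STATUS_FAILED, STATUS_FLEDGED}


def exposure_and_failures(visits: pd.DataFrame) -> tuple[float, int]:
    """Total exposure days E and failed-nest count F from a visit table.

    Per nest: consecutive-visit intervals ending ``active`` or ``fledged``
    contribute their full day span; the interval ending ``failed``
    contributes half its span (midpoint rule). Observation stops at the
    first terminal status.
    """
    E = 0.0
    F = 0
    for nest_id, g in visits.groupby("nest_id"):
        g = g.sort_values("date")
        dates = pd.DatetimeIndex(g["date"])
        if dates.has_duplicates or not dates.is_monotonic_increasing:
            raise ValueError(f"nest {nest_id}: visit dates must strictly increase")
        statuses = g["status"].tolist()
        terminal_seen = False
        for i in range(1, len(g)):
            if terminal_seen:
                raise ValueError(f"nest {nest_id}: visits after terminal status")
            span = (dates[i] - dates[i - 1]).days
            if statuses[i] == STATUS_FAILED:
                E += span / 2.0
                F += 1
                terminal_seen = True
            else:
                E += float(span)
                if statuses[i] in TERMINAL:
                    terminal_seen = True
        if len(g) == 1 and statuses[0] == STATUS_FAILED:
            F += 1  # same-day terminal: no exposure accrued
    return E, F


@dataclass
class MayfieldEstimate:
    scope: str
    exposure_days: float
    failures: int
    daily_survival: float
    variance: float
    period_days: int | None = None
    period_success: float | None = None


def mayfield_daily_survival(E: float, F: float) -> tuple[float, float]:
    """Mayfield daily survival s = 1 − F/E with Hensler variance s(1−s)/E."""
    if E <= 0:
        raise ValueError("exposure days must be positive")
    if F > E:
        raise ValueError("failures cannot exceed exposure days")
    s = 1.0 - F / E
    var = s * (1.0 - s) / E
    return s, var


def period_success(s: float, T: int) -> float:
    """Probability a nest survives T consecutive days: s^T."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("daily survival must lie in [0, 1]")
    if T <= 0:
        raise ValueError("period length must be positive")
    return float(s) ** T


def colony_estimates(visits: pd.DataFrame, period_days: int) -> list[MayfieldEstimate]:
    """Mayfield estimate per colony from one species-year visit table."""
    out = []
    for colony, g in visits.groupby("colony"):
        E, F = exposure_and_failures(g)
        if E <= 0:
            continue
        s, var = mayfield_daily_survival(E, F)
        out.append(MayfieldEstimate(
            scope=str(colony), exposure_days=E, failures=int(F),
            daily_survival=s, variance=var, period_days=period_days,
            period_success=period_success(s, period_days)))
    return out


def annual_success(estimates: list[MayfieldEstimate]) -> tuple[float, float]:
    """Unweighted mean (and SD) of colony period-success values.

    A single colony yields SD = 0 (flagged upstream via n_colonies).
    """
    if not estimates:
        raise ValueError("no colonies with positive exposure")
    vals = np.array([e.period_success for e in estimates], dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def annual_success_table(visits: pd.DataFrame, period_days: int) -> pd.DataFrame:
    """Per-year Mayfield success summary for one species' visit table."""
    rows = []
    years = pd.DatetimeIndex(visits["date"]).year
    for year, g in visits.groupby(years):
        est = colony_estimates(g, period_days)
        if not est:
            continue
        mean, sd = annual_success(est)
        rows.append({
            "year": int(year), "success": mean, "success_sd": sd,
            "n_colonies": len(est),
            "exposure_days": float(sum(e.exposure_days for e in est)),
            "failures": int(sum(e.failures for e in est)),
        })
    return pd.DataFrame(rows)


def annual_effort(effort: pd.DataFrame) -> pd.DataFrame:
    """Annual maximum nest count across survey rounds, per species-year.

    ``effort`` has columns (year, species, round_date, n_active).
    """
    out = (effort.groupby(["year", "species"], as_index=False)["n_active"]
           .max().rename(columns={"n_active": "effort"}))
    return out
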