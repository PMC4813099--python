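"""Hydrologic indicator computation.

Five per-cell indicators summarize wetland hydrology at nested time scales
and act as prey-availability proxies for the foraging-condition models:

* **depth** (cm) — short-term prey availability; stage minus ground elevation.
* **recession** (cm/day) — intermediate-scale prey concentration; the rate of
  water-level decline over a trailing window, positive while drying.
* **DSD**, days since drydown — long-term prey production; days elapsed since
  the cell last had depth at or below the dry threshold.
* **hydroperiod** (days/year) — multi-year mean annual length of inundation.
* **reversal** — within-dry-season dry-to-wet event timing; days since the
  cell rewet after having gone dry this season (0 when no completed event).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import DepthCube, HydroCovariateCube

DRY_THRESHOLD_CM = 0.0
RECESSION_WINDOW_DAYS = 14
DSD_CAP_DAYS = 600
HYDROPERIOD_YEARS = 10


def daily_depth(stage: pd.Series | np.ndarray, elevation: np.ndarray,
                dates, region: np.ndarray) -> DepthCube:
    """Build a DepthCube from a daily stage series and an elevation grid.

    ``stage`` may be one value per day (uniform water surface, the flat-pool
    approximation) or an (n_days, n_rows, n_cols) array. Depth is
    ``stage − elevation`` exactly; negative values are retained.
    """
    dates = pd.DatetimeIndex(dates)
    stage = np.asarray(stage, dtype=float)
    elevation = np.asarray(elevation, dtype=float)
    if stage.ndim == 1:
        if len(stage) != len(dates):
            raise ValueError("stage length does not match date index")
        depth = stage[:, None, None] - elevation[None, :, :]
    elif stage.ndim == 3:
        if stage.shape[0] != len(dates):
            raise ValueError("stage length does not match date index")
        depth = stage - elevation[None, :, :]
    else:
        raise ValueError("stage must be 1-D (per day) or 3-D (per cell-day)")
    return DepthCube(depth, dates, elevation, region)


def recession_rate(cube: DepthCube, window_days: int = RECESSION_WINDOW_DAYS) -> np.ndarray:
    """Two-point recession rate (cm/day), positive while drying.

    ``recession(cell, t) = (depth(t − window) − depth(t)) / window``.
    The first ``window_days`` days have no history and are NaN.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if window_days >= cube.n_days:
        raise ValueError("window_days must be shorter than the series")
    out = np.full_like(cube.depth, np.nan)
    out[window_days:] = (cube.depth[:-window_days] - cube.depth[window_days:]) / window_days
    return out


def days_since_drydown(cube: DepthCube, dry_threshold_cm: float = DRY_THRESHOLD_CM,
                       cap_days: int = DSD_CAP_DAYS) -> tuple[np.ndarray, np.ndarray]:
    """Days since the most recent drydown (depth ≤ threshold), capped.

    Returns ``(dsd, left_censored)``. On a dry day DSD is 0; afterwards it
    increments by one per day up to ``cap_days``. Before a cell's first
    observed drydown the true DSD is unknown: those days carry days-since-
    series-start (capped) and are flagged in ``left_censored``.
    """
    dry = cube.depth <= dry_threshold_cm
    nt = cube.n_days
    dsd = np.empty(cube.depth.shape, dtype=float)
    censored = np.empty(cube.depth.shape, dtype=bool)
    counter = np.zeros(cube.grid_shape, dtype=float)
    seen_dry = np.zeros(cube.grid_shape, dtype=bool)
    for t in range(nt):
        d = dry[t]
        seen_dry |= d
        counter = np.where(d, 0.0, counter + (1.0 if t > 0 else 0.0))
        dsd[t] = np.minimum(counter, cap_days)
        censored[t] = ~seen_dry
    return dsd, censored


def hydroperiod(cube: DepthCube, dry_threshold_cm: float = DRY_THRESHOLD_CM,
                n_years: int = HYDROPERIOD_YEARS) -> np.ndarray:
    """Mean annual days of inundation (depth > threshold) per cell.

    Uses the most recent ``n_years`` complete calendar years in the cube;
    warns when fewer are available, errors when none is.
    """
    years = cube.dates.year
    counts = []
    for y in np.unique(years):
        sel = years == y
        n_in_year = pd.Timestamp(int(y), 12, 31).dayofyear
        if sel.sum() != n_in_year:
            continue  # incomplete year
        counts.append((cube.depth[sel] > dry_threshold_cm).sum(axis=0))
    if not counts:
        raise ValueError("hydroperiod requires at least one complete calendar year")
    if len(counts) < n_years:
        warnings.warn(
            f"hydroperiod computed over {len(counts)} complete years "
            f"(target horizon {n_years})", stacklevel=2)
    counts = counts[-n_years:]
    return np.mean(np.stack(counts), axis=0)


def dry_season_windows(dates: pd.DatetimeIndex,
                       start_month_day=(11, 1), end_month_day=(5, 31)):
    """Yield (season_year, boolean day mask) for each dry season.

    A season runs from Nov 1 of the preceding year through May 31 and is
    keyed by the calendar year of its Jan–May part. Window edges are
    configurable; partial windows at the record edges are included.
    """
    sm, sd = start_month_day
    em, ed = end_month_day
    years = sorted(set(dates.year.tolist()))
    for y in years:
        start = pd.Timestamp(y - 1, sm, sd) if sm > em else pd.Timestamp(y, sm, sd)
        end = pd.Timestamp(y, em, ed)
        mask = (dates >= start) & (dates <= end)
        if mask.any():
            yield y, mask


def dry_wet_reversal(cube: DepthCube, dry_threshold_cm: float = DRY_THRESHOLD_CM,
                     season_start=(11, 1), season_end=(5, 31)) -> np.ndarray:
    """Days since within-season rewetting after a drydown; 0 when no event.

    Within each dry-season window a cell that goes dry (depth ≤ threshold)
    and later rewets (depth > threshold) on day ``r`` emits ``t − r + 1`` on
    every subsequent season day ``t ≥ r``. The event state resets each
    season. A drydown without rewetting emits 0 (event incomplete).
    """
    start = pd.Timestamp(2000, *season_start)
    end = pd.Timestamp(2000 if season_start[0] <= season_end[0] else 2001, *season_end)
    if (end - start).days < 1:
        raise ValueError("season window must span at least 2 days")
    out = np.zeros(cube.depth.shape, dtype=float)
    dry = cube.depth <= dry_threshold_cm
    for _, mask in dry_season_windows(cube.dates, season_start, season_end):
        idx = np.flatnonzero(mask)
        been_dry = np.zeros(cube.grid_shape, dtype=bool)
        rewet_day = np.full(cube.grid_shape, -1, dtype=int)  # season-day of rewet
        for k, t in enumerate(idx):
            d = dry[t]
            rewetting = been_dry & ~d & (rewet_day < 0)
            rewet_day = np.where(rewetting, k, rewet_day)
            # a later drydown restarts the event clock
            rewet_day = np.where(d, -1, rewet_day)
            been_dry |= d
            active = rewet_day >= 0
            out[t] = np.where(active, k - rewet_day + 1, 0.0)
    return out


def compute_covariates(cube: DepthCube,
                       dry_threshold_cm: float = DRY_THRESHOLD_CM,
                       recession_window: int = RECESSION_WINDOW_DAYS,
                       dsd_cap: int = DSD_CAP_DAYS,
                       hydroperiod_years: int = HYDROPERIOD_YEARS) -> HydroCovariateCube:
    """Compute all five indicators from a DepthCube."""
    rec = recession_rate(cube, recession_window)
    dsd, censored = days_since_drydown(cube, dry_threshold_cm, dsd_cap)
    hp = hydroperiod(cube, dry_threshold_cm, hydroperiod_years)
    rev = dry_wet_reversal(cube, dry_threshold_cm)
    return HydroCovariateCube(
        dates=cube.dates, depth=cube.depth, recession=rec, dsd=dsd,
        hydroperiod=hp, reversal=rev, region=cube.region,
        dsd_left_censored=censored,
    )
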