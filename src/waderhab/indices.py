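"""Season-level habitat-quality indices.

From the daily TFC/SFC outputs this module derives, per species:

* the **foraging index** FI = daily individual abundance × daily patch
  abundance, which is high only when many birds and many high-quality
  patches coincide;
* the **flocking ratio** = individuals / flocks, the mean number of birds
  per flock — an index of conspecific foraging aggregation, floored at 1
  because a flock cannot hold fewer than one bird;
* monthly means and monthly mean day-over-day changes (Δ) of abundance and
  FI for the dry-season months;
* dry-season means and standard errors (SE = sample SD / √n) of abundance,
  FI and the ratio, plus the hydrologic-regime Decade label.

One row per year × species of these summaries, joined to the nesting
responses, forms the season covariate table consumed by the multimodel
inference stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DECADE_SPLIT_YEAR = 2000   # 1993–1999 = wetter regime, 2000–2013 = recent
MONTH_ABBR = {1: "jan", 2: "feb", 3: "mar", 4: "apr", 5: "may"}


def foraging_index(individuals, patch_abundance):
    """FI = individual abundance × patch abundance (exact product)."""
    individuals = np.asarray(individuals, dtype=float)
    patch = np.asarray(patch_abundance, dtype=float)
    if (individuals < 0).any() or (patch < 0).any():
        raise ValueError("foraging_index inputs must be nonnegative")
    return individuals * patch


def flocking_ratio(individuals, flocks):
    """Individuals per flock, floored at 1.0.

    flocks = 0 with individuals = 0 gives NaN (no birds, ratio undefined);
    flocks = 0 with individuals > 0 is inconsistent and raises.
    """
    individuals = np.asarray(individuals, dtype=float)
    flocks = np.asarray(flocks, dtype=float)
    if ((flocks == 0) & (individuals > 0)).any():
        raise ValueError("positive individuals with zero flocks")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(flocks > 0, individuals / np.where(flocks > 0, flocks, 1.0),
                         np.nan)
    ratio = np.where(np.isnan(ratio), np.nan, np.maximum(ratio, 1.0))
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def build_daily_series(landscape: pd.DataFrame, patch: pd.Series) -> pd.DataFrame:
    """Join TFC landscape totals with SFC patch abundance; derive FI, ratio, Δ.

    ``landscape`` has columns (date, species, individuals, flocks); ``patch``
    is a date-indexed daily patch-abundance series for the same species.
    """
    df = landscape.sort_values("date").reset_index(drop=True).copy()
    df["patch_abundance"] = patch.reindex(pd.DatetimeIndex(df["date"])).to_numpy()
    df["fi"] = foraging_index(df["individuals"], df["patch_abundance"])
    df["ratio"] = flocking_ratio(df["individuals"], df["flocks"])
    df["delta"] = df["individuals"].diff()
    df["fi_delta"] = df["fi"].diff()
    return df


def monthly_stats(series: pd.Series, month: int, year: int | None = None
                  ) -> tuple[float, float]:
    """(mean, mean day-over-day Δ) of a daily series for one calendar month.

    The first day's Δ uses the prior day's value when the series provides
    it (cross-month difference), so a linear series of slope m has monthly
    Δ exactly m.
    """
    s = series.sort_index()
    sel = s.index.month == month
    if year is not None:
        sel &= s.index.year == year
    if not sel.any():
        raise ValueError(f"no data for month {month}")
    month_vals = s[sel]
    deltas = s.diff()[sel]
    return float(month_vals.mean()), float(deltas.mean())


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return np.nan, np.nan
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), se


def decade_label(year: int) -> str:
    return "1993-1999" if year < DECADE_SPLIT_YEAR else "2000-2013"


def season_summary(daily: pd.DataFrame, year: int,
                   months: tuple[int, ...] = (1, 2, 3, 4)) -> dict:
    """One season covariate row for a year (dry season Jan–May).

    Means/SEs cover the whole Jan–May season; monthly means and Δs are
    produced for the requested months. Rows with more than 20% of season
    days missing are flagged, not dropped.
    """
    d = daily.copy()
    d["date"] = pd.DatetimeIndex(d["date"])
    d = d.set_index("date").sort_index()
    season = d[(d.index.year == year) & (d.index.month <= 5)]
    if season.empty:
        raise ValueError(f"no daily values for year {year}")
    n_expected = (pd.Timestamp(year, 5, 31) - pd.Timestamp(year, 1, 1)).days + 1
    row: dict = {"year": year, "decade": decade_label(year),
                 "season_days": int(len(season)),
                 "low_coverage": bool(len(season) < 0.8 * n_expected)}
    if "species" in season.columns:
        row["species"] = season["species"].iloc[0]
    row["mean_tfc"], row["se_tfc"] = _mean_se(season["individuals"].to_numpy())
    row["mean_fi"], row["se_fi"] = _mean_se(season["fi"].to_numpy())
    row["mean_ratio"], row["se_ratio"] = _mean_se(season["ratio"].to_numpy())
    for m in months:
        abbr = MONTH_ABBR[m]
        if not (season.index.month == m).any():   # month absent: NaN columns
            row[f"{abbr}_tfc"] = row[f"{abbr}_delta"] = row[f"{abbr}_fi"] = np.nan
            continue
        mean_tfc, delta_tfc = monthly_stats(season["individuals"], m)
        mean_fi, _ = monthly_stats(season["fi"], m)
        row[f"{abbr}_tfc"] = mean_tfc
        row[f"{abbr}_delta"] = delta_tfc
        row[f"{abbr}_fi"] = mean_fi
    return row


def build_season_table(daily: pd.DataFrame,
                       months: tuple[int, ...] = (1, 2, 3, 4)) -> pd.DataFrame:
    """Season covariate rows for every year present in the daily series."""
    years = sorted(pd.DatetimeIndex(daily["date"]).year.unique())
    rows = [season_summary(daily, int(y), months) for y in years]
    return pd.DataFrame(rows)
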