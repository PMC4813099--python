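"""Temporal foraging-conditions (TFC) model.

A two-stage regional chain run per species:

1. **availability → use.** On each survey day, cells are *available* when
   their depth lies in the species' foraging range. Per region, the mean and
   SD of each resource (depth, recession, DSD) over available surveyed cells
   summarize availability; observed *use* of a resource is the count-weighted
   mean of that resource over occupied available cells. A linear model
   predicts daily use from the three availability means, their pairwise
   interactions, and the three SDs.

2. **use → abundance.** Overdispersed count regressions (log link) predict
   per-region daily totals of individuals (Σ counts) and flocks (number of
   occupied cells) from the predicted use values.

Applying both stages to every day of the dry season — survey day or not —
and summing regions gives daily landscape abundance of flocks and
individuals. The two stages are kept separate deliberately (point
predictions feed forward; no uncertainty propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._countglm import CountFit, fit_count_glm
from .grids import HydroCovariateCube
from .species import SpeciesProfile

RESOURCES = ("depth", "recession", "dsd")

USE_DESIGN_COLUMNS = (
    "const",
    "mean_depth", "mean_recession", "mean_dsd",
    "mean_depth:mean_recession", "mean_depth:mean_dsd",
    "mean_recession:mean_dsd",
    "sd_depth", "sd_recession", "sd_dsd",
)

ABUND_DESIGN_COLUMNS = ("const", "use_depth", "use_recession", "use_dsd")


def availability_mask(depth_slice: np.ndarray, profile: SpeciesProfile) -> np.ndarray:
    """True where depth lies in the species' closed foraging interval."""
    return ((depth_slice >= profile.depth_min_cm)
            & (depth_slice <= profile.depth_max_cm))


def regional_resource_summary(cov: HydroCovariateCube, mask: np.ndarray,
                              date, species: str,
                              cell_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Availability-masked mean/SD of each resource per region on one day.

    ``cell_subset`` (boolean grid) restricts the summary to surveyed cells
    (e.g. transect rows); regions with no masked cell emit no row. SD uses
    the n−1 denominator and is 0 for a single cell.
    """
    layers = cov.day_layers(date)
    m = mask if cell_subset is None else (mask & cell_subset)
    rows = []
    for region in np.unique(cov.region):
        sel = m & (cov.region == region)
        n = int(sel.sum())
        if n == 0:
            continue
        row = {"date": pd.Timestamp(date), "region": region,
               "species": species, "n_available": n}
        for res in RESOURCES:
            vals = layers[res][sel]
            row[f"mean_{res}"] = float(np.mean(vals))
            row[f"sd_{res}"] = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def observed_use(surveys: pd.DataFrame, cov: HydroCovariateCube,
                 mask: np.ndarray, date, region: str | None = None) -> dict:
    """Count-weighted mean of each resource over occupied available cells.

    Occupied = count ≥ 1. Returns NaNs (flagged via ``n_occupied = 0``)
    when no occupied available cell exists for the date/region.
    """
    layers = cov.day_layers(date)
    day = surveys[(surveys["date"] == pd.Timestamp(date)) & (surveys["count"] >= 1)]
    out = {"date": pd.Timestamp(date), "region": region}
    rows = day["row"].to_numpy(dtype=int)
    cols = day["col"].to_numpy(dtype=int)
    counts = day["count"].to_numpy(dtype=float)
    keep = mask[rows, cols]
    if region is not None:
        keep &= cov.region[rows, cols] == region
    rows, cols, counts = rows[keep], cols[keep], counts[keep]
    out["n_occupied"] = int(len(rows))
    for res in RESOURCES:
        if len(rows) == 0:
            out[f"use_{res}"] = np.nan
        else:
            vals = layers[res][rows, cols]
            out[f"use_{res}"] = float(np.sum(counts * vals) / np.sum(counts))
    return out


def use_design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Design for the use model: means, pairwise mean interactions, SDs."""
    md, mr, ms = (df[f"mean_{r}"].to_numpy(dtype=float) for r in RESOURCES)
    sds = [df[f"sd_{r}"].to_numpy(dtype=float) for r in RESOURCES]
    return np.column_stack([
        np.ones(len(df)), md, mr, ms, md * mr, md * ms, mr * ms, *sds])


def _check_rank(X: np.ndarray, columns) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    aliased = [columns[i] for i in np.flatnonzero(diag <= tol)]
    if aliased:
        raise ValueError(f"rank-deficient use-model design; aliased terms: {aliased}")


@dataclass
class UseModel:
    """Per-resource linear use models (least squares)."""

    params: dict = field(default_factory=dict)   # resource -> ndarray
    bse: dict = field(default_factory=dict)
    resid_sd: dict = field(default_factory=dict)
    columns: tuple = USE_DESIGN_COLUMNS

    def predict(self, summaries: pd.DataFrame) -> pd.DataFrame:
        X = use_design_matrix(summaries)
        out = summaries.copy()
        for res, beta in self.params.items():
            out[f"use_{res}"] = X @ beta
        return out

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "resources": {
                res: {"params": self.params[res].tolist(),
                      "bse": self.bse[res].tolist(),
                      "resid_sd": self.resid_sd[res]}
                for res in self.params
            },
        }


def fit_use_model(table: pd.DataFrame) -> UseModel:
    """Fit use ~ availability means + interactions + SDs per resource.

    ``table`` holds one row per region-day with ``mean_*``, ``sd_*`` and
    observed ``use_*`` columns; rows with missing use are dropped per
    resource. Requires at least 3 rows per parameter.
    """
    model = UseModel()
    for res in RESOURCES:
        sub = table.dropna(subset=[f"use_{res}"])
        X = use_design_matrix(sub)
        if len(sub) < 3 * X.shape[1]:
            raise ValueError(
                f"need >= {3 * X.shape[1]} region-days to fit use_{res}; "
                f"have {len(sub)}")
        _check_rank(X, USE_DESIGN_COLUMNS)
        res_fit = sm.OLS(sub[f"use_{res}"].to_numpy(dtype=float), X).fit()
        model.params[res] = np.asarray(res_fit.params)
        model.bse[res] = np.asarray(res_fit.bse)
        model.resid_sd[res] = float(np.sqrt(res_fit.scale))
    return model


@dataclass
class AbundanceModel:
    """Count models for individual and flock totals given predicted use."""

    individuals: CountFit = None
    flocks: CountFit = None
    columns: tuple = ABUND_DESIGN_COLUMNS

    def predict(self, use_table: pd.DataFrame) -> pd.DataFrame:
        X = np.column_stack([np.ones(len(use_table))] + [
            use_table[c].to_numpy(dtype=float) for c in self.columns[1:]])
        out = use_table.copy()
        out["individuals"] = self.individuals.predict_mean(X)
        out["flocks"] = self.flocks.predict_mean(X)
        return out

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "responses": {
                name: {"params": fit.params.tolist(), "bse": fit.bse.tolist(),
                       "alpha": fit.alpha, "family": fit.family}
                for name, fit in (("individuals", self.individuals),
                                  ("flocks", self.flocks))
            },
        }


def fit_abundance_model(table: pd.DataFrame) -> AbundanceModel:
    """Fit flock/individual totals on predicted use (log link, overdispersed).

    ``table`` holds one row per region-day with ``use_*`` predictors and
    ``individuals``/``flocks`` totals. Validates flocks ≤ individuals (a
    flock is one or more birds in a cell).
    """
    sub = table.dropna(subset=[f"use_{r}" for r in RESOURCES])
    if (sub["flocks"] > sub["individuals"]).any():
        raise ValueError("flocks exceed individuals in at least one row")
    X = np.column_stack([np.ones(len(sub))] + [
        sub[f"use_{r}"].to_numpy(dtype=float) for r in RESOURCES])
    model = AbundanceModel()
    model.individuals = fit_count_glm(
        sub["individuals"].to_numpy(), X, columns=ABUND_DESIGN_COLUMNS)
    model.flocks = fit_count_glm(
        sub["flocks"].to_numpy(), X, columns=ABUND_DESIGN_COLUMNS)
    return model


def build_training_table(cov: HydroCovariateCube, surveys: pd.DataFrame,
                         profile: SpeciesProfile, survey_dates,
                         transect_row_step: int | None = None) -> pd.DataFrame:
    """One row per region-day: availability summaries, observed use, totals.

    Only surveyed cells (transect rows, when given) enter the availability
    summaries, matching the survey design.
    """
    subset = None
    if transect_row_step is not None:
        subset = np.zeros(cov.depth.shape[1:], dtype=bool)
        subset[::transect_row_step, :] = True
    rows = []
    for date in survey_dates:
        t = cov.day_index(date)
        mask = availability_mask(cov.depth[t], profile)
        summ = regional_resource_summary(cov, mask, date, profile.name, subset)
        if summ.empty:
            continue
        day = surveys[surveys["date"] == pd.Timestamp(date)]
        for _, row in summ.iterrows():
            region = row["region"]
            use = observed_use(surveys, cov, mask, date, region)
            rec = row.to_dict()
            rec.update({k: v for k, v in use.items() if k.startswith("use_")
                        or k == "n_occupied"})
            day_regions = cov.region[day["row"].to_numpy(), day["col"].to_numpy()]
            in_region = day[day_regions == region]
            rec["individuals"] = int(in_region["count"].sum())
            occupied = in_region[in_region["count"] >= 1]
            rec["flocks"] = int(len(occupied))
            rows.append(rec)
    return pd.DataFrame(rows)


def predict_daily_abundance(use_model: UseModel, abundance_model: AbundanceModel,
                            cov: HydroCovariateCube, profile: SpeciesProfile,
                            dates, cell_subset: np.ndarray | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily per-region and landscape flock/individual abundance.

    For every requested day (survey day or not): availability mask →
    regional summaries → predicted use → predicted abundance. Regions with
    zero available cells contribute 0. Returns ``(per_region, landscape)``;
    the landscape table is the exact per-day sum over regions.
    """
    dates = pd.DatetimeIndex(dates)
    missing = dates.difference(cov.dates)
    if len(missing):
        raise ValueError(f"dates outside covariate coverage: {missing[0].date()} ...")
    per_region = []
    all_regions = np.unique(cov.region)
    for date in dates:
        t = cov.day_index(date)
        mask = availability_mask(cov.depth[t], profile)
        summ = regional_resource_summary(cov, mask, date, profile.name, cell_subset)
        if not summ.empty:
            summ = use_model.predict(summ)
            summ = abundance_model.predict(summ)
        present = set(summ["region"]) if not summ.empty else set()
        empty = [{"date": pd.Timestamp(date), "region": r,
                  "species": profile.name, "n_available": 0,
                  "use_depth": np.nan, "use_recession": np.nan,
                  "use_dsd": np.nan, "individuals": 0.0, "flocks": 0.0}
                 for r in all_regions if r not in present]
        per_region.append(pd.concat([summ, pd.DataFrame(empty)], ignore_index=True)
                          if empty else summ)
    per_region = pd.concat(per_region, ignore_index=True)
    landscape = (per_region.groupby(["date", "species"], as_index=False)
                 [["individuals", "flocks"]].sum())
    return per_region, landscape
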