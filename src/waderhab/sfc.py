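"""Spatial foraging-conditions (SFC) model.

Models the *occurrence frequency* of a species in each 400 m cell — the
number of survey dates on which it was detected there — as an overdispersed
count regression (log link) on the cell's hydrologic covariates averaged
over its survey dates, the pairwise interactions of the three resources,
and a spatial autocovariate (mean occurrence frequency of the
8-neighborhood) that absorbs topographic patterns spanning multiple cells.
The number of surveys covering a cell enters as an exposure offset.

Evaluating the fitted per-survey occurrence rate on a single day's
covariate layers (autocovariate held at its fitted-period value) and
averaging over all cells yields the daily *patch abundance* — a
dimensionless surrogate for the landscape abundance of high-quality
patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from ._countglm import CountFit, fit_count_glm
from .grids import HydroCovariateCube

SFC_COVARIATES = ("depth", "recession", "dsd", "hydroperiod", "reversal")
SFC_DESIGN_COLUMNS = (
    "const", "depth", "recession", "dsd", "hydroperiod", "reversal",
    "depth:recession", "depth:dsd", "recession:dsd", "autocov",
)


def occurrence_frequency(surveys: pd.DataFrame, species: str,
                         grid_shape: tuple[int, int]) -> np.ndarray:
    """Per-cell count of distinct survey dates with a detection (count ≥ 1)."""
    freq = np.zeros(grid_shape, dtype=float)
    det = surveys[(surveys["species"] == species) & (surveys["count"] >= 1)]
    det = det.drop_duplicates(subset=["date", "row", "col"])
    np.add.at(freq, (det["row"].to_numpy(), det["col"].to_numpy()), 1.0)
    return freq


def spatial_autocovariate(grid: np.ndarray) -> np.ndarray:
    """Mean of the 8-neighborhood; edge cells average available neighbors."""
    g = np.asarray(grid, dtype=float)
    ones = np.ones_like(g)
    # 3x3 box sums with zero padding, then remove the center and renormalize
    box = uniform_filter(g, size=3, mode="constant", cval=0.0) * 9.0
    nnb = uniform_filter(ones, size=3, mode="constant", cval=0.0) * 9.0 - 1.0
    return (box - g) / nnb


def build_cell_records(cov: HydroCovariateCube, surveys: pd.DataFrame,
                       species: str, survey_dates,
                       transect_row_step: int | None = None) -> pd.DataFrame:
    """One row per surveyed cell: frequency, averaged covariates, autocovariate.

    Covariates are averaged over all survey dates covering the cell
    (equal weights, unconditional on detection). The autocovariate is the
    8-neighborhood mean of the full frequency grid.
    """
    shape = cov.depth.shape[1:]
    freq = occurrence_frequency(surveys, species, shape)
    auto = spatial_autocovariate(freq)
    idx = [cov.day_index(d) for d in survey_dates]
    layer_means = {
        name: (getattr(cov, name)[idx].mean(axis=0)
               if name != "hydroperiod" else cov.hydroperiod)
        for name in SFC_COVARIATES
    }
    rows = np.arange(0, shape[0], transect_row_step or 1)
    rr, cc = np.meshgrid(rows, np.arange(shape[1]), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    df = pd.DataFrame({
        "row": rr, "col": cc, "species": species,
        "frequency": freq[rr, cc].astype(int),
        "n_surveys": len(survey_dates),
        "autocov": auto[rr, cc],
    })
    for name, grid in layer_means.items():
        df[name] = grid[rr, cc]
    return df


def sfc_design_matrix(df: pd.DataFrame, scale: dict | None = None,
                      z_bounds: dict | None = None) -> tuple[np.ndarray, dict]:
    """Standardized design; returns (X, scale) so prediction reuses the scale.

    ``z_bounds`` (per-covariate standardized min/max from the fitted
    records) clamps covariates to the fitted support: the occurrence
    surface is descriptive inside the hull of the data that built it and
    is not extrapolated beyond it.
    """
    if scale is None:
        scale = {name: (float(df[name].mean()), float(df[name].std() or 1.0))
                 for name in SFC_COVARIATES}
    z = {name: (df[name].to_numpy(dtype=float) - mu) / (sd or 1.0)
         for name, (mu, sd) in scale.items()}
    if z_bounds is not None:
        z = {name: np.clip(v, *z_bounds[name]) for name, v in z.items()}
    X = np.column_stack([
        np.ones(len(df)),
        z["depth"], z["recession"], z["dsd"], z["hydroperiod"], z["reversal"],
        z["depth"] * z["recession"], z["depth"] * z["dsd"],
        z["recession"] * z["dsd"],
        df["autocov"].to_numpy(dtype=float),
    ])
    return X, scale


@dataclass
class SFCModel:
    fit: CountFit
    scale: dict
    autocov_mean: float
    z_bounds: dict = None
    columns: tuple = SFC_DESIGN_COLUMNS

    def coef(self, name: str) -> tuple[float, float]:
        i = self.columns.index(name)
        return float(self.fit.params[i]), float(self.fit.bse[i])

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "params": self.fit.params.tolist(),
            "bse": self.fit.bse.tolist(),
            "alpha": self.fit.alpha,
            "family": self.fit.family,
            "scale": {k: list(v) for k, v in self.scale.items()},
            "z_bounds": {k: list(v) for k, v in (self.z_bounds or {}).items()},
            "autocov_mean": self.autocov_mean,
        }


def fit_sfc(records: pd.DataFrame) -> SFCModel:
    """Fit the occurrence-frequency model with a survey-count offset."""
    n_params = len(SFC_DESIGN_COLUMNS)
    if len(records) < 10 * n_params:
        raise ValueError(
            f"need >= {10 * n_params} cells for {n_params} parameters; "
            f"have {len(records)}")
    X, scale = sfc_design_matrix(records)
    try:
        fit = fit_count_glm(records["frequency"].to_numpy(), X,
                            offset=records["n_surveys"].to_numpy(),
                            columns=SFC_DESIGN_COLUMNS)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular occurrence design ({SFC_DESIGN_COLUMNS}): {err}")
    z_bounds = {}
    for name, (mu, sd) in scale.items():
        zv = (records[name].to_numpy(dtype=float) - mu) / (sd or 1.0)
        z_bounds[name] = (float(zv.min()), float(zv.max()))
    return SFCModel(fit=fit, scale=scale, z_bounds=z_bounds,
                    autocov_mean=float(records["autocov"].mean()))


def daily_patch_abundance(model: SFCModel, cov: HydroCovariateCube,
                          dates) -> pd.Series:
    """Landscape-mean fitted occurrence rate per survey, one value per day.

    The autocovariate is held at its fitted-period mean; all other
    covariates come from the requested day's layers.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.empty(len(dates))
    for i, date in enumerate(dates):
        layers = cov.day_layers(date)
        flat = pd.DataFrame({name: layers[name].ravel()
                             for name in SFC_COVARIATES})
        flat["autocov"] = model.autocov_mean
        X, _ = sfc_design_matrix(flat, scale=model.scale,
                                 z_bounds=model.z_bounds)
        rate = model.fit.predict_mean(X)
        values[i] = float(np.mean(rate))
    return pd.Series(values, index=dates, name="patch_abundance")
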