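"""Gridded hydrology containers.

The study landscape is a regular grid of 400 m cells. ``DepthCube`` holds a
daily water-depth record per cell (cm; negative = water table below ground)
together with the static ground elevation and a hydrologic-basin ("region")
label per cell. ``HydroCovariateCube`` holds the per-cell, per-day hydrologic
indicators derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_SIZE_M = 400.0


def _as_datetime_index(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(dates)
    if len(idx) == 0:
        raise ValueError("empty date index")
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("date index must be strictly increasing")
    step = np.diff(idx.values).astype("timedelta64[D]")
    if len(step) and not (step == np.timedelta64(1, "D")).all():
        raise ValueError("date index must be daily and gap-free")
    return idx


@dataclass
class DepthCube:
    """Daily water depth (cm) on a regular cell grid.

    Attributes
    ----------
    depth : ndarray, shape (n_days, n_rows, n_cols)
        Water depth above ground, cm. Negative values (below-ground water
        table) are retained.
    dates : pandas.DatetimeIndex
        Daily, strictly increasing, gap-free.
    elevation : ndarray, shape (n_rows, n_cols)
        Ground elevation, cm, in the same vertical datum as stage.
    region : ndarray of str, shape (n_rows, n_cols)
        Hydrologic basin label per cell.
    """

    depth: np.ndarray
    dates: pd.DatetimeIndex
    elevation: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.region = np.asarray(self.region)
        self.dates = _as_datetime_index(self.dates)
        if self.depth.ndim != 3:
            raise ValueError("depth must be (n_days, n_rows, n_cols)")
        if len(self.dates) != self.depth.shape[0]:
            raise ValueError("date index length does not match depth")
        if self.elevation.shape != self.depth.shape[1:]:
            raise ValueError("elevation shape mismatch")
        if self.region.shape != self.depth.shape[1:]:
            raise ValueError("region shape mismatch")

    @property
    def n_days(self) -> int:
        return self.depth.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.depth.shape[1:]

    @property
    def regions(self) -> list[str]:
        return sorted(np.unique(self.region).tolist())

    def day_slice(self, date) -> np.ndarray:
        """Depth grid for one calendar day."""
        loc = self.dates.get_loc(pd.Timestamp(date))
        return self.depth[loc]

    def sel_dates(self, start, end) -> "DepthCube":
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise ValueError("requested window outside cube coverage")
        return DepthCube(self.depth[mask], self.dates[mask], self.elevation, self.region)

    def to_xarray(self):
        import xarray as xr

        return xr.Dataset(
            {
                "depth": (("time", "row", "col"), self.depth),
                "elevation": (("row", "col"), self.elevation),
                "region": (("row", "col"), self.region.astype(str)),
            },
            coords={
                "time": self.dates,
                "row": np.arange(self.grid_shape[0]),
                "col": np.arange(self.grid_shape[1]),
            },
        )

    def to_netcdf(self, path) -> None:
        # scipy backend writes NetCDF3, which has no string type; encode
        # region labels as integer codes with the legend in attrs.
        ds = self.to_xarray()
        labels = self.regions
        codes = np.searchsorted(labels, self.region.astype(str))
        ds["region"] = (("row", "col"), codes.astype("int32"))
        ds["region"].attrs["labels"] = ",".join(labels)
        ds.to_netcdf(path, engine="scipy")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (date, row, col, region, depth) table."""
        nt, nr, nc = self.depth.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        return pd.DataFrame(
            {
                "date": np.repeat(self.dates.values, nr * nc),
                "row": np.tile(rows.ravel(), nt),
                "col": np.tile(cols.ravel(), nt),
                "region": np.tile(self.region.ravel(), nt),
                "depth_cm": self.depth.ravel(),
            }
        )


@dataclass
class HydroCovariateCube:
    """Per-cell, per-day hydrologic indicators.

    depth, recession, dsd and reversal are (n_days, n_rows, n_cols);
    hydroperiod is a static (n_rows, n_cols) grid (multi-year mean annual
    inundation, days/year). NaN marks days with insufficient history.
    """

    dates: pd.DatetimeIndex
    depth: np.ndarray
    recession: np.ndarray
    dsd: np.ndarray
    hydroperiod: np.ndarray
    reversal: np.ndarray
    region: np.ndarray
    dsd_left_censored: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dates = _as_datetime_index(self.dates)
        shape = self.depth.shape
        for name in ("recession", "dsd", "reversal"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape mismatch")
        if self.hydroperiod.shape != shape[1:]:
            raise ValueError("hydroperiod must be a static grid")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dsd) < 0 or np.nanmin(self.reversal) < 0:
                raise ValueError("DSD and reversal must be nonnegative")
            if np.nanmin(self.hydroperiod) < 0 or np.nanmax(self.hydroperiod) > 366:
                raise ValueError("hydroperiod must lie in [0, 366]")

    def day_index(self, date) -> int:
        return self.dates.get_loc(pd.Timestamp(date))

    def day_layers(self, date) -> dict[str, np.ndarray]:
        """All five indicator grids for one day."""
        t = self.day_index(date)
        return {
            "depth": self.depth[t],
            "recession": self.recession[t],
            "dsd": self.dsd[t],
            "hydroperiod": self.hydroperiod,
            "reversal": self.reversal[t],
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cell, date, variable, value) table."""
        nt, nr, nc = self.depth.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        out = []
        layers = {
            "depth": self.depth,
            "recession": self.recession,
            "dsd": self.dsd,
            "reversal": self.reversal,
        }
        for name, arr in layers.items():
            out.append(
                pd.DataFrame(
                    {
                        "date": np.repeat(self.dates.values, nr * nc),
                        "row": np.tile(rows.ravel(), nt),
                        "col": np.tile(cols.ravel(), nt),
                        "variable": name,
                        "value": arr.ravel(),
                    }
                )
            )
        out.append(
            pd.DataFrame(
                {
                    "date": pd.NaT,
                    "row": rows.ravel(),
                    "col": cols.ravel(),
                    "variable": "hydroperiod",
                    "value": self.hydroperiod.ravel(),
                }
            )
        )
        return pd.concat(out, ignore_index=True)
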