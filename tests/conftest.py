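"""Shared fixtures: small random depth cubes and full preset pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from waderhab.grids import DepthCube
from waderhab.pipeline import RunConfig, run_pipeline


def random_depth_cube(rng: np.random.Generator, n_days: int = 400,
                      n_rows: int = 1, n_cols: int = 5,
                      start: str = "2001-01-01") -> DepthCube:
    """Random-walk depth series per cell, crossing the dry threshold often."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    steps = rng.normal(0.0, 2.0, size=(n_days, n_rows, n_cols))
    depth = np.cumsum(steps, axis=0) + rng.normal(5.0, 10.0, size=(1, n_rows, n_cols))
    elevation = rng.normal(0.0, 5.0, size=(n_rows, n_cols))
    region = np.full((n_rows, n_cols), "R1", dtype=object)
    return DepthCube(depth, dates, elevation, region)


@pytest.fixture(scope="session")
def preset_runs(tmp_path_factory):
    """Full pipeline runs of the two shipped presets at default scale.

    Session-scoped: the comparison tests and the scenario-contrast
    acceptance check all read from the same pair of runs.
    """
    root = tmp_path_factory.mktemp("preset_runs")
    out = {}
    for preset in ("steady-recession", "reversal-heavy"):
        outdir = root / preset
        manifest = run_pipeline(RunConfig(preset=preset, outdir=str(outdir),
                                          seed=20130531))
        out[preset] = {"outdir": outdir, "manifest": manifest}
    return out
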