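"""Synthetic landscape, hydrology, survey, and nest-history generator.

Emulates the data streams of a subtropical wetland monitoring program on a
regular 400 m cell grid:

* a nearly flat landscape (regional slopes of a few cm per km) with
  spatially correlated microtopography;
* a seasonal water-stage cycle — wet-season peak followed by a dry-season
  recession, optionally interrupted by rainfall "reversal" events that
  re-raise stage mid-season;
* aerial belt-transect bird counts (transects every 5th grid row ≈ 2 km
  spacing) drawn from a negative-binomial count model whose log-mean is
  linear in standardized hydrologic covariates, with hard availability
  masking outside the species' foraging depth range;
* nest-check histories visited every 5–7 days, with a logit-linear link
  from the daily foraging index (FI) to daily nest survival.

Every stochastic draw flows through one :class:`numpy.random.Generator`
seeded from the scenario, so a fixed seed reproduces all outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import DepthCube
from .hydro import compute_covariates
from .species import SpeciesProfile

#: default ground-truth log-scale selection coefficients on standardized
#: (depth, recession, DSD): shallower water, faster drying, and longer
#: inundation histories all raise expected counts inside the depth range.
DEFAULT_TRUTH_COEFS = {
    "intercept": 0.4,
    "depth": -0.3,
    "recession": 0.5,
    "dsd": 0.4,
}


@dataclass
class SyntheticScenario:
    """Parametric ground truth for one simulated study.

    Stage parameters are per dry season; multi-year runs redraw the Jan 1
    stage and recession rate around the preset means, add the configured
    wet-decade stage bonus in 1993–1999, and draw the number of reversal
    events per season from a Poisson law.
    """

    name: str = "steady-recession"
    n_rows: int = 25
    n_cols: int = 25
    slope_cm_per_km: float = 4.5
    microtopo_sd_cm: float = 6.0
    microtopo_corr_cells: float = 2.0
    # single-season stage parameters
    init_stage_cm: float = 55.0          # stage above mean ground on Jan 1
    recession_cm_per_day: float = 0.5
    reversals: tuple = ()                # [(date, rise_cm), ...]
    season_start: str = "11-01"          # Nov 1 of the preceding year
    season_end: str = "05-31"
    # multi-year variation
    start_year: int = 1993
    n_years: int = 21
    init_stage_sd_cm: float = 8.0
    recession_sd: float = 0.15
    # local stage anomaly (spatially correlated, AR(1) in time): emulates
    # patchy rainfall/flow so recession varies across cells within a day
    stage_anomaly_sd_cm: float = 2.0
    stage_anomaly_rho: float = 0.95
    reversal_rate_per_season: float = 0.3
    reversal_rise_range_cm: tuple = (8.0, 12.0)
    wet_decade_bonus_cm: float = 12.0
    wet_decade_years: tuple = (1993, 1999)  # inclusive bounds
    # survey truth
    truth_coefs: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_COEFS))
    nb_dispersion: float = 2.0           # NB size k; np.inf = Poisson limit
    transect_row_step: int = 5           # every 5th row = 2 km at 400 m cells
    # nest truth: daily survival = invlogit(a + b * FI_scaled)
    nest_survival_intercept: float = 3.476   # invlogit -> 0.97/day
    nest_survival_fi_slope: float = 0.8
    fi_ref_mean: float = 60.0            # fixed reference scale for FI
    fi_ref_sd: float = 40.0
    nest_base_starts: float = 80.0       # expected starts per species-year
    nest_effort_fi_coef: float = 0.5     # log-scale effect of March FI
    n_colonies: int = 3
    seed: int = 20130531

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.recession_cm_per_day < 0:
            raise ValueError("recession rate must be nonnegative")
        for _, rise in self.reversals:
            if rise <= 0:
                raise ValueError("reversal rises must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


PRESETS = {
    # mirrors a high-initial-stage year with an uninterrupted drying pattern
    "steady-recession": dict(
        name="steady-recession", init_stage_cm=55.0,
        recession_cm_per_day=0.5, reversal_rate_per_season=0.3),
    # low initial stage with frequent mid-season rewetting events
    "reversal-heavy": dict(
        name="reversal-heavy", init_stage_cm=30.0,
        recession_cm_per_day=0.7, reversal_rate_per_season=2.5),
    # decade contrasts: same drying dynamics, shifted initial stage
    "wet-decade": dict(
        name="wet-decade", init_stage_cm=62.0,
        recession_cm_per_day=0.5, reversal_rate_per_season=0.5),
    "dry-decade": dict(
        name="dry-decade", init_stage_cm=38.0,
        recession_cm_per_day=0.6, reversal_rate_per_season=0.5),
}


def scenario_preset(name: str, **overrides) -> SyntheticScenario:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticScenario(**kwargs)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_topography(scenario: SyntheticScenario,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Planar ramp plus correlated Gaussian microtopography (cm).

    The ramp runs along columns at the configured regional slope; the noise
    field is mean-zero with the configured marginal SD and correlation
    length (Gaussian-filtered white noise, rescaled).
    """
    rng = scenario.rng() if rng is None else rng
    km_per_cell = 0.4
    cols = np.arange(scenario.n_cols) * km_per_cell
    ramp = np.broadcast_to(scenario.slope_cm_per_km * cols,
                           (scenario.n_rows, scenario.n_cols)).copy()
    if scenario.microtopo_sd_cm > 0:
        white = rng.standard_normal((scenario.n_rows, scenario.n_cols))
        noise = gaussian_filter(white, sigma=scenario.microtopo_corr_cells,
                                mode="reflect")
        noise -= noise.mean()
        sd = noise.std()
        if sd > 0:
            noise *= scenario.microtopo_sd_cm / sd
        ramp += noise
    return ramp


def default_regions(n_rows: int, n_cols: int) -> np.ndarray:
    """Quadrant basin labels (NW/NE/SW/SE)."""
    region = np.empty((n_rows, n_cols), dtype=object)
    half_r, half_c = n_rows // 2, n_cols // 2
    region[:half_r, :half_c] = "NW"
    region[:half_r, half_c:] = "NE"
    region[half_r:, :half_c] = "SW"
    region[half_r:, half_c:] = "SE"
    return region


# ---------------------------------------------------------------------------
# stage
# ---------------------------------------------------------------------------

def generate_stage_series(scenario: SyntheticScenario, year: int | None = None,
                          ) -> pd.Series:
    """Single-season daily stage (cm, relative to mean ground elevation).

    From the season start (Nov 1 of the preceding year) stage ramps up to
    the configured initial dry-season value on Jan 1, then declines at the
    recession rate; each reversal event adds its rise on its date and the
    decline resumes.
    """
    year = scenario.start_year if year is None else year
    sm, sd = (int(x) for x in scenario.season_start.split("-"))
    em, ed = (int(x) for x in scenario.season_end.split("-"))
    start = pd.Timestamp(year - 1, sm, sd)
    end = pd.Timestamp(year, em, ed)
    dates = pd.date_range(start, end, freq="D")
    jan1 = pd.Timestamp(year, 1, 1)
    days_from_jan1 = (dates - jan1).days.values.astype(float)
    stage = np.where(
        days_from_jan1 < 0,
        # wet-season ramp up to the Jan 1 stage
        scenario.init_stage_cm + 0.25 * days_from_jan1,
        scenario.init_stage_cm - scenario.recession_cm_per_day * days_from_jan1,
    )
    for when, rise in scenario.reversals:
        when = pd.Timestamp(when)
        if not (start <= when <= end):
            raise ValueError(f"reversal date {when.date()} outside the series")
        stage[dates >= when] += rise
    return pd.Series(stage, index=dates, name="stage_cm")


def generate_multiyear_stage(scenario: SyntheticScenario,
                             rng: np.random.Generator) -> pd.Series:
    """Daily stage over complete calendar years start_year−1 … last year.

    Jan 1 stage and recession rate are redrawn per year; wet-decade years
    get the configured stage bonus. Jun–Dec interpolates linearly from the
    end-of-May stage to the next year's Jan 1 stage.
    """
    y0, y1 = scenario.start_year - 1, scenario.start_year + scenario.n_years - 1
    dates = pd.date_range(pd.Timestamp(y0, 1, 1), pd.Timestamp(y1, 12, 31), freq="D")
    stage = np.empty(len(dates))
    lo, hi = scenario.wet_decade_years
    init = {}
    for y in range(y0, y1 + 2):
        v = scenario.init_stage_cm + scenario.init_stage_sd_cm * rng.standard_normal()
        if lo <= y <= hi:
            v += scenario.wet_decade_bonus_cm
        init[y] = v
    for y in range(y0, y1 + 1):
        rate = max(0.1, scenario.recession_cm_per_day
                   + scenario.recession_sd * rng.standard_normal())
        n_rev = rng.poisson(scenario.reversal_rate_per_season)
        rev_days = np.sort(rng.integers(20, 140, size=n_rev))  # Jan 21–May 20
        rlo, rhi = scenario.reversal_rise_range_cm
        rev_rise = rng.uniform(rlo, rhi, size=n_rev)
        sel = (dates.year == y)
        doy = np.arange(sel.sum(), dtype=float)
        may31 = (pd.Timestamp(y, 5, 31) - pd.Timestamp(y, 1, 1)).days
        s = init[y] - rate * np.minimum(doy, may31)
        for d, r in zip(rev_days, rev_rise):
            s[doy >= d] += r
        # wet season: linear climb from the end-of-May stage to next Jan 1
        dec31 = len(doy) - 1
        wet = doy > may31
        frac = (doy[wet] - may31) / (dec31 - may31 + 1)
        s[wet] = s[may31] + frac * (init[y + 1] - s[may31])
        stage[sel] = s
    return pd.Series(stage, index=dates, name="stage_cm")


def generate_depth_cube(scenario: SyntheticScenario,
                        rng: np.random.Generator | None = None) -> DepthCube:
    """Multi-year DepthCube: topography + stage, depth = stage − elevation."""
    rng = scenario.rng() if rng is None else rng
    elev = generate_topography(scenario, rng)
    elev_centered = elev - elev.mean()   # stage is relative to mean ground
    stage = generate_multiyear_stage(scenario, rng)
    region = default_regions(scenario.n_rows, scenario.n_cols)
    full_stage = stage.values[:, None, None] + _stage_anomaly(
        scenario, len(stage), rng)
    depth = full_stage - elev_centered[None, :, :]
    return DepthCube(depth, stage.index, elev_centered, region)


def _stage_anomaly(scenario: SyntheticScenario, n_days: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated AR(1) water-surface anomaly (cm)."""
    sd = scenario.stage_anomaly_sd_cm
    if sd <= 0:
        return np.zeros((n_days, scenario.n_rows, scenario.n_cols))
    rho = scenario.stage_anomaly_rho
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    out = np.empty((n_days, scenario.n_rows, scenario.n_cols))
    shape = (scenario.n_rows, scenario.n_cols)
    smooth = lambda f: gaussian_filter(f, sigma=scenario.microtopo_corr_cells,
                                       mode="reflect")
    # rescale the filtered field so the marginal SD is as configured
    probe = smooth(rng.standard_normal(shape))
    gain = 1.0 / (probe.std() or 1.0)
    out[0] = smooth(rng.standard_normal(shape)) * gain * sd
    for t in range(1, n_days):
        out[t] = rho * out[t - 1] + smooth(
            rng.standard_normal(shape)) * gain * innov_sd
    return out


def survey_dates_for_year(year: int, freq_days: int = 7) -> pd.DatetimeIndex:
    """Weekly aerial-survey dates through the Jan–May dry season."""
    return pd.date_range(pd.Timestamp(year, 1, 7), pd.Timestamp(year, 5, 28),
                         freq=f"{freq_days}D")


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def covariate_scale(cov, dates) -> dict[str, tuple[float, float]]:
    """Season mean/SD of depth, recession and DSD over all cells and days."""
    idx = [cov.day_index(d) for d in dates]
    out = {}
    for name in ("depth", "recession", "dsd"):
        arr = getattr(cov, name)[idx]
        out[name] = (float(np.nanmean(arr)), float(np.nanstd(arr)) or 1.0)
    return out


def simulate_surveys(cov, profile: SpeciesProfile, survey_dates,
                     rng: np.random.Generator,
                     truth_coefs: dict | None = None,
                     nb_dispersion: float = 2.0,
                     transect_row_step: int = 5,
                     scale: dict | None = None) -> pd.DataFrame:
    """Belt-transect counts from the ground-truth selection model.

    Counts in cells whose depth lies outside the species range are zero by
    construction; inside the range, the expected count is
    ``exp(b0 + Σ b_i z_i)`` on standardized (depth, recession, DSD) and the
    realized count is negative-binomial with size ``nb_dispersion``
    (Poisson in the infinite-dispersion limit).
    """
    truth = dict(DEFAULT_TRUTH_COEFS if truth_coefs is None else truth_coefs)
    names = [k for k in truth if k != "intercept"]
    bad = set(names) - {"depth", "recession", "dsd"}
    if bad:
        raise ValueError(f"truth coefficients for unknown covariates: {sorted(bad)}")
    scale = covariate_scale(cov, survey_dates) if scale is None else scale
    rows = np.arange(0, cov.depth.shape[1], transect_row_step)
    out = []
    for date in survey_dates:
        t = cov.day_index(date)
        depth = cov.depth[t][rows]
        available = ((depth >= profile.depth_min_cm)
                     & (depth <= profile.depth_max_cm))
        lp = np.full(depth.shape, truth["intercept"])
        for name in names:
            arr = getattr(cov, name)[t][rows]
            mu_s, sd_s = scale[name]
            lp += truth[name] * (arr - mu_s) / sd_s
        mean = np.where(available & np.isfinite(lp), np.exp(lp), 0.0)
        if np.isfinite(nb_dispersion):
            k = nb_dispersion
            counts = np.where(mean > 0,
                              rng.negative_binomial(k, k / (k + mean)), 0)
        else:
            counts = np.where(mean > 0, rng.poisson(mean), 0)
        rr, cc = np.meshgrid(rows, np.arange(depth.shape[1]), indexing="ij")
        out.append(pd.DataFrame({
            "date": pd.Timestamp(date),
            "row": rr.ravel(), "col": cc.ravel(),
            "species": profile.name,
            "count": counts.ravel().astype(int),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# region-day level generator (for model-recovery testing)
# ---------------------------------------------------------------------------

def simulate_region_days(n: int, rng: np.random.Generator,
                         use_coefs: np.ndarray | None = None,
                         abund_coefs: tuple = (1.0, 0.8),
                         noise_sd: float = 0.1,
                         nb_dispersion: float = 5.0) -> pd.DataFrame:
    """Region-day summaries with known use- and abundance-model truth.

    ``use_coefs`` are the 10 coefficients of the use model design
    (intercept, 3 availability means, 3 pairwise mean interactions, 3 SDs);
    observed use adds Gaussian noise. Individual totals are NB with
    log-mean ``abund_coefs[0] + abund_coefs[1]·use``; flock totals are a
    thinned copy (so flocks ≤ individuals row-wise).
    """
    from .tfc import use_design_matrix

    means = rng.normal(0.0, 1.0, size=(n, 3))
    sds = rng.uniform(0.2, 1.0, size=(n, 3))
    df = pd.DataFrame({
        "mean_depth": means[:, 0], "mean_recession": means[:, 1],
        "mean_dsd": means[:, 2],
        "sd_depth": sds[:, 0], "sd_recession": sds[:, 1], "sd_dsd": sds[:, 2],
    })
    X = use_design_matrix(df)
    if use_coefs is None:
        use_coefs = np.zeros(X.shape[1])
        use_coefs[0], use_coefs[1] = 0.5, 1.0     # intercept + depth mean
    use_coefs = np.asarray(use_coefs, dtype=float)
    if use_coefs.shape[0] != X.shape[1]:
        raise ValueError("use_coefs length mismatch with design")
    df["use_depth"] = X @ use_coefs + rng.normal(0.0, noise_sd, size=n)
    a0, a1 = abund_coefs
    mu = np.exp(a0 + a1 * (X @ use_coefs))
    k = nb_dispersion
    indiv = rng.negative_binomial(k, k / (k + mu))
    flocks = rng.binomial(indiv, 0.6)
    flocks = np.maximum(flocks, (indiv > 0).astype(int))
    df["individuals"] = indiv
    df["flocks"] = flocks
    return df


# ---------------------------------------------------------------------------
# nests
# ---------------------------------------------------------------------------

def simulate_nests(fi_series: pd.Series, scenario: SyntheticScenario,
                   profile: SpeciesProfile, rng: np.random.Generator,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nest-check histories and per-round effort counts driven by FI.

    Daily nest survival is ``invlogit(a + b · FI_scaled)`` where FI is
    scaled by the scenario's fixed reference mean/SD. Nest starts per year
    are Poisson with log-intensity increasing in the March mean of scaled
    FI; start dates fall in Feb 15–Mar 15; visits are spaced 5–7 days.

    Returns ``(visits, effort)`` tables. ``visits`` has one row per nest
    check (nest_id, colony, species, date, status); ``effort`` one row per
    monthly survey round (year, species, round_date, n_active).
    """
    if len(fi_series) == 0:
        raise ValueError("empty FI series")
    fi_series = fi_series.sort_index()
    z = (fi_series - scenario.fi_ref_mean) / scenario.fi_ref_sd
    a = scenario.nest_survival_intercept
    b = scenario.nest_survival_fi_slope
    T = profile.nest_cycle_days
    visits, effort_rows = [], []
    nest_counter = 0
    for year, zy in z.groupby(z.index.year):
        march = zy[(zy.index.month == 3)]
        if len(march) == 0:
            continue
        # intensity bounded to base × e^±3 to keep cohort sizes physical
        lam = scenario.nest_base_starts * np.exp(
            np.clip(scenario.nest_effort_fi_coef * float(march.mean()), -3, 3))
        n_starts = rng.poisson(lam)
        # starts in early March: incubation through March, chicks in nests
        # through April–May, the period the breeding cycle is sensitive to
        window_start = pd.Timestamp(year, 3, 1)
        start_offsets = rng.integers(0, 15, size=n_starts)  # Mar 1–Mar 15
        nests = []
        for off in start_offsets:
            nest_counter += 1
            start = window_start + pd.Timedelta(int(off), "D")
            colony = f"colony_{rng.integers(scenario.n_colonies) + 1}"
            # latent failure day: first day the daily survival draw fails
            fail_age = None
            for age in range(1, T + 1):
                day = start + pd.Timedelta(age, "D")
                s = expit(a + b * float(z.get(day, 0.0)))
                if rng.random() > s:
                    fail_age = age
                    break
            nests.append((nest_counter, colony, start, fail_age))
            # visit schedule: day 0 then every 5–7 days until terminal
            nid = nest_counter
            age = 0
            while True:
                day = start + pd.Timedelta(age, "D")
                if fail_age is not None and age >= fail_age:
                    status = "failed"
                elif age >= T:
                    status = "fledged"
                else:
                    status = "active"
                visits.append((nid, colony, profile.name, day, status))
                if status != "active":
                    break
                age += int(rng.integers(5, 8))
        # monthly effort rounds on the 15th, Jan–May
        for month in range(1, 6):
            round_date = pd.Timestamp(year, month, 15)
            n_active = sum(
                1 for _, _, start, fail_age in nests
                if start <= round_date
                and (fail_age is None or start + pd.Timedelta(fail_age, "D") > round_date)
                and start + pd.Timedelta(T, "D") > round_date)
            effort_rows.append((year, profile.name, round_date, n_active))
    visits_df = pd.DataFrame(
        visits, columns=["nest_id", "colony", "species", "date", "status"])
    effort_df = pd.DataFrame(
        effort_rows, columns=["year", "species", "round_date", "n_active"])
    return visits_df, effort_df


def simulate_season_table(n_years: int, rng: np.random.Generator,
                          effect_coefs: dict[str, float] | None = None,
                          response: str = "effort",
                          noise_sd: float = 1.0,
                          start_year: int = 1993) -> pd.DataFrame:
    """Season covariate table with a known response-generating model.

    All index columns (season means/SEs, monthly means and Δs) are drawn
    independently standard normal (season SE columns folded positive); the
    response is the linear combination in ``effect_coefs`` plus Gaussian
    noise. Used for multimodel-inference recovery testing.
    """
    effect_coefs = effect_coefs or {"mar_delta": 1.0, "mean_tfc": 1.0}
    cols = (["mean_tfc", "se_tfc", "mean_fi", "se_fi", "mean_ratio", "se_ratio"]
            + [f"{m}_{v}" for m in ("jan", "feb", "mar", "apr")
               for v in ("tfc", "fi", "delta")])
    data = {c: rng.normal(0.0, 1.0, size=n_years) for c in cols}
    for c in cols:
        if c.startswith("se_"):
            data[c] = np.abs(data[c])
    df = pd.DataFrame(data)
    df.insert(0, "year", np.arange(start_year, start_year + n_years))
    df["decade"] = np.where(df["year"] < 2000, "1993-1999", "2000-2013")
    y = rng.normal(0.0, noise_sd, size=n_years)
    for term, coef in effect_coefs.items():
        y = y + coef * df[term].to_numpy()
    df[response] = y
    return df


def scenario_covariates(scenario: SyntheticScenario,
                        rng: np.random.Generator | None = None):
    """Convenience: depth cube + full covariate cube for a scenario."""
    cube = generate_depth_cube(scenario, rng)
    return cube, compute_covariates(cube)
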