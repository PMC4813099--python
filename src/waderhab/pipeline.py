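"""End-to-end pipeline: scenario → hydrology → TFC/SFC → indices → nests → MMI.

Stages run in dependency order with one shared seeded RNG, write plain-text
artifacts (CSV/JSON) under the output directory, and record every artifact
with a SHA-256 checksum in ``manifest.json``. A rerun with the same
configuration and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hydro, indices, mmi, nests, sfc, tfc
from .candidate_sets import load_candidate_set
from .species import DEFAULT_SPECIES, get_profile
from .synthetic import (SyntheticScenario, scenario_preset, simulate_nests,
                        simulate_surveys, covariate_scale,
                        generate_depth_cube, survey_dates_for_year)

log = logging.getLogger("waderhab.pipeline")

STAGES = ("scenario", "surveys", "tfc", "sfc", "indices", "nests", "mmi")

#: species whose nesting success is modeled (stork success is effort-only;
#: its success samples are too sparse to estimate)
SUCCESS_SPECIES = ("great_egret", "white_ibis")

#: responses fourth-root transformed before Gaussian fitting
FOURTH_ROOT_EFFORT = ("wood_stork",)


@dataclass
class RunConfig:
    preset: str = "steady-recession"
    species: tuple = tuple(DEFAULT_SPECIES)
    outdir: str = "waderhab_run"
    seed: int = 20130531
    scenario_overrides: dict = field(default_factory=dict)
    dry_threshold_cm: float = hydro.DRY_THRESHOLD_CM
    recession_window: int = hydro.RECESSION_WINDOW_DAYS
    dsd_cap: int = hydro.DSD_CAP_DAYS
    stage: str = "mmi"          # run through this stage (inclusive)
    write_depth_cube: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.10g")


def _dry_season_dates(scenario: SyntheticScenario) -> pd.DatetimeIndex:
    """Every Jan 1 – May 31 day of every study year."""
    parts = [pd.date_range(pd.Timestamp(y, 1, 1), pd.Timestamp(y, 5, 31))
             for y in range(scenario.start_year,
                            scenario.start_year + scenario.n_years)]
    return parts[0].append(parts[1:])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.stage not in STAGES:
        raise ValueError(f"unknown stage {config.stage!r}; choose from {STAGES}")
    last = STAGES.index(config.stage)
    artifacts: dict[str, Path] = {}
    manifest = {"config": {**config.__dict__, "species": list(config.species),
                           "scenario_overrides": dict(config.scenario_overrides)},
                "stages": [], "artifacts": {}}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = path

    def stage_done(name: str) -> None:
        manifest["stages"].append(name)
        log.info("stage %s complete", name)

    # ---- stage: scenario (landscape + hydrology) --------------------------
    scenario = scenario_preset(config.preset, seed=config.seed,
                               **config.scenario_overrides)
    rng = scenario.rng()
    log.info("stage scenario: preset=%s grid=%dx%d years=%d seed=%d",
             scenario.name, scenario.n_rows, scenario.n_cols,
             scenario.n_years, scenario.seed)
    cube = generate_depth_cube(scenario, rng)
    cov = hydro.compute_covariates(
        cube, dry_threshold_cm=config.dry_threshold_cm,
        recession_window=config.recession_window, dsd_cap=config.dsd_cap)
    with open(outdir / "scenario.json", "w") as fh:
        json.dump({"seed": scenario.seed, **scenario.to_dict()}, fh,
                  indent=2, default=str)
    emit("scenario", outdir / "scenario.json")
    elev = pd.DataFrame({
        "row": np.repeat(np.arange(scenario.n_rows), scenario.n_cols),
        "col": np.tile(np.arange(scenario.n_cols), scenario.n_rows),
        "region": cube.region.ravel(),
        "elevation_cm": cube.elevation.ravel(),
    })
    _write_csv(elev, outdir / "elevation.csv")
    emit("elevation", outdir / "elevation.csv")
    regional_depth = (cube.to_frame().groupby(["date", "region"], as_index=False)
                      ["depth_cm"].mean())
    _write_csv(regional_depth, outdir / "regional_depth.csv")
    emit("regional_depth", outdir / "regional_depth.csv")
    if config.write_depth_cube:
        cube.to_netcdf(outdir / "depth_cube.nc")
        emit("depth_cube", outdir / "depth_cube.nc")
    stage_done("scenario")

    survey_dates_all = {
        y: survey_dates_for_year(y)
        for y in range(scenario.start_year,
                       scenario.start_year + scenario.n_years)}
    flat_dates = [d for dates in survey_dates_all.values() for d in dates]

    surveys = daily = season_tables = None
    if last >= STAGES.index("surveys"):
        # ---- stage: surveys ----------------------------------------------
        scale = covariate_scale(cov, flat_dates)
        frames = []
        for name in config.species:
            profile = get_profile(name)
            frames.append(simulate_surveys(
                cov, profile, flat_dates, rng,
                truth_coefs=scenario.truth_coefs,
                nb_dispersion=scenario.nb_dispersion,
                transect_row_step=scenario.transect_row_step, scale=scale))
        surveys = pd.concat(frames, ignore_index=True)
        _write_csv(surveys, outdir / "surveys.csv")
        emit("surveys", outdir / "surveys.csv")
        stage_done("surveys")

    tfc_landscape = {}
    if last >= STAGES.index("tfc"):
        # ---- stage: tfc --------------------------------------------------
        predict_dates = _dry_season_dates(scenario)
        tfc_models = {}
        per_region_frames, landscape_frames = [], []
        for name in config.species:
            profile = get_profile(name)
            sp_surveys = surveys[surveys["species"] == name]
            table = tfc.build_training_table(
                cov, sp_surveys, profile, flat_dates,
                transect_row_step=scenario.transect_row_step)
            use_model = tfc.fit_use_model(table)
            pred_table = use_model.predict(table)
            abund_model = tfc.fit_abundance_model(pred_table)
            tfc_models[name] = {"use": use_model.to_dict(),
                                "abundance": abund_model.to_dict()}
            per_region, landscape = tfc.predict_daily_abundance(
                use_model, abund_model, cov, profile, predict_dates)
            per_region_frames.append(per_region)
            landscape_frames.append(landscape)
            tfc_landscape[name] = landscape
        with open(outdir / "tfc_models.json", "w") as fh:
            json.dump(tfc_models, fh, indent=2)
        emit("tfc_models", outdir / "tfc_models.json")
        _write_csv(pd.concat(landscape_frames, ignore_index=True),
                   outdir / "daily_abundance.csv")
        emit("daily_abundance", outdir / "daily_abundance.csv")
        stage_done("tfc")

    patch = {}
    if last >= STAGES.index("sfc"):
        # ---- stage: sfc --------------------------------------------------
        predict_dates = _dry_season_dates(scenario)
        sfc_models = {}
        patch_frames = []
        for name in config.species:
            records = sfc.build_cell_records(
                cov, surveys, name, flat_dates,
                transect_row_step=scenario.transect_row_step)
            model = sfc.fit_sfc(records)
            sfc_models[name] = model.to_dict()
            series = sfc.daily_patch_abundance(model, cov, predict_dates)
            patch[name] = series
            patch_frames.append(pd.DataFrame({
                "date": series.index, "species": name,
                "patch_abundance": series.values}))
        with open(outdir / "sfc_models.json", "w") as fh:
            json.dump(sfc_models, fh, indent=2)
        emit("sfc_models", outdir / "sfc_models.json")
        _write_csv(pd.concat(patch_frames, ignore_index=True),
                   outdir / "patch_abundance.csv")
        emit("patch_abundance", outdir / "patch_abundance.csv")
        stage_done("sfc")

    if last >= STAGES.index("indices"):
        # ---- stage: indices ----------------------------------------------
        daily = {}
        season_tables = {}
        daily_frames, season_frames = [], []
        for name in config.species:
            d = indices.build_daily_series(tfc_landscape[name], patch[name])
            daily[name] = d
            season = indices.build_season_table(d)
            season_tables[name] = season
            daily_frames.append(d)
            season_frames.append(season)
        _write_csv(pd.concat(daily_frames, ignore_index=True),
                   outdir / "daily_index.csv")
        emit("daily_index", outdir / "daily_index.csv")
        _write_csv(pd.concat(season_frames, ignore_index=True),
                   outdir / "season_table.csv")
        emit("season_table", outdir / "season_table.csv")
        stage_done("indices")

    if last >= STAGES.index("nests"):
        # ---- stage: nests ------------------------------------------------
        visit_frames, metric_frames = [], []
        for name in config.species:
            profile = get_profile(name)
            d = daily[name]
            fi_series = pd.Series(d["fi"].to_numpy(),
                                  index=pd.DatetimeIndex(d["date"]))
            visits, effort = simulate_nests(fi_series, scenario, profile, rng)
            visit_frames.append(visits)
            eff = nests.annual_effort(effort)
            metrics = eff
            if name in SUCCESS_SPECIES and not visits.empty:
                succ = nests.annual_success_table(visits, profile.nest_cycle_days)
                metrics = eff.merge(succ, on="year", how="left")
            season_tables[name] = season_tables[name].merge(
                metrics.drop(columns=["species"], errors="ignore"),
                on="year", how="left")
            metric_frames.append(metrics.assign(species=name))
        _write_csv(pd.concat(visit_frames, ignore_index=True),
                   outdir / "nest_visits.csv")
        emit("nest_visits", outdir / "nest_visits.csv")
        _write_csv(pd.concat(metric_frames, ignore_index=True),
                   outdir / "nest_metrics.csv")
        emit("nest_metrics", outdir / "nest_metrics.csv")
        _write_csv(pd.concat(season_tables.values(), ignore_index=True),
                   outdir / "season_table.csv")
        stage_done("nests")

    if last >= STAGES.index("mmi"):
        # ---- stage: mmi --------------------------------------------------
        summary = {}
        for name in config.species:
            table = season_tables[name]
            transform = ("fourth-root" if name in FOURTH_ROOT_EFFORT
                         else "identity")
            sp_summary = {}
            specs = load_candidate_set("effort", "effort", transform=transform)
            result = mmi.run_mmi(table, specs)
            _write_csv(result.ranking, outdir / f"mmi_effort_{name}_ranking.csv")
            emit(f"mmi_effort_{name}_ranking",
                 outdir / f"mmi_effort_{name}_ranking.csv")
            _write_csv(result.averaged, outdir / f"mmi_effort_{name}_averaged.csv")
            emit(f"mmi_effort_{name}_averaged",
                 outdir / f"mmi_effort_{name}_averaged.csv")
            sp_summary["effort"] = {
                "top_model": result.ranking["model"].iloc[0],
                "r2": result.r2,
                "importance": result.importance,
            }
            if name in SUCCESS_SPECIES and "success" in table.columns \
                    and table["success"].notna().sum() >= 8:
                specs = load_candidate_set("success", "success")
                result = mmi.run_mmi(table, specs)
                _write_csv(result.ranking,
                           outdir / f"mmi_success_{name}_ranking.csv")
                emit(f"mmi_success_{name}_ranking",
                     outdir / f"mmi_success_{name}_ranking.csv")
                _write_csv(result.averaged,
                           outdir / f"mmi_success_{name}_averaged.csv")
                emit(f"mmi_success_{name}_averaged",
                     outdir / f"mmi_success_{name}_averaged.csv")
                sp_summary["success"] = {
                    "top_model": result.ranking["model"].iloc[0],
                    "r2": result.r2,
                    "importance": result.importance,
                }
                sub = table.dropna(subset=["effort", "success"])
                if len(sub) >= 4 and sub["success"].std() > 0 \
                        and sub["effort"].std() > 0:
                    rs, p, n = mmi.effort_success_correlation(
                        sub["effort"], sub["success"])
                    sp_summary["effort_success_spearman"] = {
                        "rs": rs, "p": p, "n": n}
            summary[name] = sp_summary
        with open(outdir / "mmi_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        emit("mmi_summary", outdir / "mmi_summary.json")
        stage_done("mmi")

    manifest["artifacts"] = {
        name: {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
        for name, path in artifacts.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
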