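"""Temporal foraging-conditions chain: masks, summaries, use and abundance fits."""

import numpy as np
import pandas as pd
import pytest

from waderhab import hydro, tfc
from waderhab.grids import DepthCube, HydroCovariateCube
from waderhab.species import GREAT_EGRET, SpeciesProfile
from waderhab.synthetic import simulate_region_days


def toy_cov(depth_grids, dates=None) -> HydroCovariateCube:
    """Covariate cube with recession = depth/10 and dsd = depth*2 (distinct)."""
    depth = np.asarray(depth_grids, dtype=float)
    dates = pd.date_range("2005-01-01", periods=depth.shape[0], freq="D") \
        if dates is None else pd.DatetimeIndex(dates)
    nr, nc = depth.shape[1:]
    region = np.empty((nr, nc), dtype=object)
    region[:, : nc // 2] = "W"
    region[:, nc // 2:] = "E"
    return HydroCovariateCube(
        dates=dates, depth=depth, recession=depth / 10.0, dsd=np.abs(depth) * 2,
        hydroperiod=np.full((nr, nc), 200.0), reversal=np.zeros_like(depth),
        region=region)


class TestAvailabilityMask:
    def test_closed_interval_and_below_ground(self):
        profile = SpeciesProfile("t", 5.0, 30.0, 14, 21)
        depth = np.array([[5.0, 30.0, 4.99, -2.0, 31.0]])
        mask = tfc.availability_mask(depth, profile)
        assert mask.tolist() == [[True, True, False, False, False]]

    def test_cardinality_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(-10, 50, size=(8, 8))
        mask = tfc.availability_mask(depth, GREAT_EGRET)
        brute = sum(GREAT_EGRET.depth_min_cm <= d <= GREAT_EGRET.depth_max_cm
                    for d in depth.ravel())
        assert mask.sum() == brute

    def test_shrinking_range_never_gains_cells(self):
        rng = np.random.default_rng(1)
        depth = rng.uniform(-10, 50, size=(10, 10))
        wide = tfc.availability_mask(depth, SpeciesProfile("w", 0, 40, 14, 21))
        narrow = tfc.availability_mask(depth, SpeciesProfile("n", 5, 35, 14, 21))
        assert narrow.sum() <= wide.sum()
        assert not (narrow & ~wide).any()


class TestRegionalSummary:
    def test_single_cell_sd_zero(self):
        cov = toy_cov(np.full((1, 2, 2), -5.0))
        cov.depth[0, 0, 0] = 10.0  # only one cell in range
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        out = tfc.regional_resource_summary(cov, mask, "2005-01-01", "sp")
        assert len(out) == 1
        assert out["sd_depth"].iloc[0] == 0.0
        assert out["mean_depth"].iloc[0] == 10.0

    def test_two_cells_mean_and_sample_sd(self):
        cov = toy_cov(np.zeros((1, 1, 2)))
        cov.depth[0, 0, 0], cov.depth[0, 0, 1] = 10.0, 20.0
        mask = np.ones((1, 2), dtype=bool)
        out = tfc.regional_resource_summary(cov, mask, "2005-01-01", "sp")
        west = out[out["region"] == "W"].iloc[0]
        assert west["mean_depth"] == 10.0
        # two-cell region pooled per region: W has 1 cell, E has 1 cell
        assert len(out) == 2

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        cov = toy_cov(rng.uniform(-5, 40, size=(1, 6, 6)))
        mask = rng.random((6, 6)) > 0.4
        out = tfc.regional_resource_summary(cov, mask, "2005-01-01", "sp")
        for _, row in out.iterrows():
            sel = mask & (cov.region == row["region"])
            vals = cov.depth[0][sel]
            assert row["mean_depth"] == pytest.approx(vals.mean())
            expected_sd = np.sqrt(((vals - vals.mean()) ** 2).sum()
                                  / (len(vals) - 1)) if len(vals) > 1 else 0.0
            assert row["sd_depth"] == pytest.approx(expected_sd)
            assert row["n_available"] == sel.sum()

    def test_empty_region_emits_no_row(self):
        cov = toy_cov(np.zeros((1, 2, 4)))
        mask = np.zeros((2, 4), dtype=bool)
        mask[:, 3] = True  # only the eastern region
        out = tfc.regional_resource_summary(cov, mask, "2005-01-01", "sp")
        assert set(out["region"]) == {"E"}


class TestObservedUse:
    def _surveys(self, rows):
        return pd.DataFrame(rows, columns=["date", "row", "col", "species",
                                           "count"])

    def test_all_birds_in_one_cell(self):
        cov = toy_cov(np.arange(16, dtype=float).reshape(1, 4, 4))
        mask = np.ones((4, 4), dtype=bool)
        surveys = self._surveys(
            [(pd.Timestamp("2005-01-01"), 2, 3, "sp", 12)])
        use = tfc.observed_use(surveys, cov, mask, "2005-01-01")
        assert use["use_depth"] == cov.depth[0, 2, 3]
        assert use["use_recession"] == cov.recession[0, 2, 3]

    def test_equal_counts_give_midpoint(self):
        cov = toy_cov(np.arange(16, dtype=float).reshape(1, 4, 4))
        mask = np.ones((4, 4), dtype=bool)
        surveys = self._surveys([
            (pd.Timestamp("2005-01-01"), 0, 0, "sp", 5),
            (pd.Timestamp("2005-01-01"), 3, 3, "sp", 5)])
        use = tfc.observed_use(surveys, cov, mask, "2005-01-01")
        assert use["use_depth"] == pytest.approx(
            (cov.depth[0, 0, 0] + cov.depth[0, 3, 3]) / 2)

    def test_weighted_mean_oracle_and_missing_flag(self):
        rng = np.random.default_rng(3)
        cov = toy_cov(rng.uniform(0, 30, size=(1, 5, 5)))
        mask = np.ones((5, 5), dtype=bool)
        rows = [(pd.Timestamp("2005-01-01"), int(r), int(c), "sp",
                 int(rng.integers(0, 6)))
                for r in range(5) for c in range(5)]
        surveys = self._surveys(rows)
        use = tfc.observed_use(surveys, cov, mask, "2005-01-01")
        occ = surveys[surveys["count"] >= 1]
        w = occ["count"].to_numpy(dtype=float)
        vals = cov.depth[0][occ["row"], occ["col"]]
        assert use["use_depth"] == pytest.approx((w * vals).sum() / w.sum())
        # no occupied cells -> NaN use, flagged by n_occupied == 0
        none = tfc.observed_use(self._surveys([]), cov, mask, "2005-01-01")
        assert none["n_occupied"] == 0 and np.isnan(none["use_depth"])


class TestUseModel:
    def _table(self, rng, n):
        return simulate_region_days(n, rng, noise_sd=0.0)

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        df = simulate_region_days(120, rng, noise_sd=0.0)
        df["use_depth"] = df["mean_depth"]  # use = depth mean exactly
        df["use_recession"] = df["mean_depth"]
        df["use_dsd"] = df["mean_depth"]
        model = tfc.fit_use_model(df)
        expected = np.zeros(10)
        expected[1] = 1.0
        np.testing.assert_allclose(model.params["depth"], expected, atol=1e-9)

    def test_recovery_within_2se_with_noise(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.5, 1.0, -0.4, 0.3, 0.6, 0.0, 0.0, 0.2, 0.0, -0.1])
        df = simulate_region_days(500, rng, use_coefs=truth, noise_sd=0.1)
        df["use_recession"] = df["use_depth"]
        df["use_dsd"] = df["use_depth"]
        model = tfc.fit_use_model(df)
        err = np.abs(model.params["depth"] - truth)
        assert (err <= 2 * model.bse["depth"] + 1e-12).all()

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(6)
        df = simulate_region_days(200, rng, noise_sd=0.1)
        df["use_recession"] = df["use_depth"]
        df["use_dsd"] = df["use_depth"]
        a = tfc.fit_use_model(df)
        b = tfc.fit_use_model(df.sample(frac=1.0, random_state=0))
        np.testing.assert_allclose(a.params["depth"], b.params["depth"],
                                   atol=1e-10)

    def test_rank_deficiency_names_terms(self):
        rng = np.random.default_rng(7)
        df = simulate_region_days(100, rng)
        df["sd_dsd"] = 0.0  # aliased with nothing -> zero column
        df["use_recession"] = df["use_depth"]
        df["use_dsd"] = df["use_depth"]
        with pytest.raises(ValueError, match="sd_dsd"):
            tfc.fit_use_model(df)


class TestAbundanceModel:
    def test_slope_recovery_negative_binomial(self):
        rng = np.random.default_rng(8)
        df = simulate_region_days(400, rng, abund_coefs=(1.0, 0.8),
                                  noise_sd=0.05)
        df["use_recession"] = rng.normal(size=len(df)) * 0.01
        df["use_dsd"] = rng.normal(size=len(df)) * 0.01
        model = tfc.fit_abundance_model(df)
        i = model.columns.index("use_depth")
        est, se = model.individuals.params[i], model.individuals.bse[i]
        assert abs(est - 0.8) <= 2 * se

    def test_flocks_exceeding_individuals_rejected(self):
        rng = np.random.default_rng(9)
        df = simulate_region_days(150, rng)
        df["use_recession"] = 0.0
        df["use_dsd"] = 0.0
        df.loc[0, "flocks"] = df.loc[0, "individuals"] + 1
        with pytest.raises(ValueError, match="flocks"):
            tfc.fit_abundance_model(df)

    def test_null_truth_intercept_near_log_mean(self):
        rng = np.random.default_rng(10)
        df = simulate_region_days(400, rng, use_coefs=np.zeros(10),
                                  abund_coefs=(1.2, 0.0))
        df["use_recession"] = rng.normal(size=len(df)) * 0.01
        df["use_dsd"] = rng.normal(size=len(df)) * 0.01
        model = tfc.fit_abundance_model(df)
        est, se = model.individuals.params[0], model.individuals.bse[0]
        assert abs(est - np.log(df["individuals"].mean())) <= 2 * se + 0.05


class TestPredictDailyAbundance:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(11)
        df = simulate_region_days(400, rng, noise_sd=0.1)
        df["use_recession"] = df["use_depth"] * 0.5
        df["use_dsd"] = df["use_depth"] * 0.25
        use_model = tfc.fit_use_model(df)
        abund = tfc.fit_abundance_model(df)
        return use_model, abund

    def test_landscape_total_is_region_sum_and_nonnegative(self, fitted):
        use_model, abund = fitted
        rng = np.random.default_rng(12)
        cov = toy_cov(rng.uniform(-5, 35, size=(6, 6, 6)))
        dates = cov.dates[2:5]
        per_region, landscape = tfc.predict_daily_abundance(
            use_model, abund, cov, GREAT_EGRET, dates)
        assert (per_region["individuals"].fillna(0) >= 0).all()
        for date in dates:
            total = landscape.loc[landscape["date"] == date,
                                  "individuals"].iloc[0]
            parts = per_region.loc[per_region["date"] == date, "individuals"]
            assert total == pytest.approx(parts.sum())

    def test_no_available_region_contributes_zero(self, fitted):
        use_model, abund = fitted
        depth = np.full((3, 4, 4), -20.0)   # everything dry/unavailable
        depth[:, :, 2:] = 15.0              # eastern region in range
        cov = toy_cov(depth)
        per_region, landscape = tfc.predict_daily_abundance(
            use_model, abund, cov, GREAT_EGRET, cov.dates[:1])
        west = per_region[per_region["region"] == "W"]
        assert (west["individuals"] == 0).all()
        assert (west["n_available"] == 0).all()

    def test_date_outside_coverage_errors(self, fitted):
        use_model, abund = fitted
        cov = toy_cov(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            tfc.predict_daily_abundance(use_model, abund, cov, GREAT_EGRET,
                                        ["2010-01-01"])


def test_full_chain_recovery_in_sample_rank_correlation():
    """Fit-on-self predictions rank-correlate with observed totals (n=400)."""
    rng = np.random.default_rng(13)
    df = simulate_region_days(400, rng, abund_coefs=(1.0, 0.8), noise_sd=0.1)
    df["use_recession"] = df["use_depth"] * 0.5
    df["use_dsd"] = df["use_depth"] * 0.25
    use_model = tfc.fit_use_model(df)
    pred = use_model.predict(df.drop(columns=["use_depth", "use_recession",
                                              "use_dsd"]))
    abund = tfc.fit_abundance_model(df)
    fitted = abund.predict(pred)
    from scipy.stats import spearmanr
    rho, _ = spearmanr(fitted["individuals"], df["individuals"])
    assert rho > 0
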