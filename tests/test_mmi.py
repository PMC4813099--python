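"""AICc multimodel inference: closed forms, ranking oracle, averaging, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waderhab import mmi
from waderhab.candidate_sets import load_candidate_set
from waderhab.synthetic import simulate_season_table


class TestAicc:
    def test_closed_form_example(self):
        assert mmi.aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-10.0) + 2 * 3
        # correction term is exactly 2K(K+1)/(n-K-1): 2.4e-5 at n=1e6
        assert abs(mmi.aicc(-10.0, 3, 10 ** 6) - aic) < 1e-4
        assert abs(mmi.aicc(-10.0, 3, 10 ** 8) - aic) < 1e-6

    def test_matches_formula_on_random_tuples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ll = rng.normal(-50, 20)
            k = int(rng.integers(2, 8))
            n = int(rng.integers(k + 2, 200))
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert mmi.aicc(ll, k, n) == pytest.approx(expected)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            mmi.aicc(-10.0, 5, 6)


def make_fits(aiccs, response="y"):
    fits = []
    for i, a in enumerate(aiccs):
        spec = mmi.CandidateSpec(response=response, terms=(f"x{i}",))
        fc = mmi.FittedCandidate(spec=spec, loglik=0.0, k=3, n=20,
                                 coefs={"const": (0.0, 0.1),
                                        f"x{i}": (1.0, 0.1)})
        fc.aicc_value = a
        fits.append(fc)
    return fits


class TestRankAndWeight:
    def test_delta_two_closed_form(self):
        fits = mmi.rank_and_weight(make_fits([100.0, 102.0]))
        assert fits[0].weight == pytest.approx(0.7311, abs=1e-4)
        assert fits[1].weight == pytest.approx(0.2689, abs=1e-4)
        assert fits[0].delta == 0.0

    def test_identical_aicc_equal_weights(self):
        fits = mmi.rank_and_weight(make_fits([50.0, 50.0, 50.0]))
        for f in fits:
            assert f.weight == pytest.approx(1 / 3)

    def test_support_bands(self):
        fits = mmi.rank_and_weight(make_fits([10.0, 11.0, 16.0]))
        assert fits[0].support == "plausible"
        assert fits[1].support == "plausible"      # delta 1 < 2
        assert fits[2].support == "unsupported"    # delta 6 > 4

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 500), min_size=2, max_size=12))
    def test_weights_sum_to_one(self, aiccs):
        fits = mmi.rank_and_weight(make_fits(aiccs))
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_mixed_responses_rejected(self):
        fits = make_fits([1.0, 2.0])
        fits[1].spec.response = "other"
        with pytest.raises(ValueError):
            mmi.rank_and_weight(fits)


class TestModelAverage:
    def test_term_in_single_model_passthrough(self):
        fits = mmi.rank_and_weight(make_fits([10.0, 12.0]))
        avg = mmi.model_average(fits).set_index("term")
        assert avg.loc["x0", "estimate"] == 1.0

    def test_two_model_closed_form_unconditional_se(self):
        specs = [mmi.CandidateSpec("y", ("x",)), mmi.CandidateSpec("y", ("x",))]
        fits = []
        for spec, beta, a in zip(specs, (1.0, 3.0), (5.0, 5.0)):
            fc = mmi.FittedCandidate(spec=spec, loglik=0.0, k=3, n=20,
                                     coefs={"const": (0.0, 0.0),
                                            "x": (beta, 0.0)})
            fc.aicc_value = a
            fits.append(fc)
        fits = mmi.rank_and_weight(fits)
        avg = mmi.model_average(fits).set_index("term")
        assert avg.loc["x", "estimate"] == pytest.approx(2.0)
        assert avg.loc["x", "unconditional_se"] == pytest.approx(1.0)

    def test_average_bounded_by_containing_models(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            fits = make_fits(rng.uniform(0, 20, size=5).tolist())
            for f in fits:
                f.coefs["shared"] = (float(rng.normal()), 0.1)
            fits = mmi.rank_and_weight(fits)
            avg = mmi.model_average(fits).set_index("term")
            betas = [f.coefs["shared"][0] for f in fits]
            assert min(betas) - 1e-12 <= avg.loc["shared", "estimate"] \
                <= max(betas) + 1e-12


class TestVariableImportance:
    def test_everywhere_term_is_one(self):
        fits = make_fits([3.0, 3.0])
        for f in fits:
            f.spec.terms = ("z",)
        fits = mmi.rank_and_weight(fits)
        imp = mmi.variable_importance(fits)
        assert imp["z"] == pytest.approx(1.0)

    def test_partial_membership_sums_weights(self):
        fits = make_fits([0.0, 1.0, 2.0])
        fits = mmi.rank_and_weight(fits)
        imp = mmi.variable_importance(fits)
        w = {f.spec.terms[0]: f.weight for f in fits}
        # complementary partition: importances equal the weights themselves
        assert imp["x0"] == pytest.approx(w["x0"])
        assert sum(imp.values()) == pytest.approx(1.0)


class TestFitR2:
    def test_perfect_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        assert mmi.fit_r2(y, y) == pytest.approx(1.0)
        assert mmi.fit_r2(y, 3 * y + 7) == pytest.approx(1.0)

    def test_orthogonal_noise_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10 ** 4)
        assert mmi.fit_r2(y, rng.normal(size=10 ** 4)) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mmi.fit_r2(np.ones(10), np.arange(10.0))


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(10.0)
        rs, p, n = mmi.effort_success_correlation(x, x ** 3)
        assert rs == pytest.approx(1.0) and n == 10
        rs, _, _ = mmi.effort_success_correlation(x, -x)
        assert rs == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rs, _, _ = mmi.effort_success_correlation(x, y)
            rx = pd.Series(x).rank().to_numpy()
            ry = pd.Series(y).rank().to_numpy()
            d2 = ((rx - ry) ** 2).sum()
            assert rs == pytest.approx(1 - 6 * d2 / (12 * (12 ** 2 - 1)))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mmi.effort_success_correlation([1, 2, 3], [3, 2, 1])


class TestFitCandidate:
    def test_slope_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        table = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 0.1, 20)})
        fc = mmi.fit_candidate(table, mmi.CandidateSpec("y", ("x",)))
        beta, se = fc.coefs["x"]
        assert abs(beta - 2.0) <= 2 * se
        assert fc.k == 3  # intercept + slope + residual variance

    def test_fourth_root_transform_applied(self):
        table = pd.DataFrame({"y": [16.0] * 8, "x": np.arange(8.0)})
        y = mmi.transform_response(table["y"].to_numpy(), "fourth-root")
        assert (y == 2.0).all()
        back = mmi.back_transform(y, "fourth-root")
        assert (back == 16.0).all()

    def test_zero_variance_random_intercept_collapses_to_ols(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=24)
        table = pd.DataFrame({
            "x": x, "y": 1.5 * x + rng.normal(0, 0.2, 24),
            "decade": ["a"] * 12 + ["b"] * 12,  # no true group effect
        })
        spec = mmi.CandidateSpec("y", ("x",), random_intercept="decade")
        fc = mmi.fit_candidate(table, spec)
        assert fc.random_removed
        assert fc.k == 3  # refit without the variance component

    def test_random_intercept_retained_when_variance_real(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        group_effect = np.repeat([5.0, -5.0], 20)
        table = pd.DataFrame({
            "x": x, "y": x + group_effect + rng.normal(0, 0.3, 40),
            "decade": ["a"] * 20 + ["b"] * 20,
        })
        spec = mmi.CandidateSpec("y", ("x",), random_intercept="decade")
        fc = mmi.fit_candidate(table, spec)
        assert not fc.random_removed
        assert fc.k == 4

    def test_singular_design_rejected(self):
        table = pd.DataFrame({"y": np.arange(12.0), "x": 1.0})
        with pytest.raises(ValueError):
            mmi.fit_candidate(table, mmi.CandidateSpec("y", ("x",)))


def ols_loglik(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = (resid ** 2).sum() / n
    return -n / 2 * (np.log(2 * np.pi * s2) + 1)


def test_best_model_matches_exhaustive_enumeration_oracle():
    """AICc ranking equals brute-force enumeration on a 3-term universe."""
    rng = np.random.default_rng(8)
    universe = ("a", "b", "c")
    subsets = [tuple(s) for r in range(4)
               for s in itertools.combinations(universe, r)]
    for _ in range(50):
        n = 25
        table = pd.DataFrame({t: rng.normal(size=n) for t in universe})
        table["y"] = (rng.normal(size=n)
                      + rng.choice([0, 1]) * table["a"]
                      + rng.choice([0, 1.5]) * table["b"])
        fits = [mmi.fit_candidate(table, mmi.CandidateSpec("y", s))
                for s in subsets]
        ranked = mmi.rank_and_weight(fits)
        oracle = []
        for s in subsets:
            X = np.column_stack([np.ones(n)] + [table[t] for t in s])
            ll = ols_loglik(table["y"].to_numpy(), X)
            k = X.shape[1] + 1
            oracle.append((s, -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)))
        oracle.sort(key=lambda t: t[1])
        assert [f.spec.terms for f in ranked] == [t[0] for t in oracle]


def test_generating_terms_reach_top_importances():
    """effort = f(Mar Δ, Mean TFC) + noise: those terms rank top-two in >=80%."""
    rng = np.random.default_rng(9)
    specs = load_candidate_set("effort", "effort")
    specs = [mmi.CandidateSpec(s.response, s.terms) for s in specs]  # fixed FX
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        table = simulate_season_table(
            20, rng, effect_coefs={"mar_delta": 1.0, "mean_tfc": 1.0},
            noise_sd=0.8)
        result = mmi.run_mmi(table, specs)
        top2 = sorted(result.importance, key=result.importance.get,
                      reverse=True)[:2]
        hits += set(top2) == {"mar_delta", "mean_tfc"}
    assert hits >= 80


def test_run_mmi_reports_r2_and_ranking():
    rng = np.random.default_rng(10)
    table = simulate_season_table(21, rng, noise_sd=0.5)
    specs = load_candidate_set("effort", "effort")
    result = mmi.run_mmi(table, specs)
    assert 0.0 <= result.r2 <= 1.0
    assert result.ranking["delta_AICc"].iloc[0] == 0.0
    assert (result.ranking["weight"].sum()) == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in result.importance.values())
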