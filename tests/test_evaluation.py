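import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from immucast import ModelSpec, SurveyDesign, generate_region_graph, simulate_surveys, simulate_truth
from immucast.evaluation import (
    compare_models,
    consistency_check,
    dic,
    holdout_validate,
    select_model,
    waic,
)
from immucast.survey import derive_full_immunization, estimate_coverage


class TestWaic:
    def test_zero_variance_reduces_to_deviance(self):
        L = -3.7
        w, p_w, lppd = waic(np.full((50, 1), L))
        assert w == pytest.approx(-2 * L)
        assert p_w == pytest.approx(0.0)
        assert lppd == pytest.approx(L)

    def test_duplicating_an_observation_doubles_both_terms(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-2, 0.3, size=(200, 1))
        w1, p1, l1 = waic(ll)
        w2, p2, l2 = waic(np.concatenate([ll, ll], axis=1))
        assert l2 == pytest.approx(2 * l1)
        assert p2 == pytest.approx(2 * p1)
        assert w2 == pytest.approx(2 * w1)

    def test_non_finite_loglik_names_observation(self):
        ll = np.zeros((10, 3))
        ll[4, 2] = -np.inf
        with pytest.raises(ValueError, match=r"observations \[2\]"):
            waic(ll)

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="draws"):
            waic(np.zeros((1, 5)))


class TestDic:
    def test_constant_deviance(self):
        d, p_d = dic(np.full(100, 42.0), 42.0)
        assert d == 42.0 and p_d == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        dev = rng.normal(100, 5, 500)
        assert dic(dev, 95.0) == dic(rng.permutation(dev), 95.0)

    def test_normal_mean_toy_effective_parameters(self):
        # y ~ N(theta, 1), flat prior: posterior N(ybar, 1/n); p_D must be ~1
        rng = np.random.default_rng(2)
        n, ybar = 20, 0.3
        y = rng.normal(ybar, 1.0, n)
        theta_draws = rng.normal(y.mean(), 1 / np.sqrt(n), 200000)
        dev = np.array([np.sum((y - th) ** 2) for th in theta_draws])
        _, p_d = dic(dev, float(np.sum((y - y.mean()) ** 2)))
        assert p_d == pytest.approx(1.0, abs=0.05)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dic(np.array([]), 1.0)


class TestConsistency:
    def grid(self, n=300, value=0.7):
        years = range(2000, 2000 + n // 10)
        idx = pd.MultiIndex.from_product(
            [[f"R{i}" for i in range(10)], years], names=["region", "year"]
        )
        return pd.DataFrame({"full": value}, index=idx).reset_index()

    def components_from(self, full, offset=0.05):
        out = {}
        for k in ("bcg", "dpt3"):
            c = full.rename(columns={"full": k}).copy()
            c[k] = c[k] + offset
            out[k] = c
        return out

    def test_consistent_surfaces_have_zero_violations(self):
        full = self.grid()
        frac, flags = consistency_check(full, self.components_from(full))
        assert frac == 0.0 and len(flags) == 0

    def test_injected_violations_counted_exactly(self):
        full = self.grid()
        comps = self.components_from(full)
        full.loc[[3, 77, 200], "full"] += 0.10  # exceeds components by 5pp
        frac, flags = consistency_check(full, comps)
        assert len(flags) == 3
        assert frac == pytest.approx(3 / 300)
        assert set(flags["region"]) <= set(full["region"])

    def test_tolerance_absorbs_small_excess(self):
        full = self.grid()
        comps = self.components_from(full)
        full["full"] += 0.058  # 0.8pp above the components
        frac, _ = consistency_check(full, comps, tolerance=0.005)
        assert frac == 1.0
        frac, _ = consistency_check(full, comps, tolerance=0.01)
        assert frac == 0.0

    def test_misaligned_indices_rejected(self):
        full = self.grid()
        comps = self.components_from(full)
        comps["bcg"] = comps["bcg"].iloc[:200]
        with pytest.raises(ValueError, match="missing cells"):
            consistency_check(full, comps)


class TestHoldout:
    @pytest.fixture(scope="class")
    def broken_trend_cells(self):
        g = generate_region_graph(1, 9, seed=0)
        truth = simulate_truth(g, range(2000, 2020), seed=1).with_trend_break(2014)
        design = SurveyDesign(
            survey_years={"C00": (2002, 2008, 2014, 2019)}, clusters_per_stratum=5
        )
        ch, _ = simulate_surveys(truth, design, seed=2)
        return estimate_coverage(derive_full_immunization(ch), "dpt3"), g

    def test_flattened_truth_is_overpredicted_out_of_sample(self, broken_trend_cells):
        cells, g = broken_trend_cells
        rep = holdout_validate(cells, g, ModelSpec("bym2_1"), split_year=2014, seed=3)
        assert rep.me["out"] > 0
        assert rep.ad["out"] >= abs(rep.me["out"])
        assert rep.ad["in"] >= abs(rep.me["in"])
        assert rep.n_cells["in"] + rep.n_cells["out"] == rep.n_cells["full"]

    def test_missing_holdout_years_rejected(self, broken_trend_cells):
        cells, g = broken_trend_cells
        with pytest.raises(ValueError, match="held-out"):
            holdout_validate(cells, g, ModelSpec("bym2_1"), split_year=2030)

    def test_constant_shift_scores(self):
        from immucast.evaluation import _ad_me

        obs = np.array([0.5, 0.6, 0.7])
        ad, me = _ad_me(obs, obs)
        assert ad == 0.0 and me == 0.0
        ad, me = _ad_me(obs, obs + 0.02)
        assert ad == pytest.approx(2.0)
        assert me == pytest.approx(2.0)


class TestSelection:
    def test_rank_sum_prefers_dominating_variant(self):
        comp = pd.DataFrame(
            {
                "variant": ["besag_1", "bym2_2"],
                "dic": [110.0, 100.0],
                "waic": [112.0, 99.0],
                "ad_out": [4.0, 2.5],
                "me_out": [3.0, -0.5],
            }
        )
        assert select_model(comp) == "bym2_2"

    def test_ties_break_toward_simpler_variant(self):
        comp = pd.DataFrame(
            {
                "variant": ["bym2_2", "besag_1"],
                "dic": [100.0, 100.0],
                "waic": [100.0, 100.0],
                "ad_out": [2.0, 2.0],
                "me_out": [1.0, -1.0],
            }
        )
        assert select_model(comp) == "besag_1"

    def test_model_ranking_prefers_matching_structure(self):
        # data generated with spatially structured effects and a country
        # level: the rank-sum score should prefer bym2 over plain Besag in
        # a majority of replicates
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            g = generate_region_graph(2, 4, seed=rep)
            truth = simulate_truth(g, range(2000, 2020), seed=50 + rep)
            design = SurveyDesign(
                survey_years={c: (2003, 2010, 2016, 2019) for c in g.country_ids},
                clusters_per_stratum=4,
            )
            ch, _ = simulate_surveys(truth, design, seed=80 + rep)
            cells = estimate_coverage(derive_full_immunization(ch), "dpt3")
            comp = compare_models(cells, g, ["besag_1", "bym2_2"], split_year=2016,
                                  seed=rep, draws=400)
            if select_model(comp) == "bym2_2":
                wins += 1
        assert wins > n_rep / 2


def test_waic_beta_binomial_quadrature_oracle():
    """Draw-based WAIC agrees with numerical posterior integration.

    Conjugate toy: y ~ Bin(n, p), p ~ Beta(a0, b0), posterior
    Beta(a0 + y, b0 + n - y).  The posterior is represented by
    Gauss-Legendre nodes with posterior-density draw weights (a
    deterministic draw set) and the oracle integrates the same
    functionals independently with adaptive quadrature.
    """
    a0, b0, n, y = 2.0, 3.0, 25, 17
    post = beta_dist(a0 + y, b0 + n - y)
    nodes, wq = np.polynomial.legendre.leggauss(400)
    p_nodes = 0.5 * (nodes + 1.0)  # map [-1, 1] -> [0, 1]
    weights = wq * post.pdf(p_nodes)
    ll = binom.logpmf(y, n, p_nodes)[:, None]
    w, p_w, lppd = waic(ll, draw_weights=weights)

    def integrate(f):
        val, _ = quad(lambda p: f(p) * post.pdf(p), 1e-12, 1 - 1e-12, limit=400)
        return val

    lik_mean = integrate(lambda p: binom.pmf(y, n, p))
    ll_mean = integrate(lambda p: binom.logpmf(y, n, p))
    ll_var = integrate(lambda p: (binom.logpmf(y, n, p) - ll_mean) ** 2)
    oracle_lppd = np.log(lik_mean)
    oracle_waic = -2 * (oracle_lppd - ll_var)
    assert lppd == pytest.approx(oracle_lppd, abs=1e-6)
    assert p_w == pytest.approx(ll_var, abs=1e-6)
    assert w == pytest.approx(oracle_waic, abs=1e-6)
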