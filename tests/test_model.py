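import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from immucast import (
    CoverageTrendModel,
    ModelSpec,
    SurveyDesign,
    generate_region_graph,
    simulate_surveys,
    simulate_truth,
)
from immucast.graphs import RegionGraph
from immucast.survey import derive_full_immunization, estimate_coverage


def cells_frame(rows):
    base = dict(country="C00", region="C00_R00", year=2010, indicator="dpt3",
                n=100, n_eff=100.0, sparse=False)
    df = pd.DataFrame([{**base, **r} for r in rows])
    df["p_adj"] = df["p_hat"].clip(1 / (2 * df["n_eff"]), 1 - 1 / (2 * df["n_eff"]))
    df["logit_p"] = logit(df["p_adj"])
    df["logit_se"] = 1 / np.sqrt(df["n_eff"] * df["p_adj"] * (1 - df["p_adj"]))
    return df


class TestSpec:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec(variant="bym3_1")

    def test_bad_likelihood_and_priors_rejected(self):
        with pytest.raises(ValueError, match="likelihood"):
            ModelSpec(likelihood="poisson")
        with pytest.raises(ValueError, match="PC prior"):
            ModelSpec(U_sigma=-1)

    def test_variant_structure_flags(self):
        assert ModelSpec("bym2_2").family == "bym2"
        assert ModelSpec("bym2_2").has_country_level
        assert not ModelSpec("besag_1").has_country_level


class TestConstruction:
    def test_besag_needs_edges(self):
        g = RegionGraph(nodes=(("R0", "C0"),))
        cells = cells_frame([{"region": "R0", "country": "C0", "p_hat": 0.7}])
        with pytest.raises(ValueError, match="edge"):
            CoverageTrendModel(cells, g, ModelSpec("besag_1"))

    def test_unknown_region_rejected(self):
        g = generate_region_graph(1, 2)
        cells = cells_frame([{"region": "elsewhere", "p_hat": 0.7}])
        with pytest.raises(ValueError, match="not in graph"):
            CoverageTrendModel(cells, g)

    def test_empty_cells_rejected(self):
        g = generate_region_graph(1, 2)
        cells = cells_frame([{"region": "C00_R00", "p_hat": np.nan, "n": 0}])
        with pytest.raises(ValueError, match="no non-empty"):
            CoverageTrendModel(cells, g)


class TestFit:
    def test_single_region_posterior_tracks_weighted_proportion(self):
        # one region, flat trend: the posterior mean must sit at the pooled
        # design-weighted proportion (priors are weak at this sample size)
        g = RegionGraph(nodes=(("R0", "C0"),))
        cells = cells_frame(
            [{"region": "R0", "country": "C0", "year": y, "p_hat": 0.65, "n_eff": 400.0, "n": 400}
             for y in (2005, 2010, 2015)]
        )
        res = CoverageTrendModel(cells, g, ModelSpec("bym2_1")).fit(seed=0, draws=2000)
        pm = float(res.surface.mean().sel(region="R0", year=2010))
        assert pm == pytest.approx(0.65, abs=0.01)
        assert "structured component dropped" in " ".join(res.diagnostics["warnings"])

    def test_symmetric_regions_get_matching_posteriors(self):
        # a 2-node path with identical data is exchangeable under the swap
        g = RegionGraph(nodes=(("R0", "C0"), ("R1", "C0")),
                        edges=frozenset({frozenset(("R0", "R1"))}))
        rows = []
        for r in ("R0", "R1"):
            for y, p in ((2004, 0.55), (2012, 0.68), (2018, 0.74)):
                rows.append({"region": r, "country": "C0", "year": y,
                             "p_hat": p, "n_eff": 300.0, "n": 300})
        res = CoverageTrendModel(cells_frame(rows), g).fit(seed=1, draws=2000)
        m = res.surface.mean()
        assert float(m.sel(region="R0", year=2010)) == pytest.approx(
            float(m.sel(region="R1", year=2010)), abs=0.01
        )

    def test_surface_contract(self, fitted):
        surf = fitted.surface
        vals = surf.draws.values
        assert vals.min() >= 0 and vals.max() <= 1
        assert surf.n_draws >= 800
        # all calendar years are modelled, including non-survey years
        assert list(surf.years) == list(range(2002, 2019))
        assert fitted.diagnostics["rhat_max"] <= fitted.spec.rhat_threshold

    def test_interpolated_years_available(self, fitted):
        assert 2007 in set(int(y) for y in fitted.surface.years)

    def test_deterministic_given_seed(self, small_cells, small_graph):
        m = CoverageTrendModel(small_cells, small_graph, ModelSpec("bym2_2"))
        a = m.fit(seed=7, draws=200).surface.draws.values
        b = m.fit(seed=7, draws=200).surface.draws.values
        assert np.array_equal(a, b)

    def test_gaussian_likelihood_agrees_with_binomial(self, small_cells, small_graph):
        res_b = CoverageTrendModel(small_cells, small_graph, ModelSpec("bym2_2")).fit(seed=2, draws=500)
        res_g = CoverageTrendModel(
            small_cells, small_graph, ModelSpec("bym2_2", likelihood="gaussian")
        ).fit(seed=2, draws=500)
        diff = np.abs(res_b.surface.mean().values - res_g.surface.mean().values)
        assert diff.max() < 0.05

    def test_single_survey_country_gets_wider_intervals(self):
        # equal-size countries; C00 surveyed three times, C01 once: C01's
        # trend must borrow from the shared level and show more uncertainty
        g = generate_region_graph(2, 4, seed=0)
        truth = simulate_truth(g, range(2000, 2020), seed=3)
        design = SurveyDesign(
            survey_years={"C00": (2002, 2010, 2018), "C01": (2010,)},
            clusters_per_stratum=5,
        )
        ch, _ = simulate_surveys(truth, design, seed=4)
        cells = estimate_coverage(derive_full_immunization(ch), "dpt3")
        res = CoverageTrendModel(cells, g, ModelSpec("bym2_2")).fit(seed=5, draws=600)
        q = res.surface.quantile([0.025, 0.975])
        width = (q.sel(quantile=0.975) - q.sel(quantile=0.025)).sel(year=2018)
        rc = g.region_country
        w0 = width.sel(region=[r for r in g.region_ids if rc[r] == "C00"]).mean()
        w1 = width.sel(region=[r for r in g.region_ids if rc[r] == "C01"]).mean()
        assert float(w1) > float(w0)

    def test_all_variants_fit_small_data(self, small_cells, small_graph):
        for variant in ("besag_1", "besag_2", "bym_1", "bym_2", "bym2_1", "bym2_2"):
            res = CoverageTrendModel(small_cells, small_graph, ModelSpec(variant)).fit(
                seed=3, draws=200
            )
            assert res.diagnostics["converged"]

    def test_stratified_fit_recovers_subgroup_ordering(self, small_children, small_graph):
        children, _ = small_children
        cells = estimate_coverage(children, "dpt3", subgroup_col="wealth_quintile")
        res = CoverageTrendModel(
            cells, small_graph, ModelSpec("bym2_2", stratified=True),
            subgroup_col="wealth_quintile",
        ).fit(seed=6, draws=400)
        m = res.surface.mean().sel(year=2010).mean("region")
        # generator imposes a positive wealth gradient
        assert float(m.sel(subgroup=5)) > float(m.sel(subgroup=1))

    def test_mcmc_backend_agrees_with_laplace(self, small_graph):
        # independent sampling route on a reduced model must reproduce the
        # nested-Laplace posterior means
        g = generate_region_graph(1, 4)
        truth = simulate_truth(g, range(2000, 2020), seed=8)
        design = SurveyDesign(survey_years={"C00": (2002, 2010, 2018)},
                              clusters_per_stratum=5)
        ch, _ = simulate_surveys(truth, design, seed=9)
        cells = estimate_coverage(derive_full_immunization(ch), "dpt3")
        m = CoverageTrendModel(cells, g, ModelSpec("bym2_1"))
        res_l = m.fit(seed=10, draws=800)
        res_m = m.fit(seed=10, draws=800, method="mcmc", mcmc_steps=1200, mcmc_burn=500)
        diff = np.abs(res_l.surface.mean().values - res_m.surface.mean().values)
        assert diff.max() < 0.05

    def test_hyper_summary_on_natural_scale(self, fitted):
        hs = fitted.hyper_summary()
        assert "phi" in hs.index
        assert ((hs.loc["phi", ["mean", "q025", "q975"]] >= 0)
                & (hs.loc["phi", ["mean", "q025", "q975"]] <= 1)).all()
        assert (hs.drop(index="phi")[["mean", "q025", "q975"]] > 0).all().all()
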