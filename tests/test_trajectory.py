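import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from immucast.trajectory import (
    aarc,
    best_region_scenario,
    exceedance_probability,
    national_aggregate,
    project,
    required_aarc,
    surface_aarc,
    target_assessment,
)

from conftest import make_surface


def logit_linear_surface(intercepts, slopes, years, **kw):
    """Draws that are exactly linear on the logit scale."""
    icpt = np.asarray(intercepts, dtype=float)
    slp = np.asarray(slopes, dtype=float)
    t = np.asarray(years, dtype=float) - years[0]
    eta = icpt[:, :, None] + slp[:, :, None] * t
    return make_surface(expit(eta), years=np.asarray(years), **kw)


class TestAarc:
    def test_no_change_is_zero(self):
        assert aarc(0.6, 0.6, 10) == 0

    def test_doubling_over_thirty_years(self):
        assert aarc(0.4, 0.8, 30) == pytest.approx(100 * (2 ** (1 / 30) - 1), abs=1e-10)
        assert aarc(0.4, 0.8, 30) == pytest.approx(2.337, abs=5e-4)

    def test_compounding_inverts_exactly(self):
        rng = np.random.default_rng(0)
        P0 = rng.uniform(0.05, 0.95, 200)
        Pn = rng.uniform(0.05, 0.95, 200)
        rate = aarc(P0, Pn, 12)
        assert np.allclose(P0 * (1 + rate / 100) ** 12, Pn, atol=1e-10)

    def test_zero_start_rejected(self):
        with pytest.raises(ValueError, match="P0"):
            aarc(0.0, 0.5, 10)


class TestRequiredAarc:
    def test_already_met_is_zero(self):
        assert required_aarc(0.8, 0.8, 10) == 0
        assert required_aarc(0.9, 0.8, 10) == 0

    def test_hand_computed_case(self):
        assert required_aarc(0.5, 0.8, 10) == pytest.approx(100 * (1.6**0.1 - 1), abs=1e-10)
        assert required_aarc(0.5, 0.8, 10) == pytest.approx(4.812, abs=5e-4)

    def test_monotone_decreasing_in_years(self):
        vals = [required_aarc(0.5, 0.9, n) for n in (5, 10, 20, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestProject:
    def test_zero_slope_draw_stays_flat(self):
        surf = logit_linear_surface(np.full((50, 2), 0.3), np.zeros((50, 2)),
                                    np.arange(2000, 2006))
        proj = project(surf, 2030)
        assert np.allclose(proj.sel_year(2030).values, proj.sel_year(2005).values)

    def test_closed_form_extension(self):
        surf = logit_linear_surface(np.zeros((10, 1)), np.full((10, 1), 0.1),
                                    np.arange(2000, 2006))
        proj = project(surf, 2010)
        assert np.allclose(proj.sel_year(2010).values, expit(1.0), atol=1e-9)
        assert float(proj.sel_year(2010).values[0, 0]) == pytest.approx(0.7311, abs=1e-4)

    def test_projection_stays_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        surf = logit_linear_surface(rng.normal(0, 2, (100, 3)), rng.normal(0, 0.3, (100, 3)),
                                    np.arange(2000, 2010))
        proj = project(surf, 2040)
        vals = proj.draws.values
        assert vals.min() > 0 and vals.max() < 1

    def test_uncertainty_widens_with_horizon(self):
        rng = np.random.default_rng(2)
        surf = logit_linear_surface(rng.normal(0.5, 0.2, (500, 1)),
                                    rng.normal(0.02, 0.02, (500, 1)),
                                    np.arange(2000, 2010))
        proj = project(surf, 2030)
        q = proj.quantile([0.025, 0.975])
        width = (q.sel(quantile=0.975) - q.sel(quantile=0.025)).isel(region=0)
        assert float(width.sel(year=2030)) > float(width.sel(year=2015))

    def test_horizon_before_first_year_rejected(self):
        surf = logit_linear_surface(np.zeros((5, 1)), np.zeros((5, 1)), np.arange(2000, 2005))
        with pytest.raises(ValueError, match="precedes"):
            project(surf, 1995)

    def test_aarc_projection_consistency_per_draw(self):
        rng = np.random.default_rng(3)
        surf = logit_linear_surface(rng.normal(0, 1, (50, 2)), rng.normal(0, 0.1, (50, 2)),
                                    np.arange(2000, 2010))
        proj = project(surf, 2020)
        rate = surface_aarc(proj, 2000, 2020)
        p0 = proj.sel_year(2000).values
        pn = proj.sel_year(2020).values
        assert np.allclose(p0 * (1 + rate.values / 100) ** 20, pn, atol=1e-10)


class TestExceedance:
    def test_degenerate_draws(self):
        surf = make_surface(np.full((100, 1, 1), 0.85))
        out = exceedance_probability(surf, 0.8, 2000)
        assert out["prob"].iloc[0] == 1.0

    def test_uniform_draws_analytic_tail(self):
        rng = np.random.default_rng(4)
        surf = make_surface(rng.uniform(0, 1, (20000, 1, 1)))
        out = exceedance_probability(surf, 0.8, 2000)
        assert out["prob"].iloc[0] == pytest.approx(0.2, abs=3 * np.sqrt(0.16 / 20000))

    def test_equals_brute_force_count(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (999, 2, 1))
        surf = make_surface(vals)
        out = exceedance_probability(surf, 0.63, 2000)
        brute = (vals[:, :, 0] >= 0.63).mean(axis=0)
        assert np.allclose(out["prob"].to_numpy(), brute)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        surf = make_surface(rng.uniform(0, 1, (500, 1, 1)))
        probs = [exceedance_probability(surf, c, 2000)["prob"].iloc[0]
                 for c in (0.2, 0.5, 0.8, 0.95)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_year_out_of_range_rejected(self):
        surf = make_surface(np.full((10, 1, 3), 0.5))
        with pytest.raises(ValueError, match="year"):
            exceedance_probability(surf, 0.8, 2050)


class TestNationalAggregate:
    def two_region_surface(self, vals):
        rc = pd.Series({"R0": "C00", "R1": "C00"})
        return make_surface(vals, regions=["R0", "R1"], region_country=rc)

    def test_equal_coverage_is_preserved(self):
        surf = self.two_region_surface(np.full((20, 2, 1), 0.7))
        nat = national_aggregate(surf)
        assert np.allclose(nat.draws.values, 0.7)

    def test_hand_arithmetic(self):
        vals = np.zeros((1, 2, 1))
        vals[0, 0, 0], vals[0, 1, 0] = 0.2, 0.8
        nat = national_aggregate(self.two_region_surface(vals),
                                 pd.Series({"R0": 0.5, "R1": 0.5}))
        assert nat.draws.values[0, 0, 0] == pytest.approx(0.5)

    def test_national_within_regional_range(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.2, 0.9, (50, 2, 4))
        surf = self.two_region_surface(vals)
        nat = national_aggregate(surf, pd.Series({"R0": 0.3, "R1": 0.7}))
        assert np.all(nat.draws.values[:, 0, :] <= vals.max(axis=1))
        assert np.all(nat.draws.values[:, 0, :] >= vals.min(axis=1))

    def test_bad_weight_sum_rejected(self):
        surf = self.two_region_surface(np.full((5, 2, 1), 0.5))
        with pytest.raises(ValueError, match="sum to 1"):
            national_aggregate(surf, pd.Series({"R0": 0.6, "R1": 0.6}))


class TestBestRegionScenario:
    def test_identical_regions_reproduce_baseline(self):
        icpt = np.full((200, 2), 0.2)
        slp = np.full((200, 2), 0.05)
        rc = pd.Series({"R0": "C00", "R1": "C00"})
        surf = logit_linear_surface(icpt, slp, np.arange(2000, 2010),
                                    regions=["R0", "R1"], region_country=rc)
        scen, base, chosen = best_region_scenario(surf, (2000, 2009), 2020)
        assert not chosen["C00"]["single_region"]
        s = scen.sel_year(2020).mean("draw").values
        b = base.sel_year(2020).mean("draw").values
        assert np.allclose(s, b, atol=0.02)

    def test_best_region_rate_drives_scenario(self):
        # R1 improves at a strictly higher rate; scenario must compound it
        icpt = np.tile([0.0, 0.0], (50, 1))
        slp = np.tile([0.0, 0.08], (50, 1))
        rc = pd.Series({"R0": "C00", "R1": "C00"})
        surf = logit_linear_surface(icpt, slp, np.arange(2000, 2010),
                                    regions=["R0", "R1"], region_country=rc)
        scen, base, chosen = best_region_scenario(surf, (2000, 2009), 2020)
        assert chosen["C00"]["best_region"] == "R1"
        p0 = float(national_aggregate(surf).sel_year(2009).mean("draw").values[0])
        rate = aarc(expit(0.0), expit(0.08 * 9), 9)
        expected = p0 * (1 + rate / 100) ** 11
        got = float(scen.sel_year(2020).mean("draw").values[0])
        assert got == pytest.approx(min(expected, 1.0), rel=0.02)
        assert got >= float(base.sel_year(2020).mean("draw").values[0])

    def test_single_region_country_flagged(self):
        surf = logit_linear_surface(np.full((20, 1), 0.1), np.full((20, 1), 0.02),
                                    np.arange(2000, 2008))
        _, _, chosen = best_region_scenario(surf, (2000, 2007), 2015)
        assert chosen["C00"]["single_region"]


def test_target_assessment_counts_regions(fitted, small_cells):
    tab = target_assessment(fitted.surface, 2030)
    assert set(tab["target"]) == {"uhc", "ia2030"}
    assert (tab["regions_reaching"] <= tab["regions_total"]).all()
    assert tab["national_exceedance"].between(0, 1).all()
    assert (tab["required_aarc"] >= 0).all()
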