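"""Projection to a horizon year, AARC, exceedance probabilities and aggregates.

All operations act per posterior draw, so every derived quantity (AARC,
exceedance probability, required additional AARC, national aggregate)
carries full posterior uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit, logit

from .surface import PosteriorSurface

__all__ = [
    "project",
    "aarc",
    "exceedance_probability",
    "required_aarc",
    "national_aggregate",
    "best_region_scenario",
    "target_assessment",
]

_EPS = 1e-9

#: global coverage targets by 2030: universal health coverage and IA2030
TARGETS = {"uhc": 0.8, "ia2030": 0.9}


def _trend_coefficients(surface: PosteriorSurface):
    """Per-draw OLS intercept/slope of logit coverage over the surface years.

    Model-generated surfaces are exactly linear on the logit scale, so
    this recovers each draw's own trend; for arbitrary surfaces it is
    the least-squares trend of the draw.
    """
    years = surface.years.astype(float)
    t = years - years.mean()
    X = np.column_stack([np.ones_like(t), t])
    pinv = np.linalg.pinv(X)  # (2, n_years)
    z = logit(np.clip(surface.draws.values, _EPS, 1 - _EPS))
    zm = np.moveaxis(z, surface.draws.dims.index("year"), -1)
    coef = zm @ pinv.T  # (..., 2)
    return coef[..., 0], coef[..., 1], years.mean()


def project(surface: PosteriorSurface, horizon_year: int) -> PosteriorSurface:
    """Extend each draw's logit-linear trend to ``horizon_year``.

    Coverage passes through the inverse logit, so projections stay
    strictly inside (0, 1), and interval width grows with distance from
    the data years.
    """
    last = int(surface.years.max())
    first = int(surface.years.min())
    if horizon_year < first:
        raise ValueError(f"horizon {horizon_year} precedes first modelled year {first}")
    if horizon_year <= last:
        return surface
    icpt, slope, t_ref = _trend_coefficients(surface)
    new_years = np.arange(last + 1, horizon_year + 1)
    eta_new = icpt[..., None] + slope[..., None] * (new_years.astype(float) - t_ref)
    dims = surface.draws.dims
    order = [d for d in dims if d != "year"] + ["year"]
    ext = xr.DataArray(
        expit(eta_new),
        dims=order,
        coords={**{d: surface.draws.coords[d] for d in order[:-1]}, "year": new_years},
    ).transpose(*dims)
    combined = xr.concat([surface.draws, ext], dim="year")
    return surface.with_draws(combined)


def aarc(P0, Pn, N):
    """Average annual rate of change in % / year: ``100 ((Pn/P0)^(1/N) - 1)``.

    ``N`` is the number of years in the interval.  Applied per posterior
    draw this yields AARC credible intervals.
    """
    P0 = np.asarray(P0, dtype=float)
    Pn = np.asarray(Pn, dtype=float)
    if np.any(P0 <= 0):
        raise ValueError("P0 must be positive (continuity-correct upstream)")
    if N < 1:
        raise ValueError("N must be >= 1")
    return 100.0 * ((Pn / P0) ** (1.0 / N) - 1.0)


def surface_aarc(surface: PosteriorSurface, year0: int, year1: int) -> xr.DataArray:
    """Per-draw AARC between two years of a surface."""
    p0 = surface.sel_year(year0)
    p1 = surface.sel_year(year1)
    return xr.apply_ufunc(lambda a, b: aarc(a, b, year1 - year0), p0, p1)


def exceedance_probability(
    surface: PosteriorSurface, threshold: float, year: int
) -> pd.DataFrame:
    """Posterior probability that coverage meets or exceeds ``threshold``.

    Returns a frame per region (and subgroup, if stratified) with the
    exceedance probability and its Monte-Carlo standard error.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    da = surface.sel_year(year)
    prob = (da >= threshold).mean("draw")
    n = surface.n_draws
    out = prob.to_dataframe(name="prob").reset_index()
    out["mc_se"] = np.sqrt(out["prob"] * (1 - out["prob"]) / n)
    out["threshold"] = threshold
    out["year"] = year
    out["country"] = out["region"].map(surface.region_country)
    return out


def required_aarc(current, target, years: int):
    """AARC needed to move from ``current`` to ``target`` in ``years`` years.

    Floored at zero where the target is already met.
    """
    current = np.asarray(current, dtype=float)
    if np.any((current <= 0) | (current >= 1)):
        raise ValueError("current coverage must lie in (0, 1)")
    if years < 1:
        raise ValueError("years must be >= 1")
    return np.maximum(100.0 * ((target / current) ** (1.0 / years) - 1.0), 0.0)


def national_aggregate(
    surface: PosteriorSurface, region_weights: pd.Series | None = None
) -> PosteriorSurface:
    """Population-weighted national coverage from regional draws.

    ``region_weights`` must be non-negative and sum to one within each
    country; by default every region of a country gets equal weight
    (effective-sample-size shares can be passed in from the survey
    prep).  The aggregate is the per-draw weighted mean, hence always
    within the regional range.
    """
    rc = surface.region_country
    regions = surface.regions
    if region_weights is None:
        counts = rc.loc[regions].value_counts()
        region_weights = pd.Series(
            {r: 1.0 / counts[rc[r]] for r in regions}, dtype=float
        )
    w = region_weights.reindex(regions)
    if w.isna().any():
        raise ValueError("region_weights missing some regions")
    if (w < 0).any():
        raise ValueError("region weights must be non-negative")
    sums = w.groupby(rc.loc[regions]).sum()
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"region weights must sum to 1 per country; got {sums.to_dict()}")
    wda = xr.DataArray(w.to_numpy(), dims=("region",), coords={"region": regions})
    countries = sorted(set(rc.loc[regions]))
    pieces = []
    for c in countries:
        members = [r for r in regions if rc[r] == c]
        agg = (surface.draws.sel(region=members) * wda.sel(region=members)).sum("region")
        pieces.append(agg.expand_dims(region=[c]))
    nat = xr.concat(pieces, dim="region").transpose(*surface.draws.dims)
    return PosteriorSurface(
        draws=nat,
        region_country=pd.Series({c: c for c in countries}),
        diagnostics=surface.diagnostics,
        provenance={**surface.provenance, "aggregated": True},
    )


def n_eff_region_weights(cells: pd.DataFrame) -> pd.Series:
    """Effective-sample-size shares as a population-size proxy per region."""
    tot = cells.groupby("region")["n_eff"].sum()
    country = cells.drop_duplicates("region").set_index("region")["country"]
    shares = tot / tot.groupby(country).transform("sum")
    return shares.rename("weight")


def best_region_scenario(
    surface: PosteriorSurface,
    period: tuple[int, int],
    horizon_year: int,
    region_weights: pd.Series | None = None,
):
    """Counterfactual: every country follows its best-performing region.

    The best region maximises posterior-mean AARC over ``period``; the
    national trajectory restarts at the period's end and compounds that
    region's per-draw AARC to the horizon.  The baseline compounds the
    national AARC over the same period by the same rule, so with
    identical regions scenario and baseline coincide.  Returns
    ``(scenario, baseline, chosen)`` where the surfaces are national
    and ``chosen`` maps country to (best region, flag for single-region
    countries).
    """
    y0, y1 = period
    rates = surface_aarc(surface, y0, y1)
    if surface.stratified:
        rates = rates.mean("subgroup")
    mean_rate = rates.mean("draw")
    rc = surface.region_country
    nat_base = national_aggregate(surface, region_weights)
    nat_rates = surface_aarc(nat_base, y0, y1)
    if nat_base.stratified:
        nat_rates = nat_rates.mean("subgroup")
    chosen: dict[str, dict] = {}
    years_out = np.arange(y1, horizon_year + 1)

    def compound(p_start, rate_draws):
        grow = (1.0 + rate_draws / 100.0)[:, None] ** (years_out - y1)[None, :]
        return np.clip(p_start[:, None] * grow, 0.0, 1.0)

    scen_pieces, base_pieces = [], []
    for c in nat_base.regions:
        members = [r for r in surface.regions if rc[r] == c]
        sub = mean_rate.sel(region=members)
        best = str(sub["region"].values[int(sub.argmax("region"))])
        chosen[c] = {"best_region": best, "single_region": len(members) == 1}
        p_start = nat_base.sel_year(y1).sel(region=c).values
        if nat_base.stratified:
            p_start = p_start.mean(axis=-1)
        for bucket, rate_draws in (
            (scen_pieces, rates.sel(region=best).values),
            (base_pieces, nat_rates.sel(region=c).values),
        ):
            traj = compound(p_start, rate_draws)
            bucket.append(
                xr.DataArray(
                    traj[:, None, :],
                    dims=("draw", "region", "year"),
                    coords={
                        "draw": np.arange(traj.shape[0]),
                        "region": [c],
                        "year": years_out,
                    },
                )
            )
    countries = pd.Series({c: c for c in nat_base.regions})
    scenario = PosteriorSurface(
        draws=xr.concat(scen_pieces, dim="region"),
        region_country=countries,
        provenance={**surface.provenance, "scenario": "best_region", "period": period},
    )
    baseline = PosteriorSurface(
        draws=xr.concat(base_pieces, dim="region"),
        region_country=countries,
        provenance={**surface.provenance, "scenario": "national_aarc", "period": period},
    )
    return scenario, baseline, chosen


def target_assessment(
    surface: PosteriorSurface,
    horizon_year: int = 2030,
    thresholds: dict[str, float] | None = None,
    decision_cutoff: float = 0.5,
    region_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-country target table: exceedance, regions reaching, required AARC.

    A region counts as "projected to reach" a target when its posterior
    exceedance probability is at least ``decision_cutoff``.
    """
    thresholds = thresholds or TARGETS
    proj = project(surface, horizon_year)
    if proj.stratified:
        proj = proj.with_draws(proj.draws.mean("subgroup"))
    nat = national_aggregate(proj, region_weights)
    rows = []
    last_obs = int(surface.years.max())
    for name, thr in thresholds.items():
        reg = exceedance_probability(proj, thr, horizon_year)
        natp = exceedance_probability(nat, thr, horizon_year)
        for c in nat.regions:
            sub = reg[reg["country"] == c]
            cur = float(nat.sel_year(last_obs).sel(region=c).mean("draw"))
            rows.append(
                {
                    "country": c,
                    "target": name,
                    "threshold": thr,
                    "national_exceedance": float(natp.loc[natp["region"] == c, "prob"].iloc[0]),
                    "regions_total": len(sub),
                    "regions_reaching": int((sub["prob"] >= decision_cutoff).sum()),
                    "required_aarc": float(
                        required_aarc(cur, thr, horizon_year - last_obs)
                    ),
                }
            )
    return pd.DataFrame(rows)
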