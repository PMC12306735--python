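"""Synthetic DHS-like survey generator.

Emulates the data-generating structure the downstream analysis assumes:
region-level coverage that is linear on the logit scale over time, BYM2
spatially correlated region effects nested in countries, wealth and
education gradients that may narrow over time, and a stratified
two-stage cluster survey with heterogeneous sampling weights.

The generator is first-class, tested code: its defaults define the
study conditions for every simulation-based check in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import lognorm, norm

from .graphs import RegionGraph
from .icar import build_icar_precision, bym2_effect, sample_icar, scale_icar

__all__ = [
    "TruthParams",
    "TruthSurface",
    "SurveyDesign",
    "simulate_truth",
    "simulate_surveys",
    "true_marginal_coverage",
    "true_region_slopes",
    "VACCINES",
    "WEALTH_RIDITS",
]

VACCINES = ("bcg", "polio3", "dpt3", "mcv1")
#: ridit midpoints of five equal wealth quintiles, poorest -> richest
WEALTH_RIDITS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
EDU_GROUPS = ("less", "most")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class TruthParams:
    """Hyperparameters of the true coverage surface (logit scale).

    Defaults sketch an African DHS-era vaccine landscape: ~70% typical
    coverage improving by ~0.05 logit/year, moderate spatial structure,
    and positive wealth/education gradients that narrow slowly.
    """

    alpha_mean: float = float(logit(0.70))
    alpha_sd: float = 0.4          # between-country intercept spread
    beta_mean: float = 0.05        # mean country trend, logit units / year
    beta_sd: float = 0.02
    sigma: float = 0.35            # marginal sd of BYM2 region effect
    phi: float = 0.6               # structured fraction of region effect
    slope_sd: float = 0.02         # region slope deviations, logit / year
    wealth_gradient: float = 0.8   # logit gap across the full wealth ridit range at t0
    wealth_time_gradient: float = -0.015   # yearly change of that gap
    edu_gradient: float = 0.5
    edu_time_gradient: float = -0.008
    child_sd: float = 0.8          # shared per-child propensity (vaccine correlation)
    cluster_sd: float = 0.25       # cluster-level intercept sd
    vaccine_offsets: tuple[tuple[str, float], ...] = (
        ("bcg", 0.8),
        ("polio3", 0.1),
        ("dpt3", 0.0),
        ("mcv1", -0.3),
    )

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.sigma < 0 or self.slope_sd < 0 or self.child_sd < 0:
            raise ValueError("scale parameters must be non-negative")


@dataclass(frozen=True)
class TruthSurface:
    """True logit-linear coverage surface on a region graph.

    The linear predictor for region *i*, year *t*, wealth quintile *w*
    and education group *e* is

    ``logit p = alpha_c(i) + b_i + gamma_w + gamma_e
                + (beta_c(i) + g_i + delta_w + delta_e) * (t - t0)``

    so that coverage stays strictly inside (0, 1) and setting every
    effect to zero leaves ``p = expit(alpha_c)``.
    """

    graph: RegionGraph
    years: tuple[int, ...]
    alpha_c: dict[str, float]
    beta_c: dict[str, float]
    u: np.ndarray                  # scaled structured effect, region order
    v: np.ndarray                  # iid effect, region order
    b: np.ndarray                  # combined region intercept effect
    g: np.ndarray                  # region slope deviations
    gamma_w: np.ndarray            # wealth offsets, quintiles 1..5
    delta_w: np.ndarray            # wealth x time, per year
    gamma_e: np.ndarray            # education offsets (less, most)
    delta_e: np.ndarray
    params: TruthParams = field(default_factory=TruthParams)
    #: optional (break_year, slope_factor): after break_year every time trend
    #: continues at slope_factor times its pre-break rate (0 = flat)
    trend_break: tuple[int, float] | None = None

    @property
    def t0(self) -> int:
        return self.years[0]

    def with_trend_break(self, break_year: int, slope_factor: float = 0.0) -> "TruthSurface":
        """Truth whose trends slow (or flatten) after ``break_year``.

        Emulates recent-period stagnation: coverage follows the original
        logit-linear path up to the break, then continues at
        ``slope_factor`` times the original rate.
        """
        if not self.years[0] <= break_year <= self.years[-1]:
            raise ValueError("break_year must fall inside the truth years")
        return replace(self, trend_break=(int(break_year), float(slope_factor)))

    def _effective_time(self, year) -> np.ndarray:
        t = np.asarray(year, dtype=float) - self.t0
        if self.trend_break is None:
            return t
        tb, factor = self.trend_break
        tb = tb - self.t0
        return np.where(t > tb, tb + factor * (t - tb), t)

    def _region_index(self, regions) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.graph.region_ids)}
        return np.array([lookup[r] for r in np.atleast_1d(regions)])

    def linpred(self, region, year, wealth_q=None, edu=None, vaccine=None) -> np.ndarray:
        """Logit-scale linear predictor, broadcasting over array inputs."""
        ri = self._region_index(region)
        country = [self.graph.region_country[r] for r in np.atleast_1d(region)]
        alpha = np.array([self.alpha_c[c] for c in country])
        beta = np.array([self.beta_c[c] for c in country])
        t = self._effective_time(year)
        eta = alpha + self.b[ri] + (beta + self.g[ri]) * t
        if wealth_q is not None:
            wq = np.asarray(wealth_q, dtype=int) - 1
            eta = eta + self.gamma_w[wq] + self.delta_w[wq] * t
        if edu is not None:
            ei = np.asarray([EDU_GROUPS.index(e) for e in np.atleast_1d(edu)])
            eta = eta + self.gamma_e[ei] + self.delta_e[ei] * t
        if vaccine is not None:
            eta = eta + dict(self.params.vaccine_offsets)[vaccine]
        return eta

    def coverage(self, region, year, wealth_q=None, edu=None, vaccine=None) -> np.ndarray:
        """Conditional coverage (no child/cluster propensity integration)."""
        return expit(self.linpred(region, year, wealth_q, edu, vaccine))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.graph.region_ids:
            for t in self.years:
                for q in range(1, 6):
                    for e in EDU_GROUPS:
                        rows.append(
                            {
                                "country": self.graph.region_country[r],
                                "region": r,
                                "year": t,
                                "wealth_quintile": q,
                                "education_group": e,
                                "p": float(self.coverage(r, t, q, e)[0]),
                            }
                        )
        return pd.DataFrame(rows)


def simulate_truth(
    graph: RegionGraph,
    years,
    params: TruthParams | None = None,
    seed: int = 0,
) -> TruthSurface:
    """Draw one true coverage surface from the generator's model family."""
    years = tuple(int(y) for y in years)
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    params = params or TruthParams()
    rng = np.random.default_rng(seed)
    countries = graph.country_ids
    alpha_c = {c: params.alpha_mean + params.alpha_sd * rng.standard_normal() for c in countries}
    beta_c = {c: params.beta_mean + params.beta_sd * rng.standard_normal() for c in countries}
    n = graph.n_regions
    if len(graph.edges) > 0:
        prec = scale_icar(build_icar_precision(graph))
        u = sample_icar(prec, rng, size=1)[0]
    else:
        u = np.zeros(n)
    v = rng.standard_normal(n)
    phi = params.phi if len(graph.edges) > 0 else 0.0
    b = bym2_effect(u, v, phi, params.sigma)
    g = params.slope_sd * rng.standard_normal(n)
    centered = WEALTH_RIDITS - 0.5
    gamma_w = params.wealth_gradient * centered
    delta_w = params.wealth_time_gradient * centered
    edu_centered = np.array([-0.5, 0.5])
    gamma_e = params.edu_gradient * edu_centered
    delta_e = params.edu_time_gradient * edu_centered
    return TruthSurface(
        graph=graph, years=years, alpha_c=alpha_c, beta_c=beta_c,
        u=u, v=v, b=b, g=g,
        gamma_w=gamma_w, delta_w=delta_w, gamma_e=gamma_e, delta_e=delta_e,
        params=params,
    )


@dataclass(frozen=True)
class SurveyDesign:
    """Stratified two-stage cluster design.

    Each surveyed region contributes ``n_strata`` strata (think
    urban/rural), each with ``clusters_per_stratum`` sampled clusters of
    ``children_per_cluster`` children.  Weights are inverse inclusion
    probabilities (one per stratum) times a log-normal dispersion factor
    truncated at its own 1st/99th percentiles.
    """

    survey_years: dict[str, tuple[int, ...]]
    n_strata: int = 2
    clusters_per_stratum: int = 10
    children_per_cluster: int = 20
    weight_dispersion: float = 0.3
    n_assets: int = 8

    def __post_init__(self):
        if min(self.n_strata, self.clusters_per_stratum, self.children_per_cluster) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")


# fixed asset model: loadings tie ownership to the latent wealth score so the
# first principal component of the asset matrix recovers the wealth ranking
_ASSET_LOADINGS = np.array([1.4, 1.2, 1.1, 1.0, 0.9, 0.8, 1.3, 1.0])
_ASSET_INTERCEPTS = np.array([-1.5, -0.8, -0.2, 0.3, 0.9, 1.4, -1.0, 0.0])

_QUINTILE_EDGES = norm.ppf([0.2, 0.4, 0.6, 0.8])


def simulate_surveys(
    truth: TruthSurface,
    design: SurveyDesign,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate child records and a household asset table.

    Returns ``(children, assets)``.  One household per child is drawn (a
    simplification; DHS households can hold several eligible children).
    Vaccine indicators share a per-child latent normal propensity, so
    full immunization is positively correlated across the four vaccines.
    """
    rng = np.random.default_rng(seed)
    for c, yrs in design.survey_years.items():
        bad = [y for y in yrs if y not in truth.years]
        if bad:
            raise ValueError(f"survey years {bad} for {c} outside truth years")
    if design.weight_dispersion > 0:
        lo = lognorm.ppf(0.01, s=design.weight_dispersion)
        hi = lognorm.ppf(0.99, s=design.weight_dispersion)
    rows = []
    asset_rows = []
    p = truth.params
    n_per_cluster = design.children_per_cluster
    child_counter = 0
    offsets = dict(p.vaccine_offsets)
    region_lookup = {r: i for i, r in enumerate(truth.graph.region_ids)}
    for region in truth.graph.region_ids:
        country = truth.graph.region_country[region]
        ridx = region_lookup[region]
        for year in design.survey_years.get(country, ()):
            teff = float(truth._effective_time(year))
            eta_ry = (truth.alpha_c[country] + truth.b[ridx]
                      + (truth.beta_c[country] + truth.g[ridx]) * teff)
            for stratum in range(design.n_strata):
                stratum_id = f"{region}_{year}_s{stratum}"
                base_weight = float(np.exp(0.25 * rng.standard_normal()))
                for cluster in range(design.clusters_per_stratum):
                    cluster_id = f"{stratum_id}_c{cluster}"
                    cluster_eff = p.cluster_sd * rng.standard_normal()
                    z_w = rng.standard_normal(n_per_cluster) + 0.3 * rng.standard_normal()
                    wq = 1 + np.searchsorted(_QUINTILE_EDGES, z_w)
                    edu = np.where(rng.random(n_per_cluster) < expit(0.8 * z_w), "most", "less")
                    ages = rng.integers(0, 60, size=n_per_cluster)
                    propensity = p.child_sd * rng.standard_normal(n_per_cluster)
                    if design.weight_dispersion > 0:
                        disp = np.clip(
                            np.exp(design.weight_dispersion * rng.standard_normal(n_per_cluster)),
                            lo, hi,
                        )
                    else:
                        disp = np.ones(n_per_cluster)
                    weights = base_weight * disp
                    ei = (edu == "most").astype(int)
                    eta0 = (eta_ry
                            + truth.gamma_w[wq - 1] + truth.delta_w[wq - 1] * teff
                            + truth.gamma_e[ei] + truth.delta_e[ei] * teff
                            + cluster_eff + propensity)
                    vacc = {
                        name: (rng.random(n_per_cluster)
                               < expit(eta0 + offsets[name])).astype(int)
                        for name in VACCINES
                    }
                    own_p = expit(_ASSET_INTERCEPTS[: design.n_assets]
                                  + np.outer(z_w, _ASSET_LOADINGS[: design.n_assets]))
                    owned = (rng.random(own_p.shape) < own_p).astype(int)
                    ids = np.arange(child_counter, child_counter + n_per_cluster)
                    rows.append(
                        {
                            "ids": ids, "country": country, "region": region,
                            "year": year, "ages": ages, "vacc": vacc,
                            "wq": wq, "edu": edu, "weights": weights,
                            "cluster_id": cluster_id, "stratum_id": stratum_id,
                        }
                    )
                    asset_rows.append((ids, weights, owned))
                    child_counter += n_per_cluster
    if rows:
        all_ids = np.concatenate([r["ids"] for r in rows])
        rep = lambda key: np.concatenate(  # noqa: E731
            [np.repeat(r[key], len(r["ids"])) for r in rows]
        )
        children = pd.DataFrame(
            {
                "child_id": [f"ch{i:07d}" for i in all_ids],
                "household_id": [f"h{i:07d}" for i in all_ids],
                "country": rep("country"),
                "region": rep("region"),
                "year": rep("year"),
                "age_months": np.concatenate([r["ages"] for r in rows]),
                **{
                    v: np.concatenate([r["vacc"][v] for r in rows])
                    for v in VACCINES
                },
                "wealth_quintile": np.concatenate([r["wq"] for r in rows]),
                "education_group": np.concatenate([r["edu"] for r in rows]),
                "weight": np.concatenate([r["weights"] for r in rows]),
                "cluster_id": rep("cluster_id"),
                "stratum_id": rep("stratum_id"),
            }
        )
        owned_all = np.concatenate([o for _, _, o in asset_rows])
        assets = pd.DataFrame(
            {
                "household_id": children["household_id"],
                "weight": np.concatenate([w for _, w, _ in asset_rows]),
                **{
                    f"asset_{k}": owned_all[:, k] for k in range(design.n_assets)
                },
            }
        )
    else:
        cols = ["child_id", "household_id", "country", "region", "year", "age_months",
                *VACCINES, "wealth_quintile", "education_group", "weight",
                "cluster_id", "stratum_id"]
        children = pd.DataFrame(columns=cols)
        assets = pd.DataFrame(
            columns=["household_id", "weight"]
            + [f"asset_{k}" for k in range(design.n_assets)]
        )
    return children, assets


# -- population-level truths for recovery checks ------------------------------

def _edu_share_by_quintile(coef: float = 0.8, grid: int = 2001) -> np.ndarray:
    """P(most educated | wealth quintile) under the generator's latent link."""
    shares = np.empty(5)
    qs = np.concatenate(([-np.inf], _QUINTILE_EDGES, [np.inf]))
    z = np.linspace(-6, 6, grid)
    dens = norm.pdf(z)
    for k in range(5):
        mask = (z >= qs[k]) & (z < qs[k + 1])
        w = dens * mask
        shares[k] = float(np.sum(w * expit(coef * z)) / np.sum(w))
    return shares


def true_marginal_coverage(
    truth: TruthSurface,
    vaccine: str = "dpt3",
    years=None,
    wealth_q: int | None = None,
) -> pd.DataFrame:
    """Population coverage per (region, year), integrating latent structure.

    Marginalises the per-child propensity and cluster effect by
    Gauss–Hermite quadrature and averages over the wealth x education
    mixture (or conditions on one wealth quintile, still averaging
    education within it).  This is the quantity a survey of the region
    estimates, and the recovery target for the model.
    """
    years = list(years) if years is not None else list(truth.years)
    p = truth.params
    extra_sd = float(np.hypot(p.child_sd, p.cluster_sd))
    edu_share = _edu_share_by_quintile()
    quintiles = [wealth_q] if wealth_q is not None else list(range(1, 6))
    qw = np.ones(len(quintiles)) / len(quintiles)
    rows = []
    for region in truth.graph.region_ids:
        for year in years:
            acc = 0.0
            for widx, q in zip(qw, quintiles):
                for e, es in (("less", 1 - edu_share[q - 1]), ("most", edu_share[q - 1])):
                    eta = float(truth.linpred(region, year, q, e, vaccine)[0])
                    pm = float(np.sum(_GH_WEIGHTS * expit(eta + extra_sd * _GH_NODES)))
                    acc += widx * es * pm
            rows.append({"region": region, "year": year, "p": acc})
    out = pd.DataFrame(rows)
    out["country"] = out["region"].map(truth.graph.region_country)
    return out


def true_region_slopes(truth: TruthSurface, vaccine: str = "dpt3") -> pd.Series:
    """Per-region OLS slope of logit marginal coverage over the truth years."""
    marg = true_marginal_coverage(truth, vaccine=vaccine)
    out = {}
    for region, grp in marg.groupby("region"):
        t = grp["year"].to_numpy(dtype=float)
        z = logit(grp["p"].to_numpy())
        out[region] = float(np.polyfit(t - t.mean(), z, 1)[0])
    return pd.Series(out, name="slope")


# -- plain-text writers -------------------------------------------------------

def write_children(children: pd.DataFrame, path) -> None:
    children.to_csv(path, sep="\t", index=False)


def read_children(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: TruthSurface, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
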