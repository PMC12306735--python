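"""Bayesian spatio-temporal coverage model (Besag / BYM / BYM2 family).

The model places a logit-linear time trend in every Admin-1 region,
with spatially structured region intercepts, region-level random
slopes, an optional hierarchical country level, and optional
socioeconomic-subgroup offsets, time interactions and region-subgroup
slopes.  Six variants are recognised::

    besag_1  structured (ICAR) region intercepts only
    besag_2  ... plus the country level
    bym_1    structured + unstructured intercepts, independent scales
    bym_2    ... plus the country level
    bym2_1   BYM2 reparameterisation (total scale sigma, mixing phi)
    bym2_2   ... plus the country level   (default)

The linear predictor for region i (country c), centered year t and
subgroup s is

``logit p = mu + a_c + b_i + gamma_s + (beta + e_c + g_i + delta_s + h_is) t``

with a binomial likelihood on effective counts (Kish) by default, PC
priors on every scale and on the BYM2 mixing proportion, and soft
sum-to-zero constraints on the ICAR component per connected component.

Fitting follows the statsmodels idiom: build a
:class:`CoverageTrendModel`, call :meth:`~CoverageTrendModel.fit`, and
work with the returned :class:`CoverageTrendResults`.

The default backend is a nested Laplace approximation, the standard
approximate-inference scheme for latent Gaussian models: conditional on
the (few) hyperparameters the latent field posterior is log-concave and
is maximised by Newton iterations; the hyperparameters are optimised on
the Laplace-approximated marginal posterior; posterior draws then
propagate hyperparameter uncertainty by sampling the hyperparameters
from their Gaussian approximation and the field from its conditional
Gaussian at each hyperparameter draw.  (A joint mode over field and
scales would be degenerate — the usual hierarchical funnel — which is
why the hyperparameters are marginalised.)  An affine-invariant
ensemble MCMC backend on the same (non-centered) posterior is available
as a cross-check.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import binom as binom_dist
from scipy.stats import norm as norm_dist

from .graphs import RegionGraph
from .icar import (
    PCPriorMixing,
    build_icar_precision,
    pc_prior_scale_rate,
    scale_icar,
    structured_covariance_eigenvalues,
)
from .surface import PosteriorSurface

__all__ = ["VARIANTS", "ModelSpec", "CoverageTrendModel", "CoverageTrendResults"]

VARIANTS = ("besag_1", "besag_2", "bym_1", "bym_2", "bym2_1", "bym2_2")

_SOFT_SUM_SD = 0.01      # soft sum-to-zero sd for ICAR components
_MU_SD = 5.0             # weak prior sds for fixed-ish effects
_BETA_SD = 1.0
_TH_BOUNDS = {"scale": (-8.0, 3.0), "phi": (-6.0, 6.0)}


@dataclass(frozen=True)
class ModelSpec:
    """Variant, likelihood and prior hyperparameters of one fit."""

    variant: str = "bym2_2"
    stratified: bool = False
    likelihood: str = "binomial"         # or "gaussian" (on logit p_hat)
    U_sigma: float = 1.0                 # PC prior P(sigma > U_sigma) = alpha_sigma
    alpha_sigma: float = 0.01
    U_phi: float = 0.5                   # PC prior P(phi < U_phi) = alpha_phi
    alpha_phi: float = 2.0 / 3.0
    U_slope: float = 0.1                 # PC prior for slope-type scales (logit/yr)
    alpha_slope: float = 0.01
    min_draws: int = 1000
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.likelihood not in ("binomial", "gaussian"):
            raise ValueError("likelihood must be 'binomial' or 'gaussian'")
        for u, a in ((self.U_sigma, self.alpha_sigma), (self.U_slope, self.alpha_slope)):
            if u <= 0 or not 0 < a < 1:
                raise ValueError("PC prior needs U > 0 and alpha in (0, 1)")

    @property
    def family(self) -> str:
        return self.variant.rsplit("_", 1)[0]

    @property
    def has_country_level(self) -> bool:
        return self.variant.endswith("_2")


class CoverageTrendModel:
    """Spatio-temporal coverage model bound to cells and a region graph.

    Parameters
    ----------
    cells : DataFrame
        Output of :func:`immucast.survey.estimate_coverage`; needs
        ``country, region, year, p_hat, n_eff`` (plus ``logit_p,
        logit_se`` for the Gaussian likelihood, and a subgroup column
        when ``spec.stratified``).
    graph : RegionGraph
        Adjacency of all modelled regions (regions without data are
        still modelled, borrowing through space and the trend).
    spec : ModelSpec
    subgroup_col : str, optional
        Column holding the ordered subgroup (e.g. ``wealth_quintile``).

    Notes
    -----
    Internally the latent field is standardized (non-centered): each
    random-effect block has a fixed standard-normal (or scaled-ICAR)
    prior, and its standard deviation enters as a per-column scaling of
    the design matrix controlled by the hyperparameters.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        graph: RegionGraph,
        spec: ModelSpec | None = None,
        subgroup_col: str | None = None,
    ):
        self.spec = spec or ModelSpec()
        self.graph = graph
        if self.spec.stratified and subgroup_col is None:
            raise ValueError("stratified spec needs subgroup_col")
        self.subgroup_col = subgroup_col if self.spec.stratified else None
        data = cells.loc[(cells["n"] > 0) & cells["p_hat"].notna()].copy()
        if data.empty:
            raise ValueError("no non-empty cells to fit")
        unknown = set(data["region"]) - set(graph.region_ids)
        if unknown:
            raise ValueError(f"cells reference regions not in graph: {sorted(unknown)}")
        self.regions = list(graph.region_ids)
        self.countries = graph.country_ids
        self._r_index = {r: i for i, r in enumerate(self.regions)}
        self._c_index = {c: i for i, c in enumerate(self.countries)}
        rc = graph.region_country
        self.region_country_idx = np.array([self._c_index[rc[r]] for r in self.regions])
        for c in set(data["country"]):
            if c not in self._c_index:
                raise ValueError(f"cells reference country {c!r} not in graph")
        self.t_ref = float(np.median(data["year"]))
        self.years = np.arange(int(data["year"].min()), int(data["year"].max()) + 1)
        if self.subgroup_col:
            self.subgroups = sorted(data[self.subgroup_col].unique())
            if len(self.subgroups) < 2:
                raise ValueError("stratified fit needs >= 2 subgroups")
        else:
            self.subgroups = None
        self._build_arrays(data)
        self._build_spatial()
        self._build_design()
        self.data = data

    # -- construction ------------------------------------------------------
    def _build_arrays(self, data: pd.DataFrame) -> None:
        self.ri = data["region"].map(self._r_index).to_numpy()
        self.ci = data["country"].map(self._c_index).to_numpy()
        self.t = data["year"].to_numpy(dtype=float) - self.t_ref
        n_eff = data["n_eff"].to_numpy(dtype=float)
        self.m = np.maximum(np.round(n_eff), 1.0)
        self.y = np.clip(np.round(n_eff * data["p_hat"].to_numpy(dtype=float)), 0.0, self.m)
        if self.spec.likelihood == "gaussian":
            if not {"logit_p", "logit_se"} <= set(data.columns):
                raise ValueError("gaussian likelihood needs logit_p / logit_se columns")
            self.z = data["logit_p"].to_numpy(dtype=float)
            self.se = data["logit_se"].to_numpy(dtype=float)
        if self.subgroup_col:
            smap = {s: i for i, s in enumerate(self.subgroups)}
            self.si = data[self.subgroup_col].map(smap).to_numpy()
        else:
            self.si = None

    def _build_spatial(self) -> None:
        self.has_struct = len(self.graph.edges) > 0
        if self.spec.family == "besag" and not self.has_struct:
            raise ValueError(
                "Besag variants need at least one adjacency edge (structured effect undefined)"
            )
        self._phi_prior = None
        if self.has_struct:
            prec = scale_icar(build_icar_precision(self.graph))
            self.prec = prec
            struct = [r for r in self.regions if r not in prec.isolated]
            self.struct_regions = struct
            self.struct_pos = np.array([self._r_index[r] for r in struct])
            sel = prec.index_of(struct)
            self.Qs = prec.Q_star[np.ix_(sel, sel)]
            lookup = {r: i for i, r in enumerate(struct)}
            self.comp_masks = []
            for comp in prec.components:
                mask = np.zeros(len(struct))
                mask[[lookup[r] for r in comp]] = 1.0
                self.comp_masks.append(mask)
            if self.spec.family == "bym2":
                gam = structured_covariance_eigenvalues(prec)
                self._phi_prior = PCPriorMixing(gam, self.spec.U_phi, self.spec.alpha_phi)
        else:
            self.struct_regions = []
            self.struct_pos = np.array([], dtype=int)

    def _build_design(self) -> None:
        """Design matrix over the standardized latent field + hyper layout."""
        spec = self.spec
        n_r, n_c, n_obs = len(self.regions), len(self.countries), len(self.ri)
        self.country_level = spec.has_country_level and n_c > 1
        cols: list[np.ndarray] = []
        latent: list[tuple[str, int]] = []
        ones = np.ones(n_obs)

        def add(name, block):
            latent.append((name, block.shape[1]))
            cols.append(block)

        def onehot(idx, n, vals):
            out = np.zeros((n_obs, n))
            out[np.arange(n_obs), idx] = vals
            return out

        add("mu", ones[:, None])
        add("beta", self.t[:, None])
        if self.country_level:
            add("a", onehot(self.ci, n_c, ones))
            add("e", onehot(self.ci, n_c, self.t))
        if self.has_struct:
            n_u = len(self.struct_regions)
            upos = {p: j for j, p in enumerate(self.struct_pos)}
            ublock = np.zeros((n_obs, n_u))
            for row, r in enumerate(self.ri):
                if r in upos:
                    ublock[row, upos[r]] = 1.0
            add("u", ublock)
        if spec.family in ("bym", "bym2"):
            add("v", onehot(self.ri, n_r, ones))
        add("g", onehot(self.ri, n_r, self.t))
        if self.subgroup_col:
            k = len(self.subgroups) - 1
            gblock = np.zeros((n_obs, k))
            dblock = np.zeros((n_obs, k))
            hblock = np.zeros((n_obs, n_r * k))
            nz = self.si >= 1
            gblock[nz, self.si[nz] - 1] = 1.0
            dblock[nz, self.si[nz] - 1] = self.t[nz]
            hblock[nz, self.ri[nz] * k + self.si[nz] - 1] = self.t[nz]
            add("gamma", gblock)
            add("delta", dblock)
            add("h", hblock)
        self.X = np.concatenate(cols, axis=1)
        self.latent_layout: dict[str, slice] = {}
        ofs = 0
        for name, size in latent:
            self.latent_layout[name] = slice(ofs, ofs + size)
            ofs += size
        self.n_latent = ofs
        # fixed prior precision of the standardized field
        P0 = np.zeros((ofs, ofs))
        diag = np.ones(ofs)
        diag[self.latent_layout["mu"]] = 1.0 / _MU_SD**2
        diag[self.latent_layout["beta"]] = 1.0 / _BETA_SD**2
        if self.subgroup_col:
            diag[self.latent_layout["gamma"]] = 1.0 / _MU_SD**2
            diag[self.latent_layout["delta"]] = 1.0 / _BETA_SD**2
        P0[np.diag_indices(ofs)] = diag
        if self.has_struct:
            sl = self.latent_layout["u"]
            P0[sl, sl] = self.Qs
            for mask in self.comp_masks:
                P0[sl, sl] += np.outer(mask, mask) / _SOFT_SUM_SD**2
        self.P0 = P0
        # hyperparameters
        hyper: list[tuple[str, str, float]] = []  # (name, kind, start)
        lam_sig = pc_prior_scale_rate(spec.U_sigma, spec.alpha_sigma)
        lam_slp = pc_prior_scale_rate(spec.U_slope, spec.alpha_slope)
        if self.country_level:
            hyper += [("th_sa", "scale", np.log(0.2)), ("th_se", "slope", np.log(0.02))]
        if spec.family == "besag":
            hyper.append(("th_su", "scale", np.log(0.2)))
        elif spec.family == "bym":
            hyper.append(("th_su", "scale", np.log(0.2)))
            hyper.append(("th_sv", "scale", np.log(0.2)))
        else:
            hyper.append(("th_sb", "scale", np.log(0.2)))
            if self.has_struct:
                hyper.append(("th_phi", "phi", 0.0))
        hyper.append(("th_sg", "slope", np.log(0.02)))
        if self.subgroup_col:
            hyper.append(("th_sh", "slope", np.log(0.02)))
        self.hyper_names = [h[0] for h in hyper]
        self.hyper_index = {n: i for i, n in enumerate(self.hyper_names)}
        self.n_hyper = len(hyper)
        self._hyper_start = np.array([h[2] for h in hyper])
        self._hyper_bounds = [
            _TH_BOUNDS["phi" if h[1] == "phi" else "scale"] for h in hyper
        ]
        self._hyper_rate = {
            h[0]: (lam_slp if h[1] == "slope" else lam_sig) for h in hyper if h[1] != "phi"
        }

    # -- hyperparameter machinery ------------------------------------------
    def column_scales(self, theta: np.ndarray) -> np.ndarray:
        """Per-column design scaling S(theta) for the standardized field."""
        S = np.ones(self.n_latent)
        idx = self.hyper_index
        th = lambda n: theta[idx[n]]  # noqa: E731
        if self.country_level:
            S[self.latent_layout["a"]] = np.exp(th("th_sa"))
            S[self.latent_layout["e"]] = np.exp(th("th_se"))
        fam = self.spec.family
        if fam == "besag":
            S[self.latent_layout["u"]] = np.exp(th("th_su"))
        elif fam == "bym":
            S[self.latent_layout["u"]] = np.exp(th("th_su"))
            S[self.latent_layout["v"]] = np.exp(th("th_sv"))
        else:
            sb = np.exp(th("th_sb"))
            if self.has_struct:
                phi = expit(th("th_phi"))
                S[self.latent_layout["u"]] = sb * np.sqrt(phi)
                S[self.latent_layout["v"]] = sb * np.sqrt(1.0 - phi)
            else:
                S[self.latent_layout["v"]] = sb
        S[self.latent_layout["g"]] = np.exp(th("th_sg"))
        if self.subgroup_col:
            S[self.latent_layout["h"]] = np.exp(th("th_sh"))
        return S

    def hyper_logprior(self, theta: np.ndarray) -> float:
        lp = 0.0
        for name, lam in self._hyper_rate.items():
            th = theta[self.hyper_index[name]]
            lp += np.log(lam) - lam * np.exp(th) + th  # PC prior + log-scale Jacobian
        if "th_phi" in self.hyper_index:
            th = theta[self.hyper_index["th_phi"]]
            phi = float(expit(th))
            lp += float(self._phi_prior.logpdf(phi)) + np.log(phi * (1 - phi))
        return float(lp)

    # -- likelihood ---------------------------------------------------------
    def _loglik_terms(self, eta: np.ndarray):
        """(loglik, working residual, working weight) at eta."""
        if self.spec.likelihood == "binomial":
            eta = np.clip(eta, -35, 35)
            p = expit(eta)
            ll = float(np.sum(self.y * eta - self.m * np.logaddexp(0.0, eta)))
            return ll, self.y - self.m * p, np.maximum(self.m * p * (1 - p), 1e-10)
        resid = self.z - eta
        w = 1.0 / self.se**2
        return float(-0.5 * np.sum(resid**2 * w)), resid * w, w

    def _newton(self, theta: np.ndarray, x0: np.ndarray | None = None,
                tol: float = 1e-10, maxiter: int = 100):
        """Mode and Cholesky of the conditional latent posterior at theta."""
        Xs = self.X * self.column_scales(theta)[None, :]
        x = np.zeros(self.n_latent) if x0 is None else x0.copy()
        obj = None
        for _ in range(maxiter):
            eta = Xs @ x
            ll, r, w = self._loglik_terms(eta)
            f = ll - 0.5 * float(x @ self.P0 @ x)
            grad = Xs.T @ r - self.P0 @ x
            H = Xs.T @ (w[:, None] * Xs) + self.P0
            cf = cho_factor(H, lower=True)
            dx = cho_solve(cf, grad)
            step = 1.0
            for _ in range(40):
                xn = x + step * dx
                lln = self._loglik_terms(Xs @ xn)[0]
                fn = lln - 0.5 * float(xn @ self.P0 @ xn)
                if fn >= f - 1e-12:
                    break
                step *= 0.5
            x = xn
            if obj is not None and abs(fn - obj) < tol * (1 + abs(fn)):
                obj = fn
                break
            obj = fn
        eta = Xs @ x
        ll, r, w = self._loglik_terms(eta)
        H = Xs.T @ (w[:, None] * Xs) + self.P0
        cf = cho_factor(H, lower=True)
        return x, cf, float(ll - 0.5 * x @ self.P0 @ x)

    def marginal_logpost(self, theta: np.ndarray, x0: np.ndarray | None = None) -> float:
        """Laplace-approximated log posterior of the hyperparameters."""
        x, cf, f = self._newton(theta, x0)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self._last_mode = x
        return f - 0.5 * logdet + self.hyper_logprior(theta)

    def logpost_joint(self, z: np.ndarray) -> float:
        """Joint (non-centered) log posterior over [latent, hyper] — MCMC target."""
        x, theta = z[: self.n_latent], z[self.n_latent:]
        lo = np.array([b[0] for b in self._hyper_bounds])
        hi = np.array([b[1] for b in self._hyper_bounds])
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        eta = (self.X * self.column_scales(theta)[None, :]) @ x
        ll = self._loglik_terms(eta)[0]
        return ll - 0.5 * float(x @ self.P0 @ x) + self.hyper_logprior(theta)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        draws: int | None = None,
        method: str = "laplace",
        mcmc_steps: int = 1500,
        mcmc_burn: int = 500,
    ) -> "CoverageTrendResults":
        """Fit and return posterior draws of coverage for every modelled cell."""
        draws = draws or self.spec.min_draws
        t_start = time.perf_counter()
        self._last_mode = None
        warm: dict = {"x": None}

        def neg(theta):
            val = -self.marginal_logpost(theta, warm["x"])
            warm["x"] = self._last_mode
            return val

        res = minimize(
            neg, self._hyper_start, method="L-BFGS-B", bounds=self._hyper_bounds,
            options={"maxiter": 200, "eps": 1e-4},
        )
        theta_hat = res.x
        warnings: list[str] = []
        if not res.success:
            warnings.append(f"hyperparameter optimizer: {res.message}")
        if method == "laplace":
            x_draws, th_draws, diag = self._laplace_draws(theta_hat, draws, seed)
        elif method == "mcmc":
            x_draws, th_draws, diag = self._mcmc_draws(theta_hat, draws, seed,
                                                       mcmc_steps, mcmc_burn)
        else:
            raise ValueError(f"unknown method {method!r}")
        diag["method"] = method
        diag["converged"] = bool(res.success)
        diag["runtime_s"] = time.perf_counter() - t_start
        diag["theta_mode"] = dict(zip(self.hyper_names, theta_hat))
        diag["warnings"] = warnings + diag.get("warnings", [])
        if not self.has_struct and self.spec.family in ("bym", "bym2"):
            diag["warnings"].append("no adjacency edges: structured component dropped")
        surface = self._surface_from_draws(x_draws, th_draws, diag, seed)
        return CoverageTrendResults(self, theta_hat, x_draws, th_draws, surface, diag)

    def _hyper_hessian(self, theta_hat: np.ndarray) -> np.ndarray:
        n = self.n_hyper
        h = 1e-3
        H = np.empty((n, n))
        f0 = self.marginal_logpost(theta_hat)
        fp = np.empty(n)
        fm = np.empty(n)
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h
            fp[i] = self.marginal_logpost(theta_hat + ei)
            fm[i] = self.marginal_logpost(theta_hat - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for i in range(n):
            for j in range(i + 1, n):
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i] = h
                ej[j] = h
                fpp = self.marginal_logpost(theta_hat + ei + ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
        return -H  # negative log posterior curvature

    def _laplace_draws(self, theta_hat, draws, seed):
        rng = np.random.default_rng(seed)
        if self.n_hyper > 0:
            Hh = self._hyper_hessian(theta_hat)
            w, V = np.linalg.eigh(Hh)
            w = np.maximum(w, 1e-6)
            Lh = V / np.sqrt(w)
            th_draws = theta_hat + rng.standard_normal((draws, self.n_hyper)) @ Lh.T
            lo = np.array([b[0] for b in self._hyper_bounds])
            hi = np.array([b[1] for b in self._hyper_bounds])
            th_draws = np.clip(th_draws, lo, hi)
        else:
            th_draws = np.zeros((draws, 0))
        x_hat, _, _ = self._newton(theta_hat)
        x_draws = np.empty((draws, self.n_latent))
        for d in range(draws):
            x_mode, cf, _ = self._newton(th_draws[d], x_hat, tol=1e-9, maxiter=30)
            z = rng.standard_normal(self.n_latent)
            # H = L L^T  =>  cov draw = L^{-T} z
            x_draws[d] = x_mode + solve_triangular(cf[0], z, lower=True, trans="T")
        diag = {
            "n_draws": draws,
            "ess_min": float(draws),
            "rhat_max": 1.0,  # independent draws by construction
        }
        return x_draws, th_draws, diag

    def _mcmc_draws(self, theta_hat, draws, seed, steps, burn):
        import arviz as az
        import emcee

        ndim = self.n_latent + self.n_hyper
        nwalkers = 2 * ndim + 2
        rng = np.random.default_rng(seed)
        x_hat, cf, _ = self._newton(theta_hat)
        center = np.concatenate([x_hat, theta_hat])
        p0 = center + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, self.logpost_joint)
        start = emcee.State(p0, random_state=np.random.RandomState(seed % 2**31).get_state())
        sampler.run_mcmc(start, steps, progress=False)
        chain = sampler.get_chain(discard=burn)           # (step, walker, dim)
        idata = az.convert_to_dataset(np.moveaxis(chain, 1, 0))
        rhat = float(np.nanmax(az.rhat(idata).to_array().values))
        ess = float(np.nanmin(az.ess(idata).to_array().values))
        flat = chain.reshape(-1, ndim)
        take = rng.choice(flat.shape[0], size=min(draws, flat.shape[0]), replace=False)
        sel = flat[take]
        diag = {"n_draws": int(take.size), "ess_min": ess, "rhat_max": rhat, "warnings": []}
        if rhat > self.spec.rhat_threshold:
            diag["warnings"].append(
                f"rhat {rhat:.3f} above threshold {self.spec.rhat_threshold}"
            )
        return sel[:, : self.n_latent], sel[:, self.n_latent:], diag

    # -- posterior surfaces -------------------------------------------------
    def _draw_components(self, x_draws: np.ndarray, th_draws: np.ndarray):
        """Per-draw region intercepts/slopes and subgroup terms."""
        D = x_draws.shape[0]
        n_r = len(self.regions)
        S = np.empty((D, self.n_latent))
        for d in range(D):
            S[d] = self.column_scales(th_draws[d])
        xs = x_draws * S
        get = lambda n: xs[:, self.latent_layout[n]]  # noqa: E731
        b = np.zeros((D, n_r))
        if self.has_struct:
            b[:, self.struct_pos] += get("u")
        if self.spec.family in ("bym", "bym2"):
            b += get("v")
        intercept = get("mu") + b
        slope = get("beta") + get("g")
        if self.country_level:
            intercept = intercept + get("a")[:, self.region_country_idx]
            slope = slope + get("e")[:, self.region_country_idx]
        out = {"intercept": intercept, "slope": slope}
        if self.subgroup_col:
            k = len(self.subgroups) - 1
            zero = np.zeros((D, 1))
            out["gamma"] = np.concatenate((zero, get("gamma")), axis=1)
            out["delta"] = np.concatenate((zero, get("delta")), axis=1)
            h = get("h").reshape(D, n_r, k)
            out["h"] = np.concatenate((np.zeros((D, n_r, 1)), h), axis=2)
        return out

    def _surface_from_draws(self, x_draws, th_draws, diagnostics, seed) -> PosteriorSurface:
        comp = self._draw_components(x_draws, th_draws)
        tgrid = self.years.astype(float) - self.t_ref
        if self.subgroup_col:
            base_i = comp["intercept"][:, :, None, None] + comp["gamma"][:, None, None, :]
            base_s = (
                comp["slope"][:, :, None, None]
                + comp["delta"][:, None, None, :]
                + comp["h"][:, :, None, :]
            )
            eta = base_i + base_s * tgrid[None, None, :, None]
            dims = ("draw", "region", "year", "subgroup")
            coords = {
                "draw": np.arange(x_draws.shape[0]),
                "region": self.regions,
                "year": self.years,
                "subgroup": self.subgroups,
            }
        else:
            eta = (
                comp["intercept"][:, :, None]
                + comp["slope"][:, :, None] * tgrid[None, None, :]
            )
            dims = ("draw", "region", "year")
            coords = {
                "draw": np.arange(x_draws.shape[0]),
                "region": self.regions,
                "year": self.years,
            }
        da = xr.DataArray(expit(eta), dims=dims, coords=coords, name="coverage")
        digest = hashlib.sha256(
            pd.util.hash_pandas_object(self.data[["region", "year", "p_hat"]]).values.tobytes()
        ).hexdigest()[:12]
        prov = {"spec": self.spec, "seed": seed, "data_hash": digest, "t_ref": self.t_ref}
        return PosteriorSurface(
            draws=da,
            region_country=self.graph.region_country,
            diagnostics=diagnostics,
            provenance=prov,
        )

    def cell_linpred(self, x_draws: np.ndarray, th_draws: np.ndarray) -> np.ndarray:
        """Linear predictor at the observed cells for posterior draws."""
        comp = self._draw_components(x_draws, th_draws)
        eta = comp["intercept"][:, self.ri] + comp["slope"][:, self.ri] * self.t
        if self.subgroup_col:
            eta = eta + comp["gamma"][:, self.si]
            eta = eta + (comp["delta"][:, self.si] + comp["h"][:, self.ri, self.si]) * self.t
        return eta


class CoverageTrendResults:
    """Posterior draws, diagnostics and summaries of one fitted model."""

    def __init__(self, model, theta_hat, x_draws, th_draws, surface, diagnostics):
        self.model = model
        self.theta_hat = theta_hat
        self.x_draws = x_draws
        self.th_draws = th_draws
        self.surface: PosteriorSurface = surface
        self.diagnostics = diagnostics

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    # -- posterior summaries ------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Coverage mean / median / 95% CrI per modelled cell."""
        return self.surface.summary_frame()

    def hyper_summary(self) -> pd.DataFrame:
        """Posterior summary of hyperparameters on their natural scale."""
        rows = []
        for j, name in enumerate(self.model.hyper_names):
            d = self.th_draws[:, j]
            nat = expit(d) if name == "th_phi" else np.exp(d)
            label = "phi" if name == "th_phi" else name.replace("th_s", "sigma_")
            rows.append(
                {
                    "param": label,
                    "mean": nat.mean(),
                    "q025": np.quantile(nat, 0.025),
                    "q975": np.quantile(nat, 0.975),
                    "mode": float(expit(self.theta_hat[j]) if name == "th_phi"
                                  else np.exp(self.theta_hat[j])),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def region_slopes(self) -> pd.DataFrame:
        """Posterior summary of total region trend slopes (logit / year)."""
        comp = self.model._draw_components(self.x_draws, self.th_draws)
        s = comp["slope"]
        return pd.DataFrame(
            {
                "mean": s.mean(axis=0),
                "sd": s.std(axis=0, ddof=1),
                "q025": np.quantile(s, 0.025, axis=0),
                "q975": np.quantile(s, 0.975, axis=0),
            },
            index=pd.Index(self.model.regions, name="region"),
        )

    # -- fit criteria --------------------------------------------------------
    def pointwise_loglik(self) -> np.ndarray:
        """(draws, cells) pointwise log-likelihood at the observed cells."""
        eta = self.model.cell_linpred(self.x_draws, self.th_draws)
        if self.spec.likelihood == "binomial":
            return binom_dist.logpmf(self.model.y, self.model.m, expit(eta))
        return norm_dist.logpdf(self.model.z, loc=eta, scale=self.model.se)

    def waic(self):
        from .evaluation import waic

        return waic(self.pointwise_loglik())

    def dic(self):
        from .evaluation import dic

        ll = self.pointwise_loglik()
        dev = -2.0 * ll.sum(axis=1)
        eta_mean = self.model.cell_linpred(self.x_draws, self.th_draws).mean(axis=0)
        if self.spec.likelihood == "binomial":
            dev_at_mean = -2.0 * binom_dist.logpmf(
                self.model.y, self.model.m, expit(eta_mean)
            ).sum()
        else:
            dev_at_mean = -2.0 * norm_dist.logpdf(
                self.model.z, loc=eta_mean, scale=self.model.se
            ).sum()
        return dic(dev, float(dev_at_mean))

    def predict_cells(self) -> pd.DataFrame:
        """Posterior-mean coverage at the observed cells."""
        p = expit(self.model.cell_linpred(self.x_draws, self.th_draws)).mean(axis=0)
        out = self.model.data.copy()
        out["p_pred"] = p
        return out

    # -- downstream ----------------------------------------------------------
    def project(self, horizon_year: int) -> PosteriorSurface:
        from .trajectory import project

        return project(self.surface, horizon_year)

    def exceedance(self, threshold: float, year: int, horizon: int | None = None):
        from .trajectory import exceedance_probability, project

        surf = self.surface
        if year > int(self.surface.years.max()):
            surf = project(surf, horizon or year)
        return exceedance_probability(surf, threshold, year)

    def plot_trend(self, regions=None, ax=None):
        """Posterior mean and 95% CrI coverage trends for chosen regions."""
        import matplotlib.pyplot as plt

        surf = self.surface
        regions = regions or surf.regions[:4]
        if ax is None:
            _, ax = plt.subplots()
        years = surf.years
        for r in regions:
            da = surf.draws.sel(region=r)
            if surf.stratified:
                da = da.mean("subgroup")
            ax.plot(years, da.mean("draw"), label=str(r))
            ax.fill_between(
                years,
                da.quantile(0.025, dim="draw"),
                da.quantile(0.975, dim="draw"),
                alpha=0.2,
            )
        ax.set_xlabel("year")
        ax.set_ylabel("coverage")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8)
        return ax
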