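"""Model comparison and validation: WAIC, DIC, temporal hold-out, consistency.

Mirrors the validation design of multi-survey coverage modelling: fit
on early years, hold out the final years, and score with the absolute
difference (AD) and mean error (ME) between design-based observed
coverage and posterior-mean predictions, in percentage points.  A
positive out-of-sample ME means the model overpredicts — overestimates
recent progress.  The full-immunization surface is also checked against
its component vaccines, since the indicators are modelled independently
and full coverage should not exceed any component.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .graphs import RegionGraph
from .model import CoverageTrendModel, ModelSpec

__all__ = [
    "waic",
    "dic",
    "holdout_validate",
    "ValidationReport",
    "consistency_check",
    "compare_models",
    "select_model",
]


def waic(pointwise_loglik: np.ndarray, draw_weights: np.ndarray | None = None):
    """Watanabe–Akaike information criterion from pointwise log-likelihoods.

    ``pointwise_loglik`` is (draws, observations).  Returns
    ``(waic, p_waic, lppd)`` with ``lppd = sum_i log mean_d exp(ll)``,
    ``p_waic = sum_i var_d(ll)`` and ``waic = -2 (lppd - p_waic)``.

    ``draw_weights`` supports deterministic posterior representations
    (e.g. quadrature nodes): posterior means and variances then use the
    normalized weights instead of equal draw mass (and the variance is
    the population form rather than the ddof-1 sampling form).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 1:
        raise ValueError("need a (draws >= 2, observations >= 1) array")
    bad = ~np.isfinite(ll)
    if bad.any():
        obs = sorted(set(np.where(bad)[1].tolist()))
        raise ValueError(f"non-finite log-likelihood at observations {obs[:10]}")
    d = ll.shape[0]
    if draw_weights is None:
        lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(d)))
        p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    else:
        w = np.asarray(draw_weights, dtype=float)
        if w.shape != (d,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("draw_weights must be non-negative with shape (draws,)")
        w = w / w.sum()
        lppd = float(np.sum(logsumexp(ll, axis=0, b=w[:, None])))
        mean = w @ ll
        p_waic = float(np.sum(w @ (ll - mean) ** 2))
    return -2.0 * (lppd - p_waic), p_waic, lppd


def dic(deviance_draws: np.ndarray, deviance_at_posterior_mean: float):
    """Deviance information criterion.

    ``p_D = mean(deviance) - deviance_at_mean``;
    ``DIC = deviance_at_mean + 2 p_D``.
    """
    dev = np.asarray(deviance_draws, dtype=float)
    if dev.size == 0:
        raise ValueError("deviance draws must be non-empty")
    p_d = float(dev.mean() - deviance_at_posterior_mean)
    return deviance_at_posterior_mean + 2.0 * p_d, p_d


@dataclass
class ValidationReport:
    """AD/ME (percentage points) in-sample, held-out and full-period."""

    variant: str
    indicator: str
    split_year: int
    ad: dict = field(default_factory=dict)       # {"in": .., "out": .., "full": ..}
    me: dict = field(default_factory=dict)
    dic: float = np.nan
    p_d: float = np.nan
    waic: float = np.nan
    p_waic: float = np.nan
    runtime_s: float = np.nan
    n_cells: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "variant": self.variant,
            "indicator": self.indicator,
            "split_year": self.split_year,
            "dic": self.dic,
            "waic": self.waic,
            "ad_in": self.ad.get("in"),
            "ad_out": self.ad.get("out"),
            "ad_full": self.ad.get("full"),
            "me_in": self.me.get("in"),
            "me_out": self.me.get("out"),
            "me_full": self.me.get("full"),
            "runtime_s": self.runtime_s,
        }


def _ad_me(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    diff = (predicted - observed) * 100.0
    return float(np.mean(np.abs(diff))), float(np.mean(diff))


def holdout_validate(
    cells: pd.DataFrame,
    graph: RegionGraph,
    spec: ModelSpec,
    split_year: int,
    indicator: str = "",
    seed: int = 0,
    draws: int = 500,
    subgroup_col: str | None = None,
) -> ValidationReport:
    """Fit on years <= ``split_year`` and score against all observed cells.

    AD and ME are in percentage points; positive out-of-sample ME means
    the projected trend overshoots the held-out observations.
    """
    usable = cells.loc[(cells["n"] > 0) & cells["p_hat"].notna()]
    train = usable[usable["year"] <= split_year]
    test = usable[usable["year"] > split_year]
    if test.empty:
        raise ValueError(f"no held-out cells after split year {split_year}")
    if train.empty:
        raise ValueError(f"no training cells at or before split year {split_year}")
    t0 = time.perf_counter()
    model = CoverageTrendModel(train, graph, spec, subgroup_col=subgroup_col)
    res = model.fit(seed=seed, draws=draws)
    runtime = time.perf_counter() - t0
    surf = res.project(int(usable["year"].max()))
    pm = surf.draws.mean("draw")

    def predict(frame: pd.DataFrame) -> np.ndarray:
        if subgroup_col:
            return np.array(
                [
                    float(pm.sel(region=r, year=y, subgroup=s))
                    for r, y, s in zip(frame["region"], frame["year"], frame[subgroup_col])
                ]
            )
        return np.array(
            [float(pm.sel(region=r, year=y)) for r, y in zip(frame["region"], frame["year"])]
        )

    report = ValidationReport(
        variant=spec.variant,
        indicator=indicator,
        split_year=split_year,
        runtime_s=runtime,
    )
    for name, frame in (("in", train), ("out", test), ("full", usable)):
        obs = frame["p_hat"].to_numpy(dtype=float)
        pred = predict(frame)
        report.ad[name], report.me[name] = _ad_me(obs, pred)
        report.n_cells[name] = len(frame)
    report.waic, report.p_waic, _ = res.waic()
    report.dic, report.p_d = res.dic()
    return report


def consistency_check(
    surface_full,
    surfaces_components: dict,
    tolerance: float = 0.005,
):
    """Flag cells where full-immunization coverage exceeds a component.

    Compares posterior means on the shared (region, year[, subgroup])
    index; returns ``(violation_fraction, flagged)`` where ``flagged``
    lists the offending cells with their excess over the smallest
    component.  ``tolerance`` is on the probability scale (0.005 = 0.5
    percentage points).
    """
    def as_frame(obj, name):
        if isinstance(obj, pd.DataFrame):
            return obj
        if hasattr(obj, "draws"):  # PosteriorSurface
            obj = obj.mean()
        return obj.to_dataframe(name=name).reset_index()  # xarray DataArray

    full_df = as_frame(surface_full, "full")
    keys = [c for c in full_df.columns if c != "full"]
    merged = full_df.copy()
    for k, cm in surfaces_components.items():
        cdf = as_frame(cm, k)
        if sorted(c for c in cdf.columns if c != k) != sorted(keys):
            raise ValueError(f"component {k!r} index misaligned with full surface")
        merged = merged.merge(cdf, on=keys, how="inner", validate="one_to_one")
    if len(merged) != len(full_df):
        raise ValueError("component surfaces missing cells of the full surface")
    comp_min = merged[list(surfaces_components)].min(axis=1)
    excess = merged["full"] - comp_min
    viol = excess > tolerance
    flagged = merged.loc[viol, keys].copy()
    flagged["excess"] = excess[viol]
    return float(viol.mean()), flagged.reset_index(drop=True)


def compare_models(
    cells: pd.DataFrame,
    graph: RegionGraph,
    variants,
    split_year: int,
    indicator: str = "",
    seed: int = 0,
    draws: int = 500,
    subgroup_col: str | None = None,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Hold-out comparison table across model variants."""
    rows = []
    for variant in variants:
        spec = ModelSpec(variant=variant, **(spec_kwargs or {}))
        rep = holdout_validate(
            cells, graph, spec, split_year,
            indicator=indicator, seed=seed, draws=draws, subgroup_col=subgroup_col,
        )
        rows.append(rep.to_row())
    return pd.DataFrame(rows)


def select_model(comparison: pd.DataFrame) -> str:
    """Rank-sum selection over DIC, WAIC, out-of-sample AD and |ME|.

    Each criterion is ranked across variants (smaller better) and the
    ranks summed; ties break toward the simpler variant (earlier in the
    canonical variant order).
    """
    from .model import VARIANTS

    df = comparison.copy()
    df["abs_me_out"] = df["me_out"].abs()
    crit = ["dic", "waic", "ad_out", "abs_me_out"]
    ranks = sum(df[c].rank(method="average") for c in crit)
    df["rank_sum"] = ranks
    df["simplicity"] = df["variant"].map({v: i for i, v in enumerate(VARIANTS)})
    best = df.sort_values(["rank_sum", "simplicity"]).iloc[0]
    return str(best["variant"])
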