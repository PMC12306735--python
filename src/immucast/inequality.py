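"""Socioeconomic inequality indices: SII, RII, their time changes, quadrants.

The slope index of inequality (SII) and relative index of inequality
(RII) summarise the coverage gradient across ranked socioeconomic
groups (wealth quintiles, education).  Each group is placed at its
ridit midpoint — the cumulative population share below it plus half its
own share — and coverage is regressed on that rank by weighted least
squares with the shares as weights.  SII is 100 x (fitted value at rank
1 minus at rank 0), in percentage points; RII is the ratio of the same
two fitted values.  Both are computed per posterior draw.

Because SII can be negative its time change is summarised by the
absolute annual change (AAC = (SII_n - SII_0)/N) rather than AARC; RII
is strictly positive and uses the AARC.  The joint movement of the two
indices is classified into four groups: (1) both declining, (2)
absolute progress with persistent relative inequality, (3) relative
progress with persistent absolute inequality, (4) both worsening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface import PosteriorSurface
from .trajectory import aarc

__all__ = [
    "ridit_midpoints",
    "sii_rii",
    "aac",
    "classify_quadrant",
    "QuadrantLabel",
    "inequality_series",
    "InequalitySeries",
]

_RII_CLIP = (1e-6, 1.0)


def ridit_midpoints(group_shares) -> np.ndarray:
    """Relative ranks of ordered groups: cumulative share below + half own share.

    Groups must be ordered most disadvantaged to most advantaged and the
    shares must sum to one.
    """
    s = np.asarray(group_shares, dtype=float)
    if np.any(s <= 0):
        raise ValueError("group shares must be positive")
    if abs(s.sum() - 1.0) > 1e-6:
        raise ValueError(f"group shares must sum to 1, got {s.sum()}")
    below = np.concatenate(([0.0], np.cumsum(s)[:-1]))
    return below + s / 2.0


def sii_rii(
    subgroup_coverage,
    group_shares,
    method: str = "regression",
):
    """Per-draw SII (percentage points) and RII (ratio) across groups.

    ``subgroup_coverage`` has groups on the last axis (ordered
    disadvantaged to advantaged), with any leading draw axes.  The
    ``regression`` method fits a weighted least-squares line of coverage
    on ridit midpoints (weights = shares); the ``gap`` method is the
    simple advantaged-minus-disadvantaged cross-check.  Fitted values at
    ranks 0 and 1 are clipped to (1e-6, 1] before taking the ratio.
    """
    cov = np.asarray(subgroup_coverage, dtype=float)
    if cov.shape[-1] < 2:
        raise ValueError("need >= 2 groups for inequality indices")
    shares = np.asarray(group_shares, dtype=float)
    if shares.shape[0] != cov.shape[-1]:
        raise ValueError("shares and coverage group axes differ in length")
    ranks = ridit_midpoints(shares)
    if method == "gap":
        fit0, fit1 = cov[..., 0], cov[..., -1]
    elif method == "regression":
        w = shares
        xbar = np.sum(w * ranks)
        sxx = np.sum(w * (ranks - xbar) ** 2)
        ybar = np.sum(w * cov, axis=-1)
        slope = np.sum(w * (ranks - xbar) * cov, axis=-1) / sxx
        icpt = ybar - slope * xbar
        fit0, fit1 = icpt, icpt + slope
    else:
        raise ValueError(f"unknown method {method!r}")
    sii = 100.0 * (fit1 - fit0)
    lo, hi = _RII_CLIP
    rii = np.clip(fit1, lo, hi) / np.clip(fit0, lo, hi)
    return sii, rii


def aac(x0, xn, N: int):
    """Absolute annual change ``(xn - x0) / N`` (units of x per year)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return (np.asarray(xn, dtype=float) - np.asarray(x0, dtype=float)) / N


@dataclass(frozen=True)
class QuadrantLabel:
    group: int                # 1..4
    significant: bool
    description: str

    _DESCRIPTIONS = (
        "progress in both absolute and relative inequality",
        "absolute progress, persistent relative inequality",
        "relative progress, persistent absolute inequality",
        "worsening absolute and relative inequality",
    )


def classify_quadrant(
    delta_sii: tuple[float, float, float],
    delta_rii: tuple[float, float, float],
) -> QuadrantLabel:
    """Classify joint SII/RII change into the four-group scheme.

    Each argument is ``(point, lower, upper)`` of the change summary
    (AAC of SII; AARC of RII).  "Declining" means the CrI upper bound is
    below zero, "worsening" that the lower bound is above zero; when
    neither index moves significantly, the point-estimate signs decide
    and the label is flagged non-significant.
    """
    sp, slo, shi = delta_sii
    rp, rlo, rhi = delta_rii
    sii_dec, rii_dec = shi < 0, rhi < 0
    sii_wor, rii_wor = slo > 0, rlo > 0
    significant = True
    if sii_dec and rii_dec:
        group = 1
    elif sii_dec:
        group = 2
    elif rii_dec:
        group = 3
    elif sii_wor and rii_wor:
        group = 4
    else:
        significant = False
        if sp < 0 and rp < 0:
            group = 1
        elif sp < 0:
            group = 2
        elif rp < 0:
            group = 3
        else:
            group = 4
    return QuadrantLabel(group, significant, QuadrantLabel._DESCRIPTIONS[group - 1])


@dataclass
class InequalitySeries:
    """Per-year SII/RII draws with change summaries and quadrant label."""

    dimension: str
    years: np.ndarray
    sii_draws: np.ndarray        # (draw, year)
    rii_draws: np.ndarray
    aac_draws: np.ndarray        # (draw,)
    aarc_draws: np.ndarray
    quadrant: QuadrantLabel

    def summary(self) -> pd.DataFrame:
        def q(d, f):
            return np.apply_along_axis(f, 0, d)

        rows = pd.DataFrame(
            {
                "year": self.years,
                "sii_mean": self.sii_draws.mean(axis=0),
                "sii_lo": np.quantile(self.sii_draws, 0.025, axis=0),
                "sii_hi": np.quantile(self.sii_draws, 0.975, axis=0),
                "rii_mean": self.rii_draws.mean(axis=0),
                "rii_lo": np.quantile(self.rii_draws, 0.025, axis=0),
                "rii_hi": np.quantile(self.rii_draws, 0.975, axis=0),
            }
        )
        rows["dimension"] = self.dimension
        return rows

    def change_summary(self) -> dict:
        return {
            "dimension": self.dimension,
            "aac_sii": float(self.aac_draws.mean()),
            "aac_sii_lo": float(np.quantile(self.aac_draws, 0.025)),
            "aac_sii_hi": float(np.quantile(self.aac_draws, 0.975)),
            "aarc_rii": float(self.aarc_draws.mean()),
            "aarc_rii_lo": float(np.quantile(self.aarc_draws, 0.025)),
            "aarc_rii_hi": float(np.quantile(self.aarc_draws, 0.975)),
            "quadrant": self.quadrant.group,
            "significant": self.quadrant.significant,
        }


def inequality_series(
    surface: PosteriorSurface,
    group_shares,
    dimension: str = "wealth",
    period: tuple[int, int] | None = None,
    region: str | None = None,
    region_weights: pd.Series | None = None,
    method: str = "regression",
) -> InequalitySeries:
    """SII/RII time series from a stratified posterior surface.

    The surface's ``subgroup`` axis must be ordered disadvantaged to
    advantaged.  With ``region=None`` the national (region-aggregated)
    surface is used.
    """
    if not surface.stratified:
        raise ValueError("inequality indices need a subgroup-stratified surface")
    if region is None:
        from .trajectory import national_aggregate

        surf = national_aggregate(surface, region_weights)
        if len(surf.regions) == 1:
            da = surf.draws.isel(region=0)
        else:
            da = surf.draws.mean("region")
    else:
        da = surface.draws.sel(region=region)
    da = da.transpose("draw", "year", "subgroup")
    years = surface.years
    sii, rii = sii_rii(da.values, group_shares, method=method)  # (draw, year)
    y0, y1 = period or (int(years.min()), int(years.max()))
    i0, i1 = int(np.where(years == y0)[0][0]), int(np.where(years == y1)[0][0])
    n = y1 - y0
    aac_draws = aac(sii[:, i0], sii[:, i1], n)
    aarc_draws = aarc(rii[:, i0], rii[:, i1], n)
    quad = classify_quadrant(
        (
            float(aac_draws.mean()),
            float(np.quantile(aac_draws, 0.025)),
            float(np.quantile(aac_draws, 0.975)),
        ),
        (
            float(aarc_draws.mean()),
            float(np.quantile(aarc_draws, 0.025)),
            float(np.quantile(aarc_draws, 0.975)),
        ),
    )
    return InequalitySeries(
        dimension=dimension,
        years=years,
        sii_draws=sii,
        rii_draws=rii,
        aac_draws=aac_draws,
        aarc_draws=aarc_draws,
        quadrant=quad,
    )
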