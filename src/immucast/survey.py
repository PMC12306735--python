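"""Design-adjusted coverage estimation from child-level survey records.

Turns child records into per-cell coverage estimates — one cell per
(country, region, year, indicator[, subgroup]) — using sampling weights,
with the Kish effective sample size standing in for a full design-based
variance estimator.  Also derives the full-immunization indicator and
PCA wealth quintiles from household assets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.decomposition import PCA

__all__ = [
    "derive_full_immunization",
    "compute_wealth_quintiles",
    "estimate_coverage",
    "kish_n_eff",
    "INDICATORS",
    "AGE_WINDOWS",
]

logger = logging.getLogger(__name__)

INDICATORS = ("bcg", "polio3", "dpt3", "mcv1", "full")
#: age-window presets (months, inclusive): primary is 12-23
AGE_WINDOWS = {
    "12-23": (12, 23),
    "12-35": (12, 35),
    "24-35": (24, 35),
    "24-59": (24, 59),
    "12-59": (12, 59),
}
_VACCINE_COLS = ["bcg", "polio3", "dpt3", "mcv1"]


def derive_full_immunization(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``full`` column: 1 iff all four vaccine indicators equal 1.

    Records with any missing vaccine indicator are dropped (their count
    is logged), matching the exclusion of children with incomplete
    vaccination information.
    """
    missing = records[_VACCINE_COLS].isna().any(axis=1)
    if missing.any():
        logger.warning("excluding %d records with missing vaccine indicators", int(missing.sum()))
    out = records.loc[~missing].copy()
    bad = ~out[_VACCINE_COLS].isin([0, 1]).all(axis=1)
    if bad.any():
        raise ValueError("vaccine indicators must be binary 0/1")
    out["full"] = out[_VACCINE_COLS].all(axis=1).astype(int)
    return out


def compute_wealth_quintiles(
    assets: pd.DataFrame,
    asset_cols: list[str] | None = None,
    weight_col: str = "weight",
) -> pd.Series:
    """Household wealth quintiles from the first principal component.

    The asset matrix is standardized, scored on its first principal
    component (sign fixed so the score rises with total asset count) and
    cut into five weighted quintiles, each holding ~20% of the weighted
    households.  Returns quintiles 1 (poorest) .. 5 (richest) indexed
    like ``assets``.
    """
    if asset_cols is None:
        asset_cols = [c for c in assets.columns if c.startswith("asset_")]
    X = assets[asset_cols].to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 households and >= 1 asset column")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all asset columns are constant")
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    score = PCA(n_components=1).fit_transform(Xs)[:, 0]
    if np.corrcoef(score, X.sum(axis=1))[0, 1] < 0:
        score = -score
    w = assets[weight_col].to_numpy(dtype=float) if weight_col in assets else np.ones(len(assets))
    # tie-aware weighted mid-ranks: households with equal scores share a rank
    key = np.round(score, 9)
    order = np.argsort(key, kind="stable")
    sorted_key, sorted_w = key[order], w[order]
    uniq, start = np.unique(sorted_key, return_index=True)
    group_w = np.add.reduceat(sorted_w, start)
    cum = np.cumsum(group_w)
    frac = (cum - 0.5 * group_w) / cum[-1]
    q_uniq = 1 + np.minimum((frac * 5).astype(int), 4)
    quintile = q_uniq[np.searchsorted(uniq, key)]
    return pd.Series(quintile, index=assets.index, name="wealth_quintile")


def kish_n_eff(weights: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def estimate_coverage(
    records: pd.DataFrame,
    indicator: str,
    group_cols: list[str] | None = None,
    subgroup_col: str | None = None,
    age_window: tuple[int, int] = (12, 23),
    min_cell_size: int = 10,
) -> pd.DataFrame:
    """Design-weighted coverage per cell with Kish effective sample size.

    Returns one row per (group keys [+ subgroup]) cell with columns
    ``p_hat`` (weighted proportion), ``n`` (raw count), ``n_eff``
    (Kish), ``logit_se`` (binomial SE of logit p_hat at n_eff, after the
    1/(2 n_eff) continuity correction), and a ``sparse`` flag for cells
    below ``min_cell_size``.  Cells that exist in the key product of the
    observed data but contain no in-window children are emitted with
    ``n = 0`` and missing ``p_hat`` rather than silently dropped.
    """
    if indicator not in records.columns:
        raise ValueError(f"indicator column {indicator!r} not in records")
    group_cols = group_cols or ["country", "region", "year"]
    missing = [c for c in group_cols if c not in records.columns]
    if missing:
        raise ValueError(f"grouping columns missing from records: {missing}")
    lo, hi = age_window
    if hi < lo:
        raise ValueError("age window is empty")
    keys = group_cols + ([subgroup_col] if subgroup_col else [])
    inwin = records[(records["age_months"] >= lo) & (records["age_months"] <= hi)]
    rows = []
    for key, grp in inwin.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        w = grp["weight"].to_numpy(dtype=float)
        y = grp[indicator].to_numpy(dtype=float)
        n = len(grp)
        n_eff = kish_n_eff(w)
        p_hat = float(np.sum(w * y) / np.sum(w))
        # continuity handling keeps logit-scale quantities finite at 0/1
        p_adj = np.clip(p_hat, 1.0 / (2 * n_eff), 1.0 - 1.0 / (2 * n_eff))
        logit_se = float(1.0 / np.sqrt(n_eff * p_adj * (1 - p_adj)))
        rows.append(
            dict(zip(keys, key))
            | {
                "indicator": indicator,
                "p_hat": p_hat,
                "p_adj": p_adj,
                "logit_p": float(logit(p_adj)),
                "logit_se": logit_se,
                "n": n,
                "n_eff": n_eff,
                "sparse": n < min_cell_size,
            }
        )
    cells = pd.DataFrame(rows)
    if cells.empty:
        return cells
    # emit empty cells for the observed key product (per country-year survey)
    full_index = pd.MultiIndex.from_product(
        [sorted(inwin[c].unique()) for c in keys], names=keys
    )
    have = pd.MultiIndex.from_frame(cells[keys])
    absent = []
    region_country = records.drop_duplicates("region").set_index("region")["country"] \
        if {"region", "country"} <= set(records.columns) else None
    surveyed = set(map(tuple, records[["country", "year"]].drop_duplicates().to_numpy())) \
        if {"country", "year"} <= set(records.columns) else None
    for key in full_index.difference(have):
        row = dict(zip(keys, key))
        if region_country is not None and "region" in row:
            if region_country.get(row["region"]) != row.get("country"):
                continue  # region belongs to another country, not a real cell
        if surveyed is not None and (row.get("country"), row.get("year")) not in surveyed:
            continue  # country not surveyed that year
        absent.append(
            row
            | {
                "indicator": indicator,
                "p_hat": np.nan,
                "p_adj": np.nan,
                "logit_p": np.nan,
                "logit_se": np.nan,
                "n": 0,
                "n_eff": 0.0,
                "sparse": True,
            }
        )
    if absent:
        logger.info("emitting %d empty cells for indicator %s", len(absent), indicator)
        cells = pd.concat([cells, pd.DataFrame(absent)], ignore_index=True)
    return cells.sort_values(keys).reset_index(drop=True)


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
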