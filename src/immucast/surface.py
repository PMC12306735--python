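"""Posterior coverage surfaces: draws indexed by draw x region x year (x subgroup)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["PosteriorSurface"]


@dataclass
class PosteriorSurface:
    """Posterior draws of coverage on the probability scale.

    ``draws`` is an :class:`xarray.DataArray` with dims
    ``(draw, region, year)`` or ``(draw, region, year, subgroup)``,
    every value in [0, 1].  ``region_country`` maps each region to its
    country (countries map to themselves in national surfaces).
    """

    draws: xr.DataArray
    region_country: pd.Series
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = self.draws.dims
        if dims[:3] != ("draw", "region", "year"):
            raise ValueError(f"expected dims (draw, region, year[, subgroup]), got {dims}")
        vals = self.draws.values
        if not np.all((vals >= 0) & (vals <= 1)):
            raise ValueError("coverage draws must lie in [0, 1]")
        missing = set(map(str, self.draws.coords["region"].values)) - set(
            map(str, self.region_country.index)
        )
        if missing:
            raise ValueError(f"regions without country mapping: {sorted(missing)}")

    # -- views -------------------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.draws.sizes["draw"]

    @property
    def years(self) -> np.ndarray:
        return self.draws.coords["year"].values

    @property
    def regions(self) -> list[str]:
        return [str(r) for r in self.draws.coords["region"].values]

    @property
    def stratified(self) -> bool:
        return "subgroup" in self.draws.dims

    def sel_year(self, year: int) -> xr.DataArray:
        if year not in set(int(y) for y in self.years):
            raise ValueError(f"year {year} not in surface years {self.years.min()}..{self.years.max()}")
        return self.draws.sel(year=year)

    def mean(self) -> xr.DataArray:
        return self.draws.mean("draw")

    def quantile(self, q) -> xr.DataArray:
        return self.draws.quantile(q, dim="draw")

    def with_draws(self, draws: xr.DataArray) -> "PosteriorSurface":
        return replace(self, draws=draws)

    def to_zarr(self, path) -> None:
        """Persist the draw array in a chunked container (zarr)."""
        ds = self.draws.to_dataset(name="coverage")
        ds.attrs["provenance"] = str(self.provenance)
        ds.to_zarr(path, mode="w")

    def summary_frame(self) -> pd.DataFrame:
        """Flat table of mean / median / 2.5% / 97.5% per cell."""
        stats = xr.Dataset(
            {
                "mean": self.draws.mean("draw"),
                "median": self.draws.median("draw"),
                "q025": self.draws.quantile(0.025, dim="draw").drop_vars("quantile"),
                "q975": self.draws.quantile(0.975, dim="draw").drop_vars("quantile"),
            }
        )
        out = stats.to_dataframe().reset_index()
        out["country"] = out["region"].map(self.region_country)
        return out
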