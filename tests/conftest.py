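import numpy as np
import pandas as pd
import pytest
import xarray as xr

from immucast import (
    CoverageTrendModel,
    ModelSpec,
    SurveyDesign,
    generate_region_graph,
    simulate_surveys,
    simulate_truth,
)
from immucast.surface import PosteriorSurface
from immucast.survey import derive_full_immunization, estimate_coverage


def make_surface(values, regions=None, years=None, region_country=None, subgroups=None):
    """PosteriorSurface from a raw draws array (helper for trajectory tests)."""
    values = np.asarray(values, dtype=float)
    if subgroups is not None:
        dims = ("draw", "region", "year", "subgroup")
    else:
        dims = ("draw", "region", "year")
    regions = regions or [f"R{i}" for i in range(values.shape[1])]
    years = years if years is not None else np.arange(2000, 2000 + values.shape[2])
    coords = {"draw": np.arange(values.shape[0]), "region": regions, "year": years}
    if subgroups is not None:
        coords["subgroup"] = subgroups
    rc = region_country if region_country is not None else pd.Series(
        {r: "C00" for r in regions}
    )
    return PosteriorSurface(
        draws=xr.DataArray(values, dims=dims, coords=coords), region_country=rc
    )


@pytest.fixture(scope="session")
def small_graph():
    return generate_region_graph(2, 4, seed=0)


@pytest.fixture(scope="session")
def small_truth(small_graph):
    return simulate_truth(small_graph, range(2000, 2020), seed=11)


@pytest.fixture(scope="session")
def small_children(small_truth, small_graph):
    design = SurveyDesign(
        survey_years={c: (2002, 2010, 2018) for c in small_graph.country_ids},
        clusters_per_stratum=5,
    )
    children, assets = simulate_surveys(small_truth, design, seed=12)
    return derive_full_immunization(children), assets


@pytest.fixture(scope="session")
def small_cells(small_children):
    children, _ = small_children
    return estimate_coverage(children, "dpt3")


@pytest.fixture(scope="session")
def fitted(small_cells, small_graph):
    model = CoverageTrendModel(small_cells, small_graph, ModelSpec("bym2_2"))
    return model.fit(seed=5, draws=800)
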