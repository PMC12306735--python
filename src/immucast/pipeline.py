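"""End-to-end pipeline: simulate -> prepare -> fit -> project -> inequality -> validate.

Configuration is a validated schema (YAML or dict); every stage writes
delimited-text tables plus a JSON run manifest (seed, config, data
hashes, package version), so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .graphs import generate_region_graph, write_edgelist
from .inequality import inequality_series
from .model import CoverageTrendModel, ModelSpec
from .survey import (
    AGE_WINDOWS,
    compute_wealth_quintiles,
    derive_full_immunization,
    estimate_coverage,
)
from .synthetic import (
    SurveyDesign,
    TruthParams,
    simulate_surveys,
    simulate_truth,
    write_children,
    write_truth,
)
from .trajectory import n_eff_region_weights, surface_aarc, target_assessment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class SyntheticConfig(BaseModel):
    n_countries: int = Field(2, ge=1)
    regions_per_country: int = Field(4, ge=1)
    cross_border: bool = False
    year_start: int = 2000
    year_end: int = 2019
    surveys_per_country: int = Field(3, ge=1)
    n_strata: int = Field(2, ge=1)
    clusters_per_stratum: int = Field(5, ge=1)
    children_per_cluster: int = Field(20, ge=1)
    weight_dispersion: float = Field(0.3, ge=0)
    truth: dict = Field(default_factory=dict)


class PrepConfig(BaseModel):
    indicators: list[str] = ["dpt3", "full"]
    age_window: str = "12-23"
    min_cell_size: int = 10


class FitConfig(BaseModel):
    variant: str = "bym2_2"
    likelihood: str = "binomial"
    draws: int = Field(1000, ge=100)
    U_sigma: float = 1.0
    alpha_sigma: float = 0.01
    U_phi: float = 0.5
    alpha_phi: float = 2.0 / 3.0


class TrajectoryConfig(BaseModel):
    horizon_year: int = 2030
    decision_cutoff: float = Field(0.5, gt=0, lt=1)
    period: str = "full"            # or "recent" (last decade of data)


class InequalityConfig(BaseModel):
    dimensions: list[str] = ["wealth"]
    indicator: str = "full"


class ValidateConfig(BaseModel):
    enabled: bool = False
    split_year: int = 2016
    variants: list[str] = ["besag_1", "bym2_2"]
    indicator: str = "dpt3"


class PipelineConfig(BaseModel):
    seed: int = 0
    synthetic: SyntheticConfig = SyntheticConfig()
    prep: PrepConfig = PrepConfig()
    fit: FitConfig = FitConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    inequality: InequalityConfig = InequalityConfig()
    validate_stage: ValidateConfig = Field(default_factory=ValidateConfig, alias="validate")

    model_config = {"populate_by_name": True}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"invalid config field {loc!r}: {first['msg']}") from exc


def _survey_years(cfg: SyntheticConfig, seed: int) -> dict[str, tuple[int, ...]]:
    """Roughly evenly spaced survey years per country, jittered DHS-style."""
    rng = np.random.default_rng(seed + 1)
    out = {}
    span = cfg.year_end - cfg.year_start
    for ci in range(cfg.n_countries):
        base = np.linspace(cfg.year_start, cfg.year_end, cfg.surveys_per_country)
        jitter = rng.integers(-1, 2, size=cfg.surveys_per_country) if cfg.surveys_per_country > 1 else [0]
        years = sorted({int(np.clip(round(b) + j, cfg.year_start, cfg.year_end))
                        for b, j in zip(base, jitter)})
        out[f"C{ci:02d}"] = tuple(years) if span else (cfg.year_start,)
    return out


def _sha(df: pd.DataFrame) -> str:
    return hashlib.sha256(pd.util.hash_pandas_object(df).values.tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | dict, outdir, seed: int | None = None) -> dict:
    """Run every stage and write the artifact bundle under ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``).
    Stage failures re-raise as :class:`PipelineError` naming the stage.
    """
    if isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    manifest: dict = {"seed": seed, "version": __version__,
                      "config": config.model_dump(by_alias=True), "outputs": {}, "stages": {}}

    def out(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha(frame)
        return path

    # ---- simulate ---------------------------------------------------------
    try:
        scfg = config.synthetic
        graph = generate_region_graph(scfg.n_countries, scfg.regions_per_country,
                                      seed=seed, cross_border=scfg.cross_border)
        years = range(scfg.year_start, scfg.year_end + 1)
        truth = simulate_truth(graph, years, TruthParams(**scfg.truth), seed=seed)
        design = SurveyDesign(
            survey_years=_survey_years(scfg, seed),
            n_strata=scfg.n_strata,
            clusters_per_stratum=scfg.clusters_per_stratum,
            children_per_cluster=scfg.children_per_cluster,
            weight_dispersion=scfg.weight_dispersion,
        )
        children, assets = simulate_surveys(truth, design, seed=seed + 2)
        write_edgelist(graph, outdir / "graph.txt")
        write_children(children, outdir / "children.tsv")
        write_truth(truth, outdir / "truth.tsv")
        manifest["outputs"]["children.tsv"] = _sha(children)
        manifest["stages"]["simulate"] = {"n_children": len(children),
                                          "n_regions": graph.n_regions}
        logger.info("simulated %d children in %d regions", len(children), graph.n_regions)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    # ---- prepare ----------------------------------------------------------
    try:
        pcfg = config.prep
        children = derive_full_immunization(children)
        # recompute wealth quintiles from assets via PCA, as the real pipeline would
        quintiles = compute_wealth_quintiles(assets)
        quintiles.index = assets["household_id"]
        children = children.drop(columns="wealth_quintile").merge(
            quintiles.rename("wealth_quintile"),
            left_on="household_id", right_index=True, how="left",
        )
        window = AGE_WINDOWS[pcfg.age_window]
        cells: dict[str, pd.DataFrame] = {}
        for ind in pcfg.indicators:
            cells[ind] = estimate_coverage(children, ind, age_window=window,
                                           min_cell_size=pcfg.min_cell_size)
            out(f"cells_{ind}.tsv", cells[ind])
        strat_cells: dict[str, pd.DataFrame] = {}
        subgroup_cols = {"wealth": "wealth_quintile", "education": "education_group"}
        for dim in config.inequality.dimensions:
            col = subgroup_cols[dim]
            strat_cells[dim] = estimate_coverage(
                children, config.inequality.indicator, subgroup_col=col,
                age_window=window, min_cell_size=pcfg.min_cell_size,
            )
            out(f"cells_{config.inequality.indicator}_by_{dim}.tsv", strat_cells[dim])
        manifest["stages"]["prepare"] = {k: len(v) for k, v in cells.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("prepare", exc) from exc

    # ---- fit + trajectory --------------------------------------------------
    results = {}
    try:
        fcfg, tcfg = config.fit, config.trajectory
        horizon = tcfg.horizon_year
        for ind, cell_df in cells.items():
            use = cell_df
            if tcfg.period == "recent":
                cutoff = cell_df["year"].max() - 9
                use = cell_df[cell_df["year"] >= cutoff]
            spec = ModelSpec(variant=fcfg.variant, likelihood=fcfg.likelihood,
                             U_sigma=fcfg.U_sigma, alpha_sigma=fcfg.alpha_sigma,
                             U_phi=fcfg.U_phi, alpha_phi=fcfg.alpha_phi)
            res = CoverageTrendModel(use, graph, spec).fit(seed=seed, draws=fcfg.draws)
            results[ind] = res
            out(f"coverage_summary_{ind}.tsv", res.summary())
            weights = n_eff_region_weights(use)
            assess = target_assessment(res.surface, horizon,
                                       decision_cutoff=tcfg.decision_cutoff,
                                       region_weights=weights)
            out(f"targets_{ind}.tsv", assess)
            proj = res.project(horizon)
            y0 = int(use["year"].min())
            rates = surface_aarc(proj, y0, horizon)
            aarc_tab = pd.DataFrame({
                "region": proj.regions,
                "aarc_mean": rates.mean("draw").values,
                "aarc_lo": rates.quantile(0.025, dim="draw").values,
                "aarc_hi": rates.quantile(0.975, dim="draw").values,
            })
            aarc_tab["country"] = aarc_tab["region"].map(graph.region_country)
            out(f"aarc_{ind}.tsv", aarc_tab)
            manifest["stages"].setdefault("fit", {})[ind] = {
                "converged": results[ind].diagnostics.get("converged"),
                "rhat_max": results[ind].diagnostics.get("rhat_max"),
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", exc) from exc

    # ---- inequality --------------------------------------------------------
    try:
        icfg = config.inequality
        subgroup_cols = {"wealth": "wealth_quintile", "education": "education_group"}
        ineq_rows, series_rows = [], []
        for dim in icfg.dimensions:
            col = subgroup_cols[dim]
            spec = ModelSpec(variant=config.fit.variant, stratified=True)
            res = CoverageTrendModel(strat_cells[dim], graph, spec, subgroup_col=col)\
                .fit(seed=seed, draws=config.fit.draws)
            proj = res.project(config.trajectory.horizon_year)
            k = proj.draws.sizes["subgroup"]
            if dim == "wealth":
                shares = np.full(k, 1.0 / k)
            else:
                w = strat_cells[dim].groupby(col)["n_eff"].sum()
                shares = (w / w.sum()).reindex(sorted(w.index)).to_numpy()
            series = inequality_series(proj, shares, dimension=dim)
            ineq_rows.append(series.change_summary())
            series_rows.append(series.summary())
        out("inequality_changes.tsv", pd.DataFrame(ineq_rows))
        out("inequality_series.tsv", pd.concat(series_rows, ignore_index=True))
        manifest["stages"]["inequality"] = {"dimensions": icfg.dimensions}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inequality", exc) from exc

    # ---- validate ----------------------------------------------------------
    if config.validate_stage.enabled:
        try:
            from .evaluation import compare_models, select_model

            vcfg = config.validate_stage
            comp = compare_models(cells[vcfg.indicator], graph, vcfg.variants,
                                  vcfg.split_year, indicator=vcfg.indicator, seed=seed)
            out("validation.tsv", comp)
            manifest["stages"]["validate"] = {"selected": select_model(comp)}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("validate", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["results"] = results
    return manifest
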