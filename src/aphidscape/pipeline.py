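"""The end-to-end chain: simulate → landscape metrics → field metrics → fit.

Each stage is also callable on user-supplied files with the same schemas; the
chain here wires the synthetic study through the same code paths and writes
every intermediate table plus a run manifest with checksums.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import insects, io, landscape, weather
from .raster import read_legend_csv, read_raster, reclassify
from .regression import PipelineResult, run_pipeline
from .simulate import SimulationConfig, generate_study, write_study

ENV_COLUMNS = [
    "PLANDs",
    "PLANDwh",
    "PLANDc",
    "PLANDg",
    "PLANDwo",
    "PD",
    "SIDI",
    "maxTMAX",
    "sdTMAX",
    "meanPPT",
    "cvPPT",
]


def landscape_metrics_from_dir(
    rasters_dir: str | Path,
    legend_path: str | Path,
    sites_path: str | Path,
    *,
    radius: float = 5000.0,
    connectivity: int = 8,
    prox_radius: float = 1000.0,
    count_boundary: bool = True,
    reclassify_raw: bool = False,
) -> pd.DataFrame:
    """Compute the per-site-year landscape metric table from grid files named
    ``<site_id>_<year>.grid``."""
    legend = read_legend_csv(legend_path)
    sites = io.read_sites_csv(sites_path)
    rasters = {}
    for rec in sites.itertuples(index=False):
        path = Path(rasters_dir) / f"{rec.site_id}_{int(rec.year)}.grid"
        raster = read_raster(path)
        if reclassify_raw:
            raster = reclassify(raster, legend)
        rasters[(rec.site_id, int(rec.year))] = raster
    return landscape.compute_landscape_table(
        rasters,
        legend,
        sites,
        radius=radius,
        connectivity=connectivity,
        prox_radius=prox_radius,
        count_boundary=count_boundary,
    )


def sampling_windows(sampling: pd.DataFrame) -> pd.DataFrame:
    """Per site-year first/last sampling date derived from day-of-year."""
    rows = []
    for (site, year), grp in sampling.groupby(["site_id", "year"]):
        base = pd.Timestamp(year=int(year), month=1, day=1)
        rows.append(
            {
                "site_id": site,
                "year": int(year),
                "start": base + pd.Timedelta(days=int(grp["day"].min()) - 1),
                "end": base + pd.Timedelta(days=int(grp["day"].max()) - 1),
            }
        )
    return pd.DataFrame(rows)


def field_metrics_from_tables(
    sampling: pd.DataFrame, weather_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(insect metric table, weather metric table) from raw tables."""
    series = insects.series_from_frame(sampling)
    insect_table = insects.compute_insect_metric_table(series)
    windows = sampling_windows(sampling)
    weather_metrics = weather.compute_weather_metric_table(weather_table, windows)
    return insect_table, weather_metrics


def run_all(cfg: io.RunConfig, seed: int | None, out_dir: str | Path) -> PipelineResult:
    """Execute the full chain on a simulated study and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    if seed is not None:
        sim = SimulationConfig(**{**sim.__dict__, "seed": seed})

    study = generate_study(sim)
    write_study(study, out)

    reclassified = {k: r for k, r in study.rasters.items()}  # generator emits composite codes
    land_table = landscape.compute_landscape_table(
        reclassified,
        study.legend,
        study.sites,
        radius=cfg.landscape.radius,
        connectivity=cfg.landscape.connectivity,
        prox_radius=cfg.landscape.prox_radius,
        count_boundary=cfg.landscape.count_boundary,
    )
    io.write_metrics_csv(land_table, out / "landscape_metrics.csv")

    insect_table, weather_metrics = field_metrics_from_tables(study.sampling, study.weather)
    io.write_metrics_csv(insect_table, out / "insect_metrics.csv")
    io.write_metrics_csv(weather_metrics, out / "weather_metrics.csv")

    env = land_table.merge(weather_metrics, on=["site_id", "year"])
    env = env[["site_id", "year", *[c for c in ENV_COLUMNS if c in env.columns]]]
    io.write_metrics_csv(env, out / "env_covariates.csv")

    result = run_pipeline(insect_table, env, cfg.pipeline)
    result.pooling.to_csv(out / "anova_pooling.csv", index=False)
    result.optimal_models.to_csv(out / "optimal_models.csv", index=False)
    result.inclusion_frequencies.to_csv(out / "inclusion_frequencies.csv", index=False)
    result.vif_report.to_csv(out / "vif_report.csv", index=False)
    result.spearman.to_csv(out / "spearman.csv")

    io.write_manifest(
        out,
        cfg,
        seed if seed is not None else sim.seed,
        [
            "sites.csv",
            "weather.csv",
            "sampling.csv",
            "landscape_metrics.csv",
            "insect_metrics.csv",
            "weather_metrics.csv",
            "env_covariates.csv",
            "anova_pooling.csv",
            "optimal_models.csv",
            "inclusion_frequencies.csv",
            "vif_report.csv",
            "spearman.csv",
        ],
    )
    return result
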