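"""Synthetic agroecosystem generator: landscapes, weather, and insect series.

Every downstream stage of the package is testable against this module's known
ground truth.  Three generators mirror the three field inputs:

* :func:`generate_landscape` — categorical rasters with controllable class
  composition and patch aggregation.  Each class is carved from a
  Gaussian-smoothed white-noise score field: the class's quota of pixels is
  the top-scoring unassigned cells, so realized composition is exact to
  rounding, while the smoothing length (set by ``aggregation_level``) controls
  whether those cells form many scattered patches or a few large ones.
* :func:`generate_weather` — daily TMAX (Normal around a site's regional
  mean, which follows a north–south gradient) and PPT (zero-inflated Gamma).
* :func:`simulate_field_series` — a discrete-time (daily) predator–prey–
  parasitoid model observed through overdispersed per-leaf counts.

The field model, per site-year, with per-leaf aphid density A, lady beetle
density B, and mummy density M (all insects per leaf):

    A[t+1] = A[t] + r A[t] (1 − A[t]/K) − (a_LB B[t] + a_MM M[t]) A[t]
    B[t+1] = B[t] + g_LB A[t − lag_LB] − m_LB B[t]
    M[t+1] = M[t] + g_MM A[t − lag_MM] − m_MM M[t]

Aphids arrive at a random day after sampling begins (so the series opens with
at least one all-zero event); enemies recruit in proportion to the lagged
aphid density, which reproduces the qualitative field pattern of enemy spikes
trailing aphid spikes.  Covariates enter through
``ln r = ln r0 + Σ β_r,j (x_j − c_j)`` and likewise for ln K, plus lognormal
field-to-field noise.

Observation: at each sampling event the total count of each group is drawn
negative-binomially with mean = latent density × leaves examined and shape
``dispersion``; per-leaf values are totals / leaves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .insects import SamplingSeries
from .raster import Buffer, CategoryLegend, LandscapeRaster, clip_buffer, write_raster

#: composite categories emitted by the generator (background must be first)
DEFAULT_CLASS_MIX = {
    "Sorghum": 0.05,
    "Wheat": 0.22,
    "Cotton": 0.04,
    "Grassland, pasture, and herbaceous": 0.22,
    "Woodland": 0.05,
    "Corn": 0.02,
    "Fallow": 0.02,
}

BACKGROUND = "Background"


def default_legend(class_mix: dict[str, float] | None = None) -> CategoryLegend:
    """Identity legend over the generator's categories plus background."""
    names = list((class_mix or DEFAULT_CLASS_MIX).keys())
    mapping = {0: BACKGROUND}
    mapping.update({i + 1: name for i, name in enumerate(sorted(names))})
    return CategoryLegend(mapping=mapping, background=BACKGROUND)


@dataclass
class WeatherParams:
    """Regional daily-weather parameters (defaults emulate a warm-temperate
    sorghum season: TMAX around 33 °C, about one wet day in four)."""

    tmax_mean: float = 33.0  # °C at the reference latitude
    tmax_sd: float = 3.0  # day-to-day °C
    tmax_gradient: float = -4e-5  # °C per meter northward
    wet_prob: float = 0.25  # daily probability of rain
    ppt_shape: float = 0.8  # Gamma shape of wet-day totals
    ppt_scale: float = 10.0  # Gamma scale, mm
    ppt_gradient: float = 5e-6  # relative change in ppt_scale per meter north


@dataclass
class DynamicsTruth:
    """Ground-truth dynamic parameters for one simulated study."""

    r0: float = 0.28  # aphid intrinsic growth, day⁻¹
    K0: float = 150.0  # carrying capacity, aphids per leaf
    lag_LB: float = 10.0  # lady beetle recruitment lag, days
    lag_MM: float = 14.0  # parasitoid (mummy) lag, days
    gain_LB: float = 0.003  # enemies·leaf⁻¹·day⁻¹ per aphid·leaf⁻¹
    gain_MM: float = 0.006
    mort_LB: float = 0.10  # daily enemy loss rates
    mort_MM: float = 0.08
    attack_LB: float = 0.08  # per-enemy daily aphid mortality
    attack_MM: float = 0.02
    beta_lnr: dict[str, float] = field(default_factory=dict)
    beta_lnK: dict[str, float] = field(default_factory=dict)
    covariate_centers: dict[str, float] = field(default_factory=dict)
    sd_lnr: float = 0.15  # field-to-field lognormal noise
    sd_lnK: float = 0.30
    dispersion: float = 10.0  # negative-binomial shape of observed totals
    A0: float = 0.2  # aphid density at arrival, per leaf

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.K0 <= 0:
            raise ValueError("r0 and K0 must be > 0")
        if self.lag_LB < 0 or self.lag_MM < 0:
            raise ValueError("lags must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic data set."""

    seed: int = 0
    n_sites: int = 20
    years: tuple[int, ...] = (2017, 2018)
    raster_resolution: float = 30.0  # m per pixel
    buffer_radius: float = 5000.0  # m
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    mix_jitter: float = 0.4  # lognormal sd on per-site class proportions
    aggregation_level: float = 0.5  # patch clumping, in [0, 1]
    weather_params: WeatherParams = field(default_factory=WeatherParams)
    dynamics_params: DynamicsTruth = field(default_factory=DynamicsTruth)
    sampling_interval_days: int = 7
    n_events: int = 12
    leaves_per_event: int = 100
    season_start_doy: int = 150
    arrival_window: tuple[int, int] = (7, 28)  # days after season start
    start_mid_outbreak: bool = False  # start sampling after aphid arrival
    domain_size: float = 100_000.0  # m; extent of the site-placement square

    def __post_init__(self) -> None:
        mix = self.class_mix
        if any(p < 0 for p in mix.values()):
            raise ValueError("class_mix proportions must be nonnegative")
        if sum(mix.values()) > 1 + 1e-9:
            raise ValueError(f"class_mix proportions sum to {sum(mix.values()):.3f} > 1")
        if self.raster_resolution <= 0:
            raise ValueError("raster_resolution must be > 0")
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1")
        if not 0 <= self.aggregation_level <= 1:
            raise ValueError("aggregation_level must be in [0, 1]")


# ---------------------------------------------------------------------------
# landscape


def generate_landscape(
    config: SimulationConfig,
    site_seed: int,
    class_mix: dict[str, float] | None = None,
    n_pixels: int | None = None,
) -> LandscapeRaster:
    """Generate one categorical raster covering at least the buffer disc.

    Codes follow :func:`default_legend` over ``config.class_mix`` (0 =
    background).  Identical (config, site_seed) arguments reproduce the raster
    exactly.
    """
    mix = dict(class_mix if class_mix is not None else config.class_mix)
    if sum(mix.values()) > 1 + 1e-9:
        raise ValueError("class_mix proportions sum to > 1")
    rng = np.random.default_rng([abs(int(config.seed)), abs(int(site_seed))])
    res = config.raster_resolution
    if n_pixels is None:
        n_pixels = int(np.ceil(2 * config.buffer_radius / res)) + 2
    total = n_pixels * n_pixels
    # smoothing length: 0 -> salt-and-pepper, 1 -> a few large blobs
    sigma = 0.5 + config.aggregation_level * 0.06 * n_pixels

    legend = default_legend(dict.fromkeys(config.class_mix, 0.0) | mix)
    codes = np.zeros((n_pixels, n_pixels), dtype=np.int64)
    unassigned = np.ones(total, dtype=bool)
    # larger quotas carve first so small classes are not squeezed out
    order = sorted(mix, key=mix.get, reverse=True)
    for name in order:
        quota = int(round(mix[name] * total))
        if quota <= 0:
            continue
        noise = rng.standard_normal((n_pixels, n_pixels))
        score = ndimage.gaussian_filter(noise, sigma=sigma).ravel()
        score[~unassigned] = -np.inf
        take = np.argpartition(score, -quota)[-quota:]
        codes.ravel()[take] = legend.code_of(name)
        unassigned[take] = False
    return LandscapeRaster(codes=codes, resolution=res, origin=(0.0, 0.0))


# ---------------------------------------------------------------------------
# weather


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    x: float
    y: float
    year: int


def generate_weather(
    config: SimulationConfig,
    site: SiteRecord,
    dates: pd.DatetimeIndex,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily TMAX/PPT for one site over ``dates`` (columns site_id, date,
    tmax_c, ppt_mm)."""
    if len(dates) == 0:
        raise ValueError("weather window must be nonempty")
    wp = config.weather_params
    if rng is None:
        import zlib

        site_key = zlib.crc32(site.site_id.encode()) % 2**31
        rng = np.random.default_rng([abs(int(config.seed)), site_key, site.year])
    n = len(dates)
    site_mean = wp.tmax_mean + wp.tmax_gradient * site.y
    tmax = site_mean + wp.tmax_sd * rng.standard_normal(n)
    scale = wp.ppt_scale * max(0.0, 1.0 + wp.ppt_gradient * site.y)
    wet = rng.random(n) < wp.wet_prob
    amounts = rng.gamma(wp.ppt_shape, scale, size=n) if scale > 0 else np.zeros(n)
    ppt = np.where(wet, amounts, 0.0)
    return pd.DataFrame(
        {"site_id": site.site_id, "date": dates, "tmax_c": tmax, "ppt_mm": ppt}
    )


# ---------------------------------------------------------------------------
# insect dynamics


def _field_parameters(
    truth: DynamicsTruth, covariates: dict[str, float], rng: np.random.Generator
) -> tuple[float, float]:
    """Field-level (r, K) from the covariate effect model plus lognormal noise."""

    def shift(betas: dict[str, float]) -> float:
        s = 0.0
        for name, b in betas.items():
            x = covariates.get(name)
            if x is None or not np.isfinite(x):
                continue
            s += b * (x - truth.covariate_centers.get(name, 0.0))
        return s

    ln_r = np.log(truth.r0) + shift(truth.beta_lnr) + truth.sd_lnr * rng.standard_normal()
    ln_K = np.log(truth.K0) + shift(truth.beta_lnK) + truth.sd_lnK * rng.standard_normal()
    return float(np.exp(ln_r)), float(np.exp(ln_K))


def latent_trajectories(
    truth: DynamicsTruth,
    r: float,
    K: float,
    n_days: int,
    arrival_day: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic daily latent densities (aphids, lady beetles, mummies)."""
    A = np.zeros(n_days)
    B = np.zeros(n_days)
    M = np.zeros(n_days)
    if arrival_day < n_days:
        A[arrival_day] = truth.A0
    lag_b = int(round(truth.lag_LB))
    lag_m = int(round(truth.lag_MM))
    for t in range(arrival_day, n_days - 1):
        growth = r * A[t] * (1 - A[t] / K)
        predation = (truth.attack_LB * B[t] + truth.attack_MM * M[t]) * A[t]
        A[t + 1] = max(A[t] + growth - predation, 0.0)
        a_lag_b = A[t - lag_b] if t - lag_b >= arrival_day else 0.0
        a_lag_m = A[t - lag_m] if t - lag_m >= arrival_day else 0.0
        B[t + 1] = max(B[t] + truth.gain_LB * a_lag_b - truth.mort_LB * B[t], 0.0)
        M[t + 1] = max(M[t] + truth.gain_MM * a_lag_m - truth.mort_MM * M[t], 0.0)
    return A, B, M


def _observe(
    latent: np.ndarray, leaves: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial totals (Gamma–Poisson mixture) / leaves."""
    mean = latent * leaves
    lam = np.where(mean > 0, rng.gamma(dispersion, 1.0, size=mean.shape) * mean / dispersion, 0.0)
    return rng.poisson(lam).astype(float) / leaves


def simulate_field_series(
    truth: DynamicsTruth,
    covariates: dict[str, float],
    config: SimulationConfig,
    seed: int,
    site_id: str = "S0",
    year: int = 2017,
) -> SamplingSeries:
    """One simulated field-year of per-leaf sampling observations."""
    rng = np.random.default_rng([abs(int(config.seed)), abs(int(seed))])
    interval = config.sampling_interval_days
    horizon = (config.n_events - 1) * interval + 1
    lo, hi = config.arrival_window
    arrival = int(rng.integers(lo, hi + 1))
    r, K = _field_parameters(truth, covariates, rng)
    A, B, M = latent_trajectories(truth, r, K, horizon + arrival, arrival)
    start = arrival + 1 if config.start_mid_outbreak else 0
    event_idx = start + np.arange(config.n_events) * interval
    event_idx = event_idx[event_idx < len(A)]
    leaves = config.leaves_per_event
    return SamplingSeries(
        site_id=site_id,
        year=year,
        days=config.season_start_doy + event_idx - start,
        leaves=np.full(len(event_idx), leaves),
        nSA=_observe(A[event_idx], leaves, truth.dispersion, rng),
        nLB=_observe(B[event_idx], leaves, truth.dispersion, rng),
        nMM=_observe(M[event_idx], leaves, truth.dispersion, rng),
    )


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class SyntheticStudy:
    """In-memory bundle of one generated study."""

    config: SimulationConfig
    legend: CategoryLegend
    sites: pd.DataFrame  # site_id, x, y, year
    rasters: dict[tuple[str, int], LandscapeRaster]
    weather: pd.DataFrame  # site_id, date, tmax_c, ppt_mm
    sampling: pd.DataFrame  # site_id, year, day, leaves, total_SA, total_LB, total_MM
    truth: dict  # per-site-year ground-truth parameters


def _site_covariates(
    raster: LandscapeRaster,
    legend: CategoryLegend,
    center: tuple[float, float],
    radius: float,
) -> dict[str, float]:
    """Landscape covariates measured on the generated raster (the same
    definitions downstream metrics use)."""
    from .landscape import (
        PLAND_CATEGORIES,
        compute_pland,
        compute_pd,
        compute_sidi_siei,
        delineate_patches,
    )

    clipped = clip_buffer(raster, Buffer(center=center, radius=radius))
    bg = legend.code_of(legend.background)
    out: dict[str, float] = {}
    for cat, col in PLAND_CATEGORIES.items():
        patches = delineate_patches(clipped, legend.code_of(cat), background_code=bg)
        out[col] = compute_pland(patches)
        if cat == "Sorghum":
            out["PD"] = compute_pd(patches) if patches.n_patches else 0.0
    out["SIDI"] = compute_sidi_siei(clipped, background_code=bg).SIDI
    return out


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate sites, rasters, weather, and sampling series for a whole study."""
    from .weather import compute_weather_metrics
    from .weather import WeatherSeries

    rng = np.random.default_rng(abs(int(config.seed)))
    legend = default_legend(config.class_mix)
    radius = config.buffer_radius

    site_rows = []
    rasters: dict[tuple[str, int], LandscapeRaster] = {}
    weather_frames = []
    sampling_rows = []
    truth_log: dict[str, dict] = {}

    positions = rng.uniform(0, config.domain_size, size=(config.n_sites, 2))
    for i in range(config.n_sites):
        site_id = f"S{i:03d}"
        x, y = positions[i]
        for j, year in enumerate(config.years):
            site_seed = i * 1000 + j
            # per-site composition jitter so covariates vary across fields
            jit = {
                name: p * float(np.exp(config.mix_jitter * rng.standard_normal()))
                for name, p in config.class_mix.items()
            }
            scale = sum(jit.values())
            if scale > 0.95:
                jit = {k: v * 0.95 / scale for k, v in jit.items()}
            raster = generate_landscape(config, site_seed, class_mix=jit)
            extent = raster.codes.shape[0] * raster.resolution
            raster = LandscapeRaster(
                raster.codes, raster.resolution, origin=(x - extent / 2, y - extent / 2)
            )
            rasters[(site_id, year)] = raster
            site_rows.append({"site_id": site_id, "x": x, "y": y, "year": year})

            horizon = (config.n_events - 1) * config.sampling_interval_days + 1
            dates = pd.date_range(
                pd.Timestamp(year=year, month=1, day=1)
                + pd.Timedelta(days=config.season_start_doy - 1),
                periods=horizon,
                freq="D",
            )
            site = SiteRecord(site_id=site_id, x=x, y=y, year=year)
            wrng = np.random.default_rng([abs(int(config.seed)), 77, i, j])
            wdf = generate_weather(config, site, dates, rng=wrng)
            weather_frames.append(wdf)

            cov = _site_covariates(raster, legend, (x, y), radius)
            wm = compute_weather_metrics(
                WeatherSeries(
                    site_id=site_id,
                    dates=dates,
                    tmax_c=wdf["tmax_c"].to_numpy(),
                    ppt_mm=wdf["ppt_mm"].to_numpy(),
                )
            )
            cov.update(wm.as_dict())

            series = simulate_field_series(
                config.dynamics_params,
                cov,
                config,
                seed=site_seed + 500_000,
                site_id=site_id,
                year=year,
            )
            for d, lv, sa, lb, mm in zip(
                series.days, series.leaves, series.nSA, series.nLB, series.nMM
            ):
                sampling_rows.append(
                    {
                        "site_id": site_id,
                        "year": year,
                        "day": int(d),
                        "leaves": int(lv),
                        "total_SA": int(round(sa * lv)),
                        "total_LB": int(round(lb * lv)),
                        "total_MM": int(round(mm * lv)),
                    }
                )
            truth_log[f"{site_id}/{year}"] = {"covariates": cov}

    truth = {
        "dynamics": dataclasses.asdict(config.dynamics_params),
        "site_years": truth_log,
    }
    return SyntheticStudy(
        config=config,
        legend=legend,
        sites=pd.DataFrame(site_rows),
        rasters=rasters,
        weather=pd.concat(weather_frames, ignore_index=True),
        sampling=pd.DataFrame(sampling_rows),
        truth=truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write sites.csv, weather.csv, sampling.csv, truth.json, and rasters/."""
    from .raster import write_legend_csv

    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    study.sites.to_csv(out / "sites.csv", index=False)
    w = study.weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.strftime("%Y-%m-%d")
    w.to_csv(out / "weather.csv", index=False)
    study.sampling.to_csv(out / "sampling.csv", index=False)
    write_legend_csv(study.legend, out / "legend.csv")
    for (site_id, year), raster in study.rasters.items():
        write_raster(raster, out / "rasters" / f"{site_id}_{year}.grid")
    (out / "truth.json").write_text(json.dumps(study.truth, indent=1, sort_keys=True))
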