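"""Weather series handling: bilinear site interpolation and window summaries.

Weather covariates summarize the daily series over the period during which a
site was sampled: maxTMAX (°C), sdTMAX (°C), meanPPT (mm), and cvPPT
(sd/mean, unitless).  sd and cv use the sample (n-1) convention.  cvPPT is
undefined (NaN) when meanPPT is 0; such records are dropped later from models
that require cvPPT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeatherSeries:
    """Daily records for one site; dates contiguous over the window."""

    site_id: str
    dates: pd.DatetimeIndex
    tmax_c: np.ndarray
    ppt_mm: np.ndarray

    def __post_init__(self) -> None:
        d = pd.DatetimeIndex(self.dates)
        if len(d) > 1 and not (np.diff(d.values).astype("timedelta64[D]") == 1).all():
            raise ValueError(f"{self.site_id}: weather dates must be contiguous daily")
        ppt = np.asarray(self.ppt_mm, dtype=float)
        if np.any(ppt < 0):
            raise ValueError(f"{self.site_id}: PPT must be >= 0")
        object.__setattr__(self, "dates", d)
        object.__setattr__(self, "tmax_c", np.asarray(self.tmax_c, dtype=float))
        object.__setattr__(self, "ppt_mm", ppt)


@dataclass(frozen=True)
class WeatherMetricSet:
    maxTMAX: float
    sdTMAX: float
    meanPPT: float
    cvPPT: float  # NaN when meanPPT == 0

    def as_dict(self) -> dict[str, float]:
        return {
            "maxTMAX": self.maxTMAX,
            "sdTMAX": self.sdTMAX,
            "meanPPT": self.meanPPT,
            "cvPPT": self.cvPPT,
        }


def bilinear_interpolate(
    grid: np.ndarray,
    cell_size: float,
    origin: tuple[float, float],
    x: float,
    y: float,
) -> float:
    """Bilinear interpolation from the 4 surrounding cell centers.

    ``grid`` is (nrows, ncols) with row 0 at the top; cell (0, 0)'s center is
    at origin + cell_size/2 in x and origin_y + (nrows - 0.5) * cell_size in y.
    Raises ValueError when (x, y) falls outside the hull of cell centers.
    """
    nrows, ncols = grid.shape
    x0, y0 = origin
    fx = (x - x0) / cell_size - 0.5  # fractional column
    fy = (nrows - 0.5) - (y - y0) / cell_size  # fractional row (top-down)
    if fx < 0 or fx > ncols - 1 or fy < 0 or fy > nrows - 1:
        raise ValueError(f"point ({x}, {y}) outside the grid's cell-center hull")
    c0 = int(math.floor(fx))
    r0 = int(math.floor(fy))
    c1 = min(c0 + 1, ncols - 1)
    r1 = min(r0 + 1, nrows - 1)
    tx = fx - c0
    ty = fy - r0
    top = grid[r0, c0] * (1 - tx) + grid[r0, c1] * tx
    bot = grid[r1, c0] * (1 - tx) + grid[r1, c1] * tx
    return float(top * (1 - ty) + bot * ty)


def interpolate_weather(
    stacks: dict[str, np.ndarray],
    dates: pd.DatetimeIndex,
    cell_size: float,
    origin: tuple[float, float],
    site_id: str,
    x: float,
    y: float,
) -> WeatherSeries:
    """Interpolate daily TMAX/PPT stacks (n_days, nrows, ncols) at a site."""
    tmax = np.array(
        [bilinear_interpolate(day, cell_size, origin, x, y) for day in stacks["tmax_c"]]
    )
    ppt = np.array(
        [bilinear_interpolate(day, cell_size, origin, x, y) for day in stacks["ppt_mm"]]
    )
    return WeatherSeries(site_id=site_id, dates=dates, tmax_c=tmax, ppt_mm=np.maximum(ppt, 0.0))


def compute_weather_metrics(
    w: WeatherSeries,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> WeatherMetricSet:
    """Summarize TMAX/PPT over ``window`` (inclusive); default: full series."""
    if window is None:
        mask = np.ones(len(w.dates), dtype=bool)
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        mask = (w.dates >= start) & (w.dates <= end)
    if not mask.any():
        raise ValueError(f"{w.site_id}: empty weather window")
    tmax = w.tmax_c[mask]
    ppt = w.ppt_mm[mask]
    mean_ppt = float(ppt.mean())
    sd_ppt = float(ppt.std(ddof=1)) if len(ppt) > 1 else 0.0
    return WeatherMetricSet(
        maxTMAX=float(tmax.max()),
        sdTMAX=float(tmax.std(ddof=1)) if len(tmax) > 1 else 0.0,
        meanPPT=mean_ppt,
        cvPPT=(sd_ppt / mean_ppt) if mean_ppt > 0 else math.nan,
    )


def compute_weather_metric_table(
    weather: pd.DataFrame, sampling_windows: pd.DataFrame
) -> pd.DataFrame:
    """One row of weather metrics per site-year.

    ``weather`` has columns site_id, date, tmax_c, ppt_mm; ``sampling_windows``
    has site_id, year, start, end (dates bounding the sampling period).
    """
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    rows = []
    for rec in sampling_windows.itertuples(index=False):
        start, end = pd.Timestamp(rec.start), pd.Timestamp(rec.end)
        sub = weather[
            (weather["site_id"] == rec.site_id)
            & (weather["date"] >= start)
            & (weather["date"] <= end)
        ].sort_values("date")
        if sub.empty:
            raise ValueError(
                f"no weather records for site {rec.site_id} in {start.date()}..{end.date()}"
            )
        ws = WeatherSeries(
            site_id=str(rec.site_id),
            dates=pd.DatetimeIndex(sub["date"]),
            tmax_c=sub["tmax_c"].to_numpy(),
            ppt_mm=sub["ppt_mm"].to_numpy(),
        )
        ms = compute_weather_metrics(ws)
        rows.append({"site_id": rec.site_id, "year": int(rec.year), **ms.as_dict()})
    return pd.DataFrame(rows)
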