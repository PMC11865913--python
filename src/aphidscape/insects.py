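"""Insect population-dynamics metrics extracted from field sampling series.

One :class:`SamplingSeries` is the time series of per-leaf counts of sorghum
aphids (SA), lady beetles (LB), and parasitoid mummies (MM) at one field in
one year.  Ten metrics summarize its dynamics:

========== ====================================================================
nSAmax     maximum aphids per leaf
nLBmax     maximum lady beetles per leaf
nMMmax     maximum mummies per leaf
rLBMMmax   nLBmax / nMMmax (defined only when nMMmax > 0)
dtSAmax    days from the last zero-aphid event preceding the first positive
           aphid event to the first event attaining nSAmax
dtRespLB   first-appearance-after-absence day of LB minus that of SA
dtRespMM   likewise for MM
vSA        nSAmax / dtSAmax (aphids per leaf per day)
vLB, vMM   each channel's own max over its own last-zero-to-max interval
========== ====================================================================

A metric whose reference days do not exist (e.g. a series that starts with
aphids already present) is missing (NaN).  Downstream retention applies the
strictly-positive filter to nSAmax, nLBmax, nMMmax, dtRespLB and dtRespMM:
values <= 0 are computed but flagged for exclusion.

Per-leaf values are totals divided by leaves examined and are carried as
reals, never rounded.  "Zero" always means an observed count of zero at a
sampling event; unsampled days are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CHANNELS = ("SA", "LB", "MM")

METRIC_NAMES = (
    "nSAmax",
    "nLBmax",
    "nMMmax",
    "rLBMMmax",
    "dtSAmax",
    "dtRespLB",
    "dtRespMM",
    "vSA",
    "vLB",
    "vMM",
)

#: metrics subject to the strictly-positive retention filter
POSITIVE_FILTERED = ("nSAmax", "nLBmax", "nMMmax", "dtRespLB", "dtRespMM")


@dataclass(frozen=True)
class SamplingSeries:
    """Per-leaf counts at one field-year; days strictly increasing."""

    site_id: str
    year: int
    days: np.ndarray  # day of year, ints
    leaves: np.ndarray  # leaves examined per event
    nSA: np.ndarray  # per-leaf values (totals / leaves)
    nLB: np.ndarray
    nMM: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        if days.size and not np.all(np.diff(days) > 0):
            raise ValueError(
                f"{self.site_id}/{self.year}: sampling days must be strictly increasing"
            )
        leaves = np.asarray(self.leaves)
        if leaves.size and not np.all(leaves >= 1):
            raise ValueError(f"{self.site_id}/{self.year}: leaves_examined must be >= 1")
        for name in ("nSA", "nLB", "nMM"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{self.site_id}/{self.year}: {name} must be finite, >= 0")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "days", np.asarray(days))
        object.__setattr__(self, "leaves", np.asarray(leaves))

    def __len__(self) -> int:
        return len(self.days)

    def channel(self, name: str) -> np.ndarray:
        return {"SA": self.nSA, "LB": self.nLB, "MM": self.nMM}[name]


@dataclass(frozen=True)
class InsectMetricSet:
    """The ten metrics plus retention flags; NaN encodes missing."""

    values: dict[str, float]
    retained: dict[str, bool]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def first_after_absence(days: np.ndarray, values: np.ndarray) -> float:
    """Earliest day with value > 0 immediately preceded by an event with value 0.

    NaN if no such day exists (series starts positive, or never positive).
    """
    for i in range(1, len(values)):
        if values[i] > 0 and values[i - 1] == 0:
            return float(days[i])
    return math.nan


def _last_zero_before_first_positive(days: np.ndarray, values: np.ndarray) -> float:
    """Day of the last zero event preceding the first positive event; NaN if the
    series starts positive or is never positive."""
    pos = np.nonzero(values > 0)[0]
    if pos.size == 0 or pos[0] == 0:
        return math.nan
    return float(days[pos[0] - 1])


def _max_day(days: np.ndarray, values: np.ndarray) -> float:
    """Day of the first event attaining the channel maximum."""
    return float(days[int(np.argmax(values))])


def compute_insect_metrics(series: SamplingSeries) -> InsectMetricSet:
    """Apply the ten metric definitions to one sampling series."""
    if len(series) < 2:
        raise ValueError(f"{series.site_id}/{series.year}: need >= 2 sampling events")

    days = series.days
    v: dict[str, float] = {}

    maxima = {ch: float(series.channel(ch).max()) for ch in CHANNELS}
    v["nSAmax"], v["nLBmax"], v["nMMmax"] = (maxima[c] for c in CHANNELS)
    v["rLBMMmax"] = maxima["LB"] / maxima["MM"] if maxima["MM"] > 0 else math.nan

    first = {ch: first_after_absence(days, series.channel(ch)) for ch in CHANNELS}
    v["dtRespLB"] = first["LB"] - first["SA"]  # NaN-propagating
    v["dtRespMM"] = first["MM"] - first["SA"]

    # per-channel last-zero-to-max interval and speed of increase
    speeds = {}
    for ch in CHANNELS:
        vals = series.channel(ch)
        anchor = _last_zero_before_first_positive(days, vals)
        if math.isnan(anchor) or maxima[ch] <= 0:
            speeds[ch] = (math.nan, math.nan)
            continue
        dt = _max_day(days, vals) - anchor
        speeds[ch] = (dt, maxima[ch] / dt)
    v["dtSAmax"], v["vSA"] = speeds["SA"]
    _, v["vLB"] = speeds["LB"]
    _, v["vMM"] = speeds["MM"]

    retained = {
        name: (not math.isnan(v[name])) and (v[name] > 0 if name in POSITIVE_FILTERED else True)
        for name in METRIC_NAMES
    }
    return InsectMetricSet(values={n: v[n] for n in METRIC_NAMES}, retained=retained)


def series_from_frame(df: pd.DataFrame) -> list[SamplingSeries]:
    """Build SamplingSeries from a table with columns
    site_id, year, day, leaves, total_SA, total_LB, total_MM."""
    required = {"site_id", "year", "day", "leaves", "total_SA", "total_LB", "total_MM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sampling table missing columns {sorted(missing)}")
    out = []
    for (site, year), grp in df.groupby(["site_id", "year"], sort=True):
        grp = grp.sort_values("day")
        leaves = grp["leaves"].to_numpy()
        out.append(
            SamplingSeries(
                site_id=str(site),
                year=int(year),
                days=grp["day"].to_numpy(),
                leaves=leaves,
                nSA=grp["total_SA"].to_numpy() / leaves,
                nLB=grp["total_LB"].to_numpy() / leaves,
                nMM=grp["total_MM"].to_numpy() / leaves,
            )
        )
    return out


def compute_insect_metric_table(series_list: list[SamplingSeries]) -> pd.DataFrame:
    """One row per site-year: the ten metrics plus ``<name>_retained`` flags."""
    rows = []
    for s in series_list:
        ms = compute_insect_metrics(s)
        row: dict[str, object] = {"site_id": s.site_id, "year": s.year}
        row.update(ms.values)
        row.update({f"{n}_retained": ms.retained[n] for n in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def apply_retention(table: pd.DataFrame) -> pd.DataFrame:
    """Mask metric values whose retention flag is False (the '>0' filter)."""
    out = table.copy()
    for name in METRIC_NAMES:
        flag = f"{name}_retained"
        if flag in out.columns:
            out.loc[~out[flag].astype(bool), name] = np.nan
    return out
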