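"""Class- and landscape-level composition/configuration metrics.

All metrics are computed within a clipped circular buffer on a reclassified
categorical raster.  Conventions (documented once, used everywhere):

* **Landscape area** is the set of in-buffer pixels that are *not* background;
  PLAND, PD, ED, SIDI and SIEI use this area as the denominator, so PLAND sums
  to 100 over the non-background classes on any buffer.
* **Patches** are maximal connected components of same-class pixels;
  connectivity is 8-neighbor by default (the common raster default),
  configurable to 4.
* **Perimeter** counts pixel sides between a class pixel and any pixel of a
  different class; sides facing out-of-buffer or out-of-raster count by
  default (``count_boundary=False`` turns them off).
* **CLUMPY adjacency** is tallied over ordered side-adjacent pixel pairs whose
  first member is the focal class and whose second member is any in-buffer,
  non-background pixel (the double-count convention: a like pair contributes
  two ordered pairs, an unlike pair one).
* **PROX distance** between patches is the minimum cell-center to cell-center
  distance, in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .raster import OUTSIDE, Buffer, CategoryLegend, LandscapeRaster, clip_buffer

__all__ = [
    "PatchSet",
    "ClassMetricSet",
    "LandscapeMetricSet",
    "delineate_patches",
    "compute_pland",
    "compute_pd",
    "compute_ed",
    "compute_shape_md",
    "compute_clumpy",
    "compute_prox_md",
    "compute_sidi_siei",
    "compute_class_metrics",
    "compute_landscape_table",
    "prune_redundant_metrics",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class PatchSet:
    """Connected patches of one class within one buffer."""

    pixel_counts: np.ndarray  # per patch
    perimeters_m: np.ndarray  # per patch, meters
    pixel_coords: list[np.ndarray]  # per patch, (n, 2) center coords in meters
    class_pixels: int
    landscape_pixels: int  # in-buffer, non-background
    resolution: float

    @property
    def n_patches(self) -> int:
        return len(self.pixel_counts)

    @property
    def landscape_area_ha(self) -> float:
        return self.landscape_pixels * self.resolution**2 / 1e4

    @property
    def patch_areas_m2(self) -> np.ndarray:
        return self.pixel_counts * self.resolution**2


@dataclass(frozen=True)
class ClassMetricSet:
    """The class-level metric vector for one (buffer, class); NaN = missing."""

    PLAND: float
    PD: float
    ED: float
    SHAPE_MD: float
    CLUMPY: float
    PROX_MD: float


@dataclass(frozen=True)
class LandscapeMetricSet:
    """Simpson diversity (SIDI) and evenness (SIEI) over non-background classes."""

    SIDI: float
    SIEI: float


def _landscape_mask(clipped: LandscapeRaster, background_code: int) -> np.ndarray:
    return (clipped.codes != OUTSIDE) & (clipped.codes != background_code)


def delineate_patches(
    clipped: LandscapeRaster,
    cls: int,
    *,
    connectivity: int = 8,
    count_boundary: bool = True,
    background_code: int = 0,
) -> PatchSet:
    """Label maximal connected components of class ``cls`` and measure them."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    codes = clipped.codes
    res = clipped.resolution
    mask = codes == cls
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])

    # perimeter: pad with OUTSIDE so raster edges behave like buffer edges
    padded = np.pad(codes, 1, constant_values=OUTSIDE)
    core = padded[1:-1, 1:-1]
    edge_counts = np.zeros(codes.shape, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        boundary = neigh == OUTSIDE
        differs = (neigh != core) & ~boundary
        if count_boundary:
            differs = differs | boundary
        edge_counts += np.where(mask, differs, 0)

    X, Y = clipped.pixel_centers()
    pixel_counts = np.zeros(n, dtype=np.int64)
    perims = np.zeros(n, dtype=np.float64)
    coords: list[np.ndarray] = []
    for i in range(1, n + 1):
        m = labels == i
        pixel_counts[i - 1] = int(m.sum())
        perims[i - 1] = float(edge_counts[m].sum()) * res
        coords.append(np.column_stack([X[m], Y[m]]))

    return PatchSet(
        pixel_counts=pixel_counts,
        perimeters_m=perims,
        pixel_coords=coords,
        class_pixels=int(mask.sum()),
        landscape_pixels=int(_landscape_mask(clipped, background_code).sum()),
        resolution=res,
    )


def compute_pland(patches: PatchSet) -> float:
    """Percentage of landscape area occupied by the class."""
    if patches.landscape_pixels == 0:
        raise ValueError("empty landscape (no non-background in-buffer pixels)")
    return 100.0 * patches.class_pixels / patches.landscape_pixels


def compute_pd(patches: PatchSet) -> float:
    """Patch density: patches per 100 ha of landscape area."""
    area = patches.landscape_area_ha
    if area <= 0:
        raise ValueError("landscape area must be > 0")
    return patches.n_patches / area * 100.0


def compute_ed(patches: PatchSet) -> float:
    """Edge density: total class patch perimeter (m) per ha of landscape area."""
    area = patches.landscape_area_ha
    if area <= 0:
        raise ValueError("landscape area must be > 0")
    return float(patches.perimeters_m.sum()) / area


def compute_shape_md(patches: PatchSet) -> float:
    """Median raster shape index: 0.25 * perimeter / (res * sqrt(pixels)), >= 1."""
    if patches.n_patches == 0:
        return math.nan
    idx = 0.25 * patches.perimeters_m / (
        patches.resolution * np.sqrt(patches.pixel_counts)
    )
    return float(np.median(np.maximum(idx, 1.0)))


def compute_clumpy(
    clipped: LandscapeRaster, cls: int, *, background_code: int = 0
) -> float:
    """Clumpiness: like-adjacency proportion G contrasted with class proportion P.

    CLUMPY = (G - P) / (1 - P) when G >= P, else (G - P) / P; in [-1, 1].
    A class filling the landscape returns 1 (maximal aggregation limit).
    Returns NaN when the class is absent.
    """
    land = _landscape_mask(clipped, background_code)
    mask = clipped.codes == cls
    n_cls = int(mask.sum())
    n_land = int(land.sum())
    if n_cls == 0:
        return math.nan
    if n_cls == n_land:
        return 1.0
    like = 0
    total = 0
    for axis in (0, 1):
        a = np.take(clipped.codes, range(clipped.codes.shape[axis] - 1), axis=axis)
        b = np.take(clipped.codes, range(1, clipped.codes.shape[axis]), axis=axis)
        la = np.take(land, range(land.shape[axis] - 1), axis=axis)
        lb = np.take(land, range(1, land.shape[axis]), axis=axis)
        valid = la & lb
        both_cls = valid & (a == cls) & (b == cls)
        one_cls = valid & ((a == cls) | (b == cls)) & ~both_cls
        like += 2 * int(both_cls.sum())
        total += 2 * int(both_cls.sum()) + int(one_cls.sum())
    if total == 0:
        return math.nan  # isolated pixels with no in-landscape neighbors
    G = like / total
    P = n_cls / n_land
    if G >= P:
        return (G - P) / (1.0 - P)
    return (G - P) / P


def compute_prox_md(patches: PatchSet, search_radius: float) -> float:
    """Median proximity index: per patch, sum over same-class neighbor patches
    within ``search_radius`` of neighbor_area_m2 / distance_m^2."""
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    n = patches.n_patches
    if n == 0:
        return math.nan
    if n == 1:
        return 0.0
    trees = [cKDTree(c) for c in patches.pixel_coords]
    areas = patches.patch_areas_m2
    prox = np.zeros(n)
    # min center-to-center distance between every patch pair
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(patches.pixel_coords[i], k=1)
            dist[i, j] = dist[j, i] = float(d.min())
    for i in range(n):
        for j in range(n):
            if j != i and dist[i, j] <= search_radius:
                prox[i] += areas[j] / dist[i, j] ** 2
    return float(np.median(prox))


def compute_sidi_siei(
    clipped: LandscapeRaster, *, background_code: int = 0
) -> LandscapeMetricSet:
    """Simpson diversity and evenness of non-background class proportions."""
    land = _landscape_mask(clipped, background_code)
    codes = clipped.codes[land]
    if codes.size == 0:
        raise ValueError("empty landscape (no non-background in-buffer pixels)")
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    sidi = 1.0 - float(np.sum(p**2))
    m = len(counts)
    siei = math.nan if m < 2 else sidi / (1.0 - 1.0 / m)
    return LandscapeMetricSet(SIDI=sidi, SIEI=siei)


def compute_class_metrics(
    clipped: LandscapeRaster,
    cls: int,
    *,
    connectivity: int = 8,
    prox_radius: float = 1000.0,
    count_boundary: bool = True,
    background_code: int = 0,
) -> ClassMetricSet:
    """All class-level metrics for one class in one clipped buffer.

    When the class is absent PLAND is 0 and all other metrics are NaN
    (missing), per the class-present contract.
    """
    patches = delineate_patches(
        clipped,
        cls,
        connectivity=connectivity,
        count_boundary=count_boundary,
        background_code=background_code,
    )
    pland = compute_pland(patches)
    if patches.n_patches == 0:
        return ClassMetricSet(0.0, math.nan, math.nan, math.nan, math.nan, math.nan)
    return ClassMetricSet(
        PLAND=pland,
        PD=compute_pd(patches),
        ED=compute_ed(patches),
        SHAPE_MD=compute_shape_md(patches),
        CLUMPY=compute_clumpy(clipped, cls, background_code=background_code),
        PROX_MD=compute_prox_md(patches, prox_radius),
    )


#: composite category -> PLAND column suffix used in output tables
PLAND_CATEGORIES = {
    "Sorghum": "PLANDs",
    "Wheat": "PLANDwh",
    "Cotton": "PLANDc",
    "Grassland, pasture, and herbaceous": "PLANDg",
    "Woodland": "PLANDwo",
}

FOCAL_CATEGORY = "Sorghum"


def compute_landscape_table(
    rasters: dict[tuple[str, int], LandscapeRaster],
    legend: CategoryLegend,
    sites: pd.DataFrame,
    *,
    radius: float = 5000.0,
    connectivity: int = 8,
    prox_radius: float = 1000.0,
    count_boundary: bool = True,
) -> pd.DataFrame:
    """One row per (site, year): the PLAND columns, sorghum configuration
    metrics, and SIDI/SIEI.

    ``rasters`` maps (site_id, year) to a *reclassified* raster; ``sites``
    must have columns site_id, x, y, year.
    """
    bg = legend.code_of(legend.background)
    rows = []
    for rec in sites.itertuples(index=False):
        key = (rec.site_id, int(rec.year))
        if key not in rasters:
            raise KeyError(f"no raster for site-year {key}")
        clipped = clip_buffer(rasters[key], Buffer(center=(rec.x, rec.y), radius=radius))
        row: dict[str, object] = {"site_id": rec.site_id, "year": int(rec.year)}
        for cat, col in PLAND_CATEGORIES.items():
            patches = delineate_patches(
                clipped,
                legend.code_of(cat),
                connectivity=connectivity,
                count_boundary=count_boundary,
                background_code=bg,
            )
            row[col] = compute_pland(patches)
        focal = compute_class_metrics(
            clipped,
            legend.code_of(FOCAL_CATEGORY),
            connectivity=connectivity,
            prox_radius=prox_radius,
            count_boundary=count_boundary,
            background_code=bg,
        )
        row.update(
            PD=focal.PD,
            ED=focal.ED,
            SHAPE_MD=focal.SHAPE_MD,
            CLUMPY=focal.CLUMPY,
            PROX_MD=focal.PROX_MD,
        )
        div = compute_sidi_siei(clipped, background_code=bg)
        row.update(SIDI=div.SIDI, SIEI=div.SIEI)
        rows.append(row)
    return pd.DataFrame(rows)


def prune_redundant_metrics(
    metric_table: pd.DataFrame,
    threshold: float = 0.7,
    representatives: tuple[str, ...] = ("PD", "SIDI"),
) -> tuple[list[str], pd.DataFrame]:
    """Drop metrics that are redundant with a retained representative.

    Pairwise Spearman correlations are computed; metrics connected by
    |r_S| >= threshold form clusters, and one representative per cluster is
    retained (the first name from ``representatives`` present in the cluster,
    else the first column in table order).  Returns (retained names,
    correlation matrix).
    """
    cols = list(metric_table.columns)
    n = len(metric_table)
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    if len(cols) < 2:
        raise ValueError("need >= 2 metrics")
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r = spearmanr(metric_table[a], metric_table[b], nan_policy="omit").statistic
            corr.loc[a, b] = corr.loc[b, a] = r

    # union-find over the |r| >= threshold graph
    parent = {c: c for c in cols}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if abs(corr.loc[a, b]) >= threshold:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for c in cols:
        clusters.setdefault(find(c), []).append(c)
    retained = []
    for members in clusters.values():
        rep = next((r for r in representatives if r in members), members[0])
        retained.append(rep)
    retained.sort(key=cols.index)
    return retained, corr
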